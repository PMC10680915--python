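"""Run configuration: thresholds, null-set counts, seeds, and file paths.

Defaults reproduce the study settings (5% FDR for genetic correlations, 20%
FDR for QTL-effect correlations, 1,000 random marker sets / bootstraps,
marker pruning at r < 0.95, 5-kb interval padding, subsampling at
250/500/750 segregants). The desk-scale preset used by the test fixtures
scales the simulation and the null-set counts down so the whole pipeline
runs in minutes on one CPU; the full-scale preset mirrors the original
study dimensions.
"""

from __future__ import annotations

import hashlib
import json
import zlib
from dataclasses import asdict, dataclass, field, fields

import numpy as np
import yaml


class ConfigError(ValueError):
    """A configuration value is outside its valid range."""


@dataclass
class RunConfig:
    seed: int = 0

    # significance thresholds
    fdr_genetic: float = 0.05
    fdr_qtlfx: float = 0.20
    stepwise_p: float = 0.05
    coloc_min_markers: int = 3
    coloc_min_lod: float = 10.0
    prune_r: float = 0.95
    pad_bp: int = 5000
    go_p_display: float = 1e-3
    go_p_strict: float = 1e-5
    k_clusters: int = 3

    # resampling sizes
    n_null_sets: int = 1000
    n_boot: int = 1000
    bin_sizes: tuple[int, ...] = (1_000, 10_000, 50_000)
    downsample_sizes: tuple[int, ...] = (250, 500, 750)
    downsample_reps: int = 5

    # simulation dimensions (desk-scale defaults; full preset mirrors
    # 979 x 11,530 x 5,643 x 46 x 102)
    n_segregants: int = 200
    n_markers: int = 500
    n_genes: int = 300
    n_conditions: int = 8
    n_hotspots: int = 12

    # stage-specific caps for expensive scans
    coloc_max_pairs: int = 25
    min_pairs_base_medium: int = 3

    # which marker set feeds which stage (the study alternates between
    # marker sets; made explicit here)
    markers_coloc: str = "pruned"  # pruned at prune_r before the 2-D scan
    markers_varcomp: str = "all"

    # file paths (optional; pipeline simulates when absent)
    paths: dict = field(default_factory=dict)

    def validate(self) -> "RunConfig":
        for name in ("fdr_genetic", "fdr_qtlfx", "stepwise_p", "go_p_display", "go_p_strict"):
            v = getattr(self, name)
            if not (0 < v <= 1):
                raise ConfigError(f"{name}={v} must be in (0, 1]")
        if not (0 < self.prune_r <= 1):
            raise ConfigError("prune_r must be in (0, 1]")
        if self.pad_bp < 0:
            raise ConfigError("pad_bp must be >= 0")
        for name in ("n_null_sets", "n_boot", "downsample_reps", "coloc_min_markers",
                     "n_segregants", "n_markers", "n_genes", "n_conditions", "n_hotspots",
                     "k_clusters"):
            if getattr(self, name) < 1:
                raise ConfigError(f"{name} must be >= 1")
        if any(b <= 0 for b in self.bin_sizes):
            raise ConfigError("bin_sizes must be positive")
        if any(s <= 0 for s in self.downsample_sizes):
            raise ConfigError("downsample_sizes must be positive")
        if self.seed < 0 or self.seed >= 2**31:
            raise ConfigError("seed must be in [0, 2^31)")
        return self

    # -- serialization ---------------------------------------------------
    def to_dict(self) -> dict:
        d = asdict(self)
        d["bin_sizes"] = list(self.bin_sizes)
        d["downsample_sizes"] = list(self.downsample_sizes)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ConfigError(f"unknown config keys {sorted(unknown)}")
        d = dict(d)
        for k in ("bin_sizes", "downsample_sizes"):
            if k in d:
                d[k] = tuple(d[k])
        return cls(**d).validate()

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def desk_config(seed: int = 0, **overrides) -> RunConfig:
    """Desk-scale preset: small cross, null-set counts scaled down."""
    base = dict(
        seed=seed,
        n_null_sets=200,
        n_boot=200,
        downsample_sizes=(50, 100, 150),
        downsample_reps=3,
        coloc_min_lod=8.0,
        # the desk fixture plants two condition archetypes; the full-scale
        # study clusters its 46 traits into three groups
        k_clusters=2,
    )
    base.update(overrides)
    return RunConfig(**base).validate()


def full_config(seed: int = 0, **overrides) -> RunConfig:
    """Full-scale preset mirroring the original study dimensions."""
    base = dict(
        seed=seed,
        n_segregants=979,
        n_markers=11_530,
        n_genes=5_643,
        n_conditions=46,
        n_hotspots=102,
    )
    base.update(overrides)
    return RunConfig(**base).validate()


def stage_seed(seed: int, stage: str) -> int:
    """Deterministic per-stage seed derived from the global seed.

    Uses a CRC-32 hash of the stage name mixed into a SeedSequence so that
    stages draw independent streams while remaining reproducible.
    """
    ss = np.random.SeedSequence([int(seed), zlib.crc32(stage.encode())])
    return int(ss.generate_state(1)[0] % (2**31 - 1))


def stage_rng(seed: int, stage: str) -> np.random.Generator:
    return np.random.default_rng(stage_seed(seed, stage))
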