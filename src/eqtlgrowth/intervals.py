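"""Genomic-interval statistics: overlaps, placement nulls, binned peaks.

Overlap between QTL confidence intervals (optionally padded by 5 kb per
side) is counted directly; the chance expectation comes from placing
intervals of the same sizes uniformly at random on the genome subject to
mutual non-overlap. Genome-wide co-occurrence of eQTL and gQTL peaks is
summarized by the Spearman correlation of per-bin peak counts over a fixed
tiling of the genome.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import ValidationError
from .hotspots import empirical_p  # same add-one estimator device

INTERVAL_COLUMNS = ["chrom", "start_bp", "end_bp", "label"]


@dataclass
class GenomeIntervalSet:
    """Labelled 1-based inclusive intervals on a genome with known lengths."""

    intervals: pd.DataFrame  # chrom, start_bp, end_bp, label
    genome: dict[int, int] = field(default_factory=dict)  # chrom -> length bp

    def validate(self) -> "GenomeIntervalSet":
        df = self.intervals
        missing = [c for c in INTERVAL_COLUMNS if c not in df.columns]
        if missing:
            raise ValidationError(f"interval table missing columns {missing}")
        if (df["start_bp"] > df["end_bp"]).any():
            raise ValidationError("interval start must be <= end")
        if (df["start_bp"] < 1).any():
            raise ValidationError("coordinates are 1-based; start must be >= 1")
        if self.genome:
            for _, row in df.iterrows():
                if row["end_bp"] > self.genome.get(row["chrom"], np.inf):
                    raise ValidationError(
                        f"interval {row['label']!r} extends beyond chromosome "
                        f"{row['chrom']}"
                    )
        return self

    def padded(self, pad_bp: int) -> pd.DataFrame:
        """Pad by pad_bp per side, clipping at chromosome bounds."""
        df = self.intervals.copy()
        start = df["start_bp"] - pad_bp
        end = df["end_bp"] + pad_bp
        clipped = (start < 1).any()
        start = start.clip(lower=1)
        if self.genome:
            lengths = df["chrom"].map(self.genome)
            clipped = clipped or bool((end > lengths).any())
            end = np.minimum(end, lengths)
        if pad_bp > 0 and clipped:
            warnings.warn("padded interval(s) clipped at chromosome bounds")
        df["start_bp"] = start
        df["end_bp"] = end
        return df

    def to_bed(self) -> pd.DataFrame:
        """0-based half-open BED representation."""
        df = self.intervals
        return pd.DataFrame(
            {
                "chrom": "chr" + df["chrom"].astype(str),
                "start": df["start_bp"] - 1,
                "end": df["end_bp"],
                "name": df["label"],
            }
        )


def qtl_intervals(qtl_table: pd.DataFrame, genome: dict[int, int]) -> GenomeIntervalSet:
    """Interval set from a QTL table's confidence intervals."""
    df = pd.DataFrame(
        {
            "chrom": qtl_table["chrom"].to_numpy(),
            "start_bp": qtl_table["ci_start_bp"].to_numpy(),
            "end_bp": qtl_table["ci_end_bp"].to_numpy(),
            "label": (
                qtl_table["trait_id"].astype(str) + ":" + qtl_table["peak_marker_id"].astype(str)
            ).to_numpy(),
        }
    )
    return GenomeIntervalSet(df, genome).validate()


def count_overlaps(
    set_a: GenomeIntervalSet, set_b: GenomeIntervalSet, pad_bp: int = 0
) -> tuple[np.ndarray, int]:
    """Per-A-interval count of overlapping B intervals after padding.

    Two padded intervals overlap when they share at least one base pair.
    Returns the count vector (ordered like A) and the number of A intervals
    with at least one overlap.
    """
    A = set_a.padded(pad_bp)
    B = set_b.padded(pad_bp)
    counts = np.zeros(len(A), dtype=int)
    for chrom, bgrp in B.groupby("chrom"):
        on = A["chrom"] == chrom
        if not on.any():
            continue
        a_start = A.loc[on, "start_bp"].to_numpy()[:, None]
        a_end = A.loc[on, "end_bp"].to_numpy()[:, None]
        b_start = bgrp["start_bp"].to_numpy()[None, :]
        b_end = bgrp["end_bp"].to_numpy()[None, :]
        counts[np.nonzero(on.to_numpy())[0]] += (
            (a_start <= b_end) & (b_start <= a_end)
        ).sum(axis=1)
    return counts, int((counts > 0).sum())


def random_interval_placement(
    sizes,
    genome: dict[int, int],
    n_sets: int,
    seed: int | np.random.Generator,
    same_chrom: list[int] | None = None,
    max_attempts: int = 10_000,
) -> list[GenomeIntervalSet]:
    """Random non-overlapping intervals matching the given sizes.

    Each interval is placed uniformly over all genome positions where it
    fits inside a chromosome (chromosome chosen with probability
    proportional to the number of valid start positions), rejecting
    placements that overlap an already-placed interval of the same set.
    ``same_chrom`` optionally pins each interval to a chromosome.
    """
    sizes = [int(s) for s in sizes]
    if any(s < 1 for s in sizes):
        raise ValidationError("interval sizes must be >= 1")
    total = sum(genome.values())
    if sum(sizes) > total:
        raise ValidationError("interval sizes exceed total genome length")
    chroms = sorted(genome)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    out = []
    order = np.argsort(sizes)[::-1]  # place large intervals first
    for s in range(n_sets):
        placed: list[tuple[int, int, int]] = [None] * len(sizes)  # type: ignore
        for k in order:
            size = sizes[k]
            if same_chrom is not None:
                valid = [same_chrom[k]] if genome[same_chrom[k]] >= size else []
            else:
                valid = [c for c in chroms if genome[c] >= size]
            if not valid:
                raise ValidationError(f"set {s}: no chromosome fits an interval of {size} bp")
            wts = np.array([genome[c] - size + 1 for c in valid], float)
            wts /= wts.sum()
            for _ in range(max_attempts):
                c = valid[rng.choice(len(valid), p=wts)]
                start = int(rng.integers(1, genome[c] - size + 2))
                end = start + size - 1
                clash = any(
                    p is not None and p[0] == c and p[1] <= end and start <= p[2]
                    for p in placed
                )
                if not clash:
                    placed[k] = (c, start, end)
                    break
            else:
                raise ValidationError(f"set {s}: could not place interval of {size} bp")
        df = pd.DataFrame(
            {
                "chrom": [p[0] for p in placed],
                "start_bp": [p[1] for p in placed],
                "end_bp": [p[2] for p in placed],
                "label": [f"rand{s}_{k}" for k in range(len(sizes))],
            }
        )
        out.append(GenomeIntervalSet(df, dict(genome)).validate())
    return out


def overlap_pvalue(
    observed: float, null_counts: np.ndarray, direction: str = "greater"
) -> float:
    """Add-one empirical p for an observed overlap count against its null."""
    return empirical_p(observed, np.asarray(null_counts, float), direction)


def bin_cooccurrence(
    eqtl_peaks: pd.DataFrame,
    gqtl_peaks: pd.DataFrame,
    bin_size: int,
    genome: dict[int, int],
) -> tuple[float, float, pd.DataFrame]:
    """Spearman correlation of per-bin eQTL vs gQTL peak counts.

    The genome is tiled by fixed ``bin_size`` windows anchored at position 1
    of each chromosome (last bin truncated). Peak tables need ``chrom`` and
    ``peak_pos_bp`` columns.
    """
    if bin_size <= 0:
        raise ValidationError("bin_size must be positive")
    frames = []
    for chrom in sorted(genome):
        length = genome[chrom]
        edges = np.arange(1, length + bin_size + 1, bin_size)
        edges[-1] = max(edges[-1], length + 1)
        e = eqtl_peaks.loc[eqtl_peaks["chrom"] == chrom, "peak_pos_bp"].to_numpy()
        g = gqtl_peaks.loc[gqtl_peaks["chrom"] == chrom, "peak_pos_bp"].to_numpy()
        e_counts, _ = np.histogram(e, bins=edges)
        g_counts, _ = np.histogram(g, bins=edges)
        frames.append(
            pd.DataFrame(
                {
                    "chrom": chrom,
                    "bin_start": edges[:-1],
                    "n_eqtl": e_counts,
                    "n_gqtl": g_counts,
                }
            )
        )
    bins = pd.concat(frames, ignore_index=True)
    rho, p = stats.spearmanr(bins["n_eqtl"], bins["n_gqtl"])
    return float(rho), float(p), bins
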