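"""Synthetic biparental yeast cross with known genetic architecture.

Every inference stage in this package is validated against simulated data
with complete ground truth: haploid segregant genotypes from a Markov chain
along the genetic map (Haldane map function, no interference, chromosomes
independent), trans-eQTL hotspots that each affect a heavy-tailed number of
genes, local eQTLs at the marker nearest each gene for a configurable
fraction of genes, and growth conditions whose QTL effects sit mostly at
hotspot markers. Effects are specified on the standardized-phenotype scale,
so true effects are directly comparable to estimated marker-trait
correlations. Expression receives batch and OD600 covariate structure;
growth receives independent noise and missing values, mirroring the two
independently collected experiments the design relies on.

Defaults are desk-scale (200 segregants x 500 markers x 300 genes x
8 conditions x 12 hotspots); the full-scale preset mirrors
979 x 11,530 x 5,643 x 46 x 102.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datatypes import GenotypeMatrix, PhenotypeMatrix, ValidationError
from .qtlfx import lod_drop_interval, lod_from_r

# S. cerevisiae chromosome lengths (bp), chromosomes I..XVI
YEAST_CHROM_LENGTHS = (
    230_218, 813_184, 316_620, 1_531_933, 576_874, 270_161, 1_090_940,
    562_643, 439_888, 745_751, 666_816, 1_078_177, 924_431, 784_333,
    1_091_291, 948_066,
)


@dataclass
class GenomeModel:
    """Chromosome lengths plus a constant per-chromosome cM/kb rate."""

    chrom_lengths_bp: tuple[int, ...] = YEAST_CHROM_LENGTHS
    cM_per_kb: float = 0.40  # yeast-like genome-wide average

    def __post_init__(self) -> None:
        if any(length <= 0 for length in self.chrom_lengths_bp):
            raise ValidationError("chromosome lengths must be positive")
        if self.cM_per_kb <= 0:
            raise ValidationError("cM_per_kb must be positive")

    @property
    def n_chrom(self) -> int:
        return len(self.chrom_lengths_bp)

    @property
    def total_bp(self) -> int:
        return int(sum(self.chrom_lengths_bp))

    def as_dict(self) -> dict[int, int]:
        return {c + 1: int(length) for c, length in enumerate(self.chrom_lengths_bp)}


def haldane_r(d_morgans: np.ndarray) -> np.ndarray:
    """Haldane recombination fraction r = (1 - exp(-2d)) / 2."""
    return 0.5 * (1.0 - np.exp(-2.0 * np.asarray(d_morgans, float)))


def marker_map(genome: GenomeModel, marker_spacing: int) -> pd.DataFrame:
    """Evenly spaced marker map over the genome."""
    if marker_spacing <= 0:
        raise ValidationError("marker spacing must be positive")
    rows = []
    for c, length in enumerate(genome.chrom_lengths_bp, start=1):
        pos = np.arange(marker_spacing // 2 + 1, length + 1, marker_spacing, dtype=int)
        if pos.size == 0:
            pos = np.array([max(1, length // 2)], dtype=int)
        for p in pos:
            rows.append((f"chr{c}_{p}", c, int(p), p / 1000.0 * genome.cM_per_kb))
    return pd.DataFrame(rows, columns=["id", "chrom", "pos_bp", "pos_cM"])


def simulate_cross(
    genome: GenomeModel,
    n_segregants: int,
    marker_spacing: int,
    seed: int | np.random.Generator = 0,
    markers: pd.DataFrame | None = None,
) -> GenotypeMatrix:
    """Haploid segregant genotypes along the genetic map.

    Within a chromosome the genotype sequence is a two-state Markov chain:
    the first marker is BY/RM with probability 1/2 and consecutive markers
    switch with the Haldane recombination fraction of their map distance.
    Chromosomes are independent, so the expected allele frequency is 1/2
    everywhere and markers on different chromosomes are uncorrelated.
    """
    if n_segregants < 1:
        raise ValidationError("n_segregants must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    mk = marker_map(genome, marker_spacing) if markers is None else markers.reset_index(drop=True)
    blocks = []
    for _, grp in mk.groupby("chrom", sort=True):
        cm = grp["pos_cM"].to_numpy()
        r = haldane_r(np.diff(cm) / 100.0)
        m = len(grp)
        g0 = rng.choice(np.array([-1, 1], dtype=np.int8), size=n_segregants)
        if m == 1:
            blocks.append(g0[:, None])
            continue
        switches = rng.random((n_segregants, m - 1)) < r[None, :]
        parity = np.concatenate(
            [np.zeros((n_segregants, 1), dtype=int), np.cumsum(switches, axis=1)], axis=1
        ) % 2
        blocks.append((g0[:, None] * np.where(parity == 1, -1, 1)).astype(np.int8))
    values = np.concatenate(blocks, axis=1)
    ids = [f"seg{i:04d}" for i in range(n_segregants)]
    return GenotypeMatrix(values, mk, ids)


# ---------------------------------------------------------------------------
# Trait architecture
# ---------------------------------------------------------------------------

@dataclass
class ArchitectureConfig:
    """Generator settings; defaults encode the study-like conditions."""

    n_hotspots: int = 12
    # target-count range on the full 5,643-gene universe; scaled by n_genes
    hotspot_target_range: tuple[int, int] = (26, 4594)
    full_scale_genes: int = 5643
    frac_local: float = 0.55          # slightly more than half of genes
    gene_h2_range: tuple[float, float] = (0.2, 0.8)
    cond_h2_range: tuple[float, float] = (0.4, 0.8)
    gqtl_per_condition: tuple[int, int] = (4, 10)
    frac_gqtl_at_hotspots: float = 0.8
    n_condition_archetypes: int = 2   # opposite-signed hotspot response groups
    local_weight: float = 2.0         # local eQTLs tend to be stronger
    n_batches: int = 8
    batch_sd: float = 0.3
    od_coef_sd: float = 0.2
    missing_rate: float = 0.05
    min_hotspot_sep_cM: float = 10.0


@dataclass
class TraitArchitecture:
    """Ground truth: every generative effect, covariate, and noise scale."""

    gene_ids: list[str]
    condition_ids: list[str]
    marker_ids: list[str]
    gene_pos: pd.DataFrame                          # gene_id, chrom, pos_bp
    gene_effects: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]]
    cond_effects: dict[str, tuple[np.ndarray, np.ndarray]]
    hotspot_marker_idx: np.ndarray
    hotspot_targets: dict[int, np.ndarray]          # marker idx -> gene indices
    noise_sd_gene: np.ndarray
    noise_sd_cond: np.ndarray
    gene_h2: np.ndarray
    cond_h2: np.ndarray
    batch: np.ndarray
    batch_offsets: np.ndarray
    od600: np.ndarray
    od_coef: np.ndarray
    archetype: np.ndarray
    missing_rate: float = 0.05

    def genetic_score(self, genotypes: GenotypeMatrix, trait_id: str) -> np.ndarray:
        """Sum of true marker effects times genotypes for one trait."""
        if trait_id in self.gene_effects:
            idx, eff, _ = self.gene_effects[trait_id]
        else:
            idx, eff = self.cond_effects[trait_id]
        if idx.size == 0:
            return np.zeros(genotypes.n_segregants)
        return genotypes.values[:, idx].astype(float) @ eff

    # -- truth-file round trip ------------------------------------------
    def to_frame(self) -> pd.DataFrame:
        rows: list[tuple] = []
        for g, (idx, eff, is_local) in self.gene_effects.items():
            for j, e, loc in zip(idx, eff, is_local):
                rows.append(("effect", g, self.marker_ids[j],
                             "local" if loc else "trans", float(e)))
        for c, (idx, eff) in self.cond_effects.items():
            for j, e in zip(idx, eff):
                rows.append(("effect", c, self.marker_ids[j], "gqtl", float(e)))
        for g, sd, h2 in zip(self.gene_ids, self.noise_sd_gene, self.gene_h2):
            rows.append(("noise", g, "", "noise_sd", float(sd)))
            rows.append(("noise", g, "", "h2", float(h2)))
        for c, sd, h2 in zip(self.condition_ids, self.noise_sd_cond, self.cond_h2):
            rows.append(("noise", c, "", "noise_sd", float(sd)))
            rows.append(("noise", c, "", "h2", float(h2)))
        for _, r in self.gene_pos.iterrows():
            rows.append(("gene_pos", r["gene_id"], "", "chrom", float(r["chrom"])))
            rows.append(("gene_pos", r["gene_id"], "", "pos_bp", float(r["pos_bp"])))
        for i, off in enumerate(self.batch_offsets):
            rows.append(("batch_offset", "", "", str(i), float(off)))
        for i, (b, od) in enumerate(zip(self.batch, self.od600)):
            rows.append(("segregant", str(i), "", "batch", float(b)))
            rows.append(("segregant", str(i), "", "od600", float(od)))
        for g, oc in zip(self.gene_ids, self.od_coef):
            rows.append(("od_coef", g, "", "od_coef", float(oc)))
        for c, a in zip(self.condition_ids, self.archetype):
            rows.append(("archetype", c, "", "archetype", float(a)))
        for j in self.hotspot_marker_idx:
            rows.append(("hotspot", "", self.marker_ids[j], "n_targets",
                         float(len(self.hotspot_targets[int(j)]))))
        rows.append(("param", "", "", "missing_rate", float(self.missing_rate)))
        return pd.DataFrame(
            rows, columns=["record_type", "trait_id", "marker_id", "key", "value"]
        )

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, genotypes: GenotypeMatrix) -> "TraitArchitecture":
        marker_ids = genotypes.marker_ids
        midx = {m: j for j, m in enumerate(marker_ids)}
        eff = frame[frame["record_type"] == "effect"]
        gene_effects: dict[str, tuple] = {}
        cond_effects: dict[str, tuple] = {}
        noise = frame[frame["record_type"] == "noise"]
        gene_ids = sorted({t for t in noise["trait_id"] if t.startswith("gene")})
        condition_ids = sorted({t for t in noise["trait_id"] if not t.startswith("gene")})
        for t in gene_ids:
            sub = eff[eff["trait_id"] == t]
            gene_effects[t] = (
                np.array([midx[m] for m in sub["marker_id"]], int),
                sub["value"].to_numpy(float),
                (sub["key"] == "local").to_numpy(),
            )
        for t in condition_ids:
            sub = eff[eff["trait_id"] == t]
            cond_effects[t] = (
                np.array([midx[m] for m in sub["marker_id"]], int),
                sub["value"].to_numpy(float),
            )
        def _vec(rt, ids, key):
            sub = frame[(frame["record_type"] == rt) & (frame["key"] == key)]
            lut = dict(zip(sub["trait_id"], sub["value"]))
            return np.array([lut[t] for t in ids], float)

        gene_pos = pd.DataFrame(
            {
                "gene_id": gene_ids,
                "chrom": _vec("gene_pos", gene_ids, "chrom").astype(int),
                "pos_bp": _vec("gene_pos", gene_ids, "pos_bp").astype(int),
            }
        )
        hs = frame[frame["record_type"] == "hotspot"]
        hotspot_idx = np.array([midx[m] for m in hs["marker_id"]], int)
        hotspot_targets = {}
        for j in hotspot_idx:
            mid = marker_ids[j]
            tg = eff[(eff["marker_id"] == mid) & (eff["key"] == "trans")]["trait_id"]
            hotspot_targets[int(j)] = np.array(
                [gene_ids.index(t) for t in tg if t in set(gene_ids)], int
            )
        seg = frame[frame["record_type"] == "segregant"]
        n_seg = seg["trait_id"].astype(int).max() + 1 if len(seg) else genotypes.n_segregants
        batch = np.zeros(n_seg, int)
        od = np.zeros(n_seg)
        for _, r in seg.iterrows():
            i = int(r["trait_id"])
            if r["key"] == "batch":
                batch[i] = int(r["value"])
            else:
                od[i] = r["value"]
        off = frame[frame["record_type"] == "batch_offset"].sort_values(
            "key", key=lambda s: s.astype(int)
        )["value"].to_numpy(float)
        mr = float(frame[(frame["record_type"] == "param") &
                         (frame["key"] == "missing_rate")]["value"].iloc[0])
        return cls(
            gene_ids, condition_ids, marker_ids, gene_pos, gene_effects, cond_effects,
            hotspot_idx, hotspot_targets,
            _vec("noise", gene_ids, "noise_sd"), _vec("noise", condition_ids, "noise_sd"),
            _vec("noise", gene_ids, "h2"), _vec("noise", condition_ids, "h2"),
            batch, off, od, _vec("od_coef", gene_ids, "od_coef"),
            _vec("archetype", condition_ids, "archetype").astype(int), mr,
        )


def _pick_hotspot_markers(
    markers: pd.DataFrame, n_hotspots: int, min_sep_cM: float, rng: np.random.Generator
) -> np.ndarray:
    """Random hotspot peak markers with a minimum map separation."""
    order = rng.permutation(len(markers))
    chosen: list[int] = []
    for j in order:
        ok = all(
            markers["chrom"].iloc[j] != markers["chrom"].iloc[k]
            or abs(markers["pos_cM"].iloc[j] - markers["pos_cM"].iloc[k]) >= min_sep_cM
            for k in chosen
        )
        if ok:
            chosen.append(int(j))
        if len(chosen) == n_hotspots:
            return np.array(sorted(chosen), int)
    raise ValidationError("could not place hotspots with the requested separation")


def _scaled_effects(
    G: np.ndarray, idx: np.ndarray, raw: np.ndarray, h2: float
) -> np.ndarray:
    """Rescale raw effects so the realized genetic-score variance equals h2."""
    score = G[:, idx] @ raw
    v = score.var()
    if v <= 0:
        raise ValidationError("degenerate genetic score")
    if h2 >= 1:
        raise ValidationError("requested genetic variance must be < 1 after standardization")
    return raw * np.sqrt(h2 / v)


def build_architecture(
    genotypes: GenotypeMatrix,
    n_genes: int,
    n_conditions: int,
    config: ArchitectureConfig | None = None,
    seed: int | np.random.Generator = 0,
) -> TraitArchitecture:
    """Draw hotspots, local eQTLs, growth QTLs, covariates, and noise scales.

    Hotspot target counts are log-uniform over the configured range scaled
    to the simulated gene count (heavy-tailed, like the 26..4,594 spread of
    affected genes per hotspot at full scale). A ``frac_local`` fraction of
    genes get a local eQTL at the marker nearest the gene. Each condition
    receives a stated number of gQTL-effect markers, a stated fraction of
    them at hotspot peak markers, with hotspot-effect signs following the
    condition's archetype so that condition groups with opposite
    transcriptome responses exist by construction.
    """
    cfg = config or ArchitectureConfig()
    if n_genes < 1 or n_conditions < 1:
        raise ValidationError("n_genes and n_conditions must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    G = genotypes.values.astype(float)
    mk = genotypes.markers
    gene_ids = [f"gene{i:04d}" for i in range(n_genes)]
    condition_ids = [f"cond{i:02d}" for i in range(n_conditions)]

    # gene positions: chromosome proportional to length, position uniform
    chrom_lengths = mk.groupby("chrom")["pos_bp"].max().to_dict()
    chroms = np.array(sorted(chrom_lengths))
    wts = np.array([chrom_lengths[c] for c in chroms], float)
    g_chrom = rng.choice(chroms, size=n_genes, p=wts / wts.sum())
    g_pos = np.array(
        [rng.integers(1, chrom_lengths[c] + 1) for c in g_chrom], int
    )
    gene_pos = pd.DataFrame({"gene_id": gene_ids, "chrom": g_chrom, "pos_bp": g_pos})

    # hotspots and their target genes
    if cfg.n_hotspots > 0:
        hotspot_idx = _pick_hotspot_markers(mk, cfg.n_hotspots, cfg.min_hotspot_sep_cM, rng)
    else:
        hotspot_idx = np.array([], int)
    scale = n_genes / cfg.full_scale_genes
    lo = max(2, int(round(cfg.hotspot_target_range[0] * scale)))
    hi = max(lo + 1, min(n_genes, int(round(cfg.hotspot_target_range[1] * scale))))
    hotspot_targets: dict[int, np.ndarray] = {}
    for j in hotspot_idx:
        count = int(round(np.exp(rng.uniform(np.log(lo), np.log(hi)))))
        count = int(np.clip(count, 1, n_genes))
        hotspot_targets[int(j)] = np.sort(rng.choice(n_genes, size=count, replace=False))

    # local eQTLs at the marker nearest the gene
    has_local = rng.random(n_genes) < cfg.frac_local
    local_marker = np.full(n_genes, -1, int)
    for i in np.nonzero(has_local)[0]:
        on = np.nonzero((mk["chrom"] == g_chrom[i]).to_numpy())[0]
        local_marker[i] = on[np.abs(mk["pos_bp"].to_numpy()[on] - g_pos[i]).argmin()]

    # per-gene effect vectors on the standardized scale
    gene_effects: dict[str, tuple] = {}
    noise_sd_gene = np.ones(n_genes)
    gene_h2 = np.zeros(n_genes)
    trans_of_gene: dict[int, list[tuple[int, float]]] = {i: [] for i in range(n_genes)}
    for j, targets in hotspot_targets.items():
        for i in targets:
            trans_of_gene[i].append((j, 0.0))
    for i in range(n_genes):
        loci = [int(local_marker[i])] if has_local[i] else []
        is_local = [True] * len(loci)
        for j, _ in trans_of_gene[i]:
            loci.append(int(j))
            is_local.append(False)
        if not loci:
            gene_effects[gene_ids[i]] = (np.array([], int), np.array([]), np.array([], bool))
            continue
        idx = np.array(loci, int)
        w = rng.uniform(0.5, 1.5, idx.size)
        w[np.array(is_local)] *= cfg.local_weight
        signs = rng.choice([-1.0, 1.0], size=idx.size)
        h2 = rng.uniform(*cfg.gene_h2_range)
        raw = signs * np.sqrt(h2 * w / w.sum())
        eff = _scaled_effects(G, idx, raw, h2)
        gene_effects[gene_ids[i]] = (idx, eff, np.array(is_local, bool))
        noise_sd_gene[i] = np.sqrt(1.0 - h2)
        gene_h2[i] = h2

    # archetype sign patterns over hotspots
    n_arch = max(1, cfg.n_condition_archetypes)
    base = rng.choice([-1.0, 1.0], size=max(len(hotspot_idx), 1))
    arch_signs = []
    for a in range(n_arch):
        if a == 0:
            arch_signs.append(base.copy())
        elif a == 1:
            arch_signs.append(-base)
        else:
            arch_signs.append(rng.choice([-1.0, 1.0], size=max(len(hotspot_idx), 1)))
    archetype = np.array([i % n_arch for i in range(n_conditions)], int)

    # per-condition gQTL effects, mostly at hotspot markers
    cond_effects: dict[str, tuple] = {}
    noise_sd_cond = np.ones(n_conditions)
    cond_h2 = np.zeros(n_conditions)
    non_hot = np.setdiff1d(np.arange(genotypes.n_markers), hotspot_idx)
    hot_pos = {int(j): k for k, j in enumerate(hotspot_idx)}
    for c in range(n_conditions):
        n_q = int(rng.integers(cfg.gqtl_per_condition[0], cfg.gqtl_per_condition[1] + 1))
        n_hot = min(int(round(cfg.frac_gqtl_at_hotspots * n_q)), len(hotspot_idx))
        n_other = n_q - n_hot
        # hotspots affecting more genes are more likely to carry growth
        # effects (breadth of transcriptome effect tracks trait relevance)
        if n_hot:
            wts_h = np.array([len(hotspot_targets[int(j)]) for j in hotspot_idx], float)
            picks_h = rng.choice(hotspot_idx, size=n_hot, replace=False, p=wts_h / wts_h.sum())
        else:
            picks_h = np.array([], int)
        picks_o = (
            rng.choice(non_hot, size=min(n_other, non_hot.size), replace=False)
            if n_other else np.array([], int)
        )
        idx = np.concatenate([picks_h, picks_o]).astype(int)
        if idx.size == 0:
            cond_effects[condition_ids[c]] = (idx, np.array([]))
            continue
        w = rng.uniform(0.5, 1.5, idx.size)
        signs = np.empty(idx.size)
        s_arch = arch_signs[archetype[c]]
        for k, j in enumerate(idx):
            signs[k] = s_arch[hot_pos[int(j)]] if int(j) in hot_pos else rng.choice([-1.0, 1.0])
        h2 = rng.uniform(*cfg.cond_h2_range)
        raw = signs * np.sqrt(h2 * w / w.sum())
        eff = _scaled_effects(G, idx, raw, h2)
        cond_effects[condition_ids[c]] = (idx, eff)
        noise_sd_cond[c] = np.sqrt(1.0 - h2)
        cond_h2[c] = h2

    batch = rng.integers(0, cfg.n_batches, size=genotypes.n_segregants)
    batch_offsets = rng.normal(0.0, cfg.batch_sd, size=cfg.n_batches)
    od600 = rng.normal(0.4, 0.05, size=genotypes.n_segregants)
    od_coef = rng.normal(0.0, cfg.od_coef_sd, size=n_genes)

    return TraitArchitecture(
        gene_ids, condition_ids, genotypes.marker_ids, gene_pos, gene_effects,
        cond_effects, hotspot_idx, hotspot_targets, noise_sd_gene, noise_sd_cond,
        gene_h2, cond_h2, batch, batch_offsets, od600, od_coef, archetype,
        cfg.missing_rate,
    )


def generate_phenotypes(
    genotypes: GenotypeMatrix,
    arch: TraitArchitecture,
    seed: int | np.random.Generator = 0,
) -> tuple[PhenotypeMatrix, PhenotypeMatrix]:
    """Expression and growth matrices from an architecture.

    Expression: genetic score + batch offset + OD600 effect + noise.
    Growth: genetic score + independent noise, with missing values injected
    at the architecture's rate. Identical seeds reproduce the phenotypes
    exactly.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n = genotypes.n_segregants
    od_c = arch.od600 - arch.od600.mean()
    E = np.empty((n, len(arch.gene_ids)))
    for j, g in enumerate(arch.gene_ids):
        E[:, j] = (
            arch.genetic_score(genotypes, g)
            + arch.batch_offsets[arch.batch]
            + arch.od_coef[j] * od_c
            + rng.normal(0.0, arch.noise_sd_gene[j], size=n)
        )
    Gm = np.empty((n, len(arch.condition_ids)))
    for j, c in enumerate(arch.condition_ids):
        Gm[:, j] = arch.genetic_score(genotypes, c) + rng.normal(
            0.0, arch.noise_sd_cond[j], size=n
        )
    if arch.missing_rate > 0:
        miss = rng.random(Gm.shape) < arch.missing_rate
        Gm[miss] = np.nan
    cov = pd.DataFrame({"batch": arch.batch.astype(int), "od600": arch.od600})
    expr = PhenotypeMatrix(E, arch.gene_ids, genotypes.segregant_ids, cov, "expression")
    growth = PhenotypeMatrix(Gm, arch.condition_ids, genotypes.segregant_ids, None, "growth")
    return expr.validate(), growth.validate()


# ---------------------------------------------------------------------------
# Truth-derived QTL tables (the analogues of the published QTL catalogs)
# ---------------------------------------------------------------------------

def _corr_all(values: np.ndarray, G: np.ndarray) -> np.ndarray:
    """(markers x traits) correlations; traits complete."""
    V = values - values.mean(axis=0)
    Gc = G - G.mean(axis=0)
    num = Gc.T @ V
    den = np.sqrt((Gc**2).sum(axis=0))[:, None] * np.sqrt((V**2).sum(axis=0))[None, :]
    with np.errstate(divide="ignore", invalid="ignore"):
        return np.where(den > 0, num / den, 0.0)


def truth_qtl_tables(
    genotypes: GenotypeMatrix,
    expr: PhenotypeMatrix,
    growth: PhenotypeMatrix,
    arch: TraitArchitecture,
    min_lod: float = 2.5,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """eQTL, gQTL, and hotspot tables built from the generative truth.

    Peak markers are the true causal markers; realized correlations give
    signed effects and LOD scores, and confidence intervals come from the
    1.5-LOD-drop rule on the single-marker LOD curve. Like the published
    catalogs, the tables list detected QTLs only: causal markers whose
    realized LOD falls below ``min_lod`` are omitted (undetected effects
    with unbounded support intervals are not reportable QTLs). Hotspot
    positions are kept regardless, since hotspots are located from the
    joint evidence of many genes.
    """
    G = genotypes.values.astype(float)
    mk = genotypes.markers
    n = genotypes.n_segregants
    R_expr = _corr_all(expr.values, G)

    def qtl_rows(trait_id, idx, rcurve, lodcurve, classes):
        rows = []
        for j, cls in zip(idx, classes):
            ci = lod_drop_interval(lodcurve, mk, int(j))
            rows.append(
                {
                    "trait_id": trait_id,
                    "peak_marker_id": mk["id"].iloc[j],
                    "chrom": int(mk["chrom"].iloc[j]),
                    "peak_pos_bp": int(mk["pos_bp"].iloc[j]),
                    "ci_start_bp": ci[0],
                    "ci_end_bp": ci[1],
                    "lod": float(lodcurve[j]),
                    "effect_r": float(np.clip(rcurve[j], -1, 1)),
                    "qtl_class": cls,
                }
            )
        return rows

    e_rows = []
    for gi, gene in enumerate(arch.gene_ids):
        idx, _, is_local = arch.gene_effects[gene]
        if idx.size == 0:
            continue
        rcurve = R_expr[:, gi]
        lodcurve = lod_from_r(rcurve, n)
        classes = ["local-eQTL" if loc else "trans-eQTL" for loc in is_local]
        e_rows += qtl_rows(gene, idx, rcurve, lodcurve, classes)
    g_rows = []
    for ci_, cond in enumerate(arch.condition_ids):
        idx, _ = arch.cond_effects[cond]
        if idx.size == 0:
            continue
        y = growth.values[:, ci_]
        ok = ~np.isnan(y)
        rcurve = _corr_all(y[ok][:, None], G[ok])[:, 0]
        lodcurve = lod_from_r(rcurve, int(ok.sum()))
        g_rows += qtl_rows(cond, idx, rcurve, lodcurve, ["gQTL"] * idx.size)
    eqtl = pd.DataFrame(e_rows)
    gqtl = pd.DataFrame(g_rows)
    eqtl = eqtl[eqtl["lod"] >= min_lod].reset_index(drop=True)
    gqtl = gqtl[gqtl["lod"] >= min_lod].reset_index(drop=True)

    h_rows = []
    for j in arch.hotspot_marker_idx:
        targets = arch.hotspot_targets[int(j)]
        sub = eqtl[(eqtl["peak_marker_id"] == mk["id"].iloc[j])
                   & (eqtl["qtl_class"] == "trans-eQTL")]
        lod = float(sub["lod"].median()) if len(sub) else 0.0
        ci_lo = max(1, int(mk["pos_bp"].iloc[j]) - 10_000)
        chrom = int(mk["chrom"].iloc[j])
        chrom_len = int(mk.loc[mk["chrom"] == chrom, "pos_bp"].max())
        ci_hi = min(chrom_len, int(mk["pos_bp"].iloc[j]) + 10_000)
        h_rows.append(
            {
                "trait_id": "hotspot",
                "peak_marker_id": mk["id"].iloc[j],
                "chrom": chrom,
                "peak_pos_bp": int(mk["pos_bp"].iloc[j]),
                "ci_start_bp": ci_lo,
                "ci_end_bp": max(ci_hi, int(mk["pos_bp"].iloc[j])),
                "lod": lod,
                "effect_r": 0.0,
                "qtl_class": "hotspot",
                "n_target_genes": len(targets),
            }
        )
    hotspot = pd.DataFrame(h_rows).sort_values(
        "n_target_genes", ascending=False
    ).reset_index(drop=True)
    return eqtl, gqtl, hotspot


def gene_set_fixtures(arch: TraitArchitecture) -> dict[str, set[str]]:
    """Synthetic gene sets with planted structure (GMT-style fixtures).

    One set per hotspot (its target genes) plus growth-signature analogues
    from the largest hotspot: genes it up-regulates, genes it
    down-regulates, and untargeted genes.
    """
    sets: dict[str, set[str]] = {}
    for j in arch.hotspot_marker_idx:
        mid = arch.marker_ids[j]
        sets[f"targets_{mid}"] = {arch.gene_ids[i] for i in arch.hotspot_targets[int(j)]}
    if len(arch.hotspot_marker_idx):
        sizes = {int(j): len(arch.hotspot_targets[int(j)]) for j in arch.hotspot_marker_idx}
        top = max(sizes, key=sizes.get)
        up, down = set(), set()
        for i in arch.hotspot_targets[top]:
            g = arch.gene_ids[i]
            idx, eff, _ = arch.gene_effects[g]
            k = np.nonzero(idx == top)[0]
            if k.size and eff[k[0]] > 0:
                up.add(g)
            elif k.size:
                down.add(g)
        sets["signature_up"] = up
        sets["signature_down"] = down
        sets["signature_unresponsive"] = set(arch.gene_ids) - up - down
    return sets
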