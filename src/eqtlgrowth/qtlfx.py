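"""Per-marker QTL effects and weighted QTL-effect correlations.

A gene with several detected eQTLs provides genetically independent
observations of how changing its expression changes growth: at each eQTL
peak marker the allele effect on expression and on growth is a Pearson
correlation, and the agreement between the two effect profiles is a
weighted Pearson correlation, with weights equal to the inverse product of
the 95% confidence-interval widths of the two effects (precise effects
count more). A minimal single-marker LOD scan is included as plumbing for
simulated QTL tables and colocalization eligibility.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .datatypes import GenotypeMatrix, PhenotypeMatrix, ValidationError
from .gencor import pearson_p

CI_WIDTH_FLOOR = 1e-6  # |r| = 1 has an infinite Fisher z; keep weights finite


def marker_effect(trait: np.ndarray, genotype: np.ndarray) -> tuple[float, float]:
    """Pearson effect of a marker on a trait with its 95% CI width.

    The confidence interval uses the Fisher z-transform
    (z +/- 1.96 / sqrt(n - 3), mapped back with tanh); the returned width is
    upper minus lower on the r scale, floored at ``1e-6`` so degenerate
    |r| = 1 effects keep finite inverse-CI weights.
    """
    t = np.asarray(trait, float)
    g = np.asarray(genotype, float)
    ok = ~np.isnan(t) & ~np.isnan(g)
    n = int(ok.sum())
    if n < 4:
        raise ValidationError(f"need >= 4 complete observations, got {n}")
    t, g = t[ok], g[ok]
    if t.std() == 0 or g.std() == 0:
        raise ValidationError("constant trait or genotype vector")
    r = float(np.clip(np.corrcoef(t, g)[0, 1], -1, 1))
    if abs(r) >= 1.0:
        return r, CI_WIDTH_FLOOR
    z = np.arctanh(r)
    se = 1.0 / np.sqrt(n - 3)
    width = float(np.tanh(z + 1.959963984540054 * se) - np.tanh(z - 1.959963984540054 * se))
    return r, max(width, CI_WIDTH_FLOOR)


def weighted_correlation(
    x: np.ndarray, y: np.ndarray, w: np.ndarray
) -> tuple[float, float]:
    """Weighted Pearson correlation and its two-sided p-value.

    Uses weighted means and covariances; the p-value comes from the
    t-statistic with ``len(x) - 2`` degrees of freedom (the number of loci,
    not the effective sample size).
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    w = np.asarray(w, float)
    if not (len(x) == len(y) == len(w)):
        raise ValidationError("x, y, w must have equal length")
    if len(x) < 3:
        raise ValidationError("need at least 3 loci")
    if np.any(w < 0) or w.sum() == 0:
        raise ValidationError("weights must be non-negative with positive sum")
    wn = w / w.sum()
    mx = float(wn @ x)
    my = float(wn @ y)
    cov = float(wn @ ((x - mx) * (y - my)))
    vx = float(wn @ (x - mx) ** 2)
    vy = float(wn @ (y - my) ** 2)
    if vx == 0 or vy == 0:
        return np.nan, np.nan
    r = float(np.clip(cov / np.sqrt(vx * vy), -1, 1))
    p = float(pearson_p(np.array(r), len(x)))
    return r, p


def qtl_effect_correlations(
    expr: PhenotypeMatrix,
    growth: PhenotypeMatrix,
    genotypes: GenotypeMatrix,
    eqtl_table: pd.DataFrame,
    min_eqtls: int = 3,
    fdr: float = 0.20,
) -> pd.DataFrame:
    """Weighted QTL-effect correlation for every eligible gene x condition.

    Genes need at least ``min_eqtls`` detected eQTL peak markers. Effects on
    expression and growth are computed on the shared segregant panel
    (pairwise-complete for growth); each pair's weight is
    ``1 / (ci_width_expression * ci_width_growth)``. FDR across all tested
    pairs is Benjamini-Hochberg.
    """
    peaks_by_gene = {
        g: list(grp["peak_marker_id"]) for g, grp in eqtl_table.groupby("trait_id")
    }
    rows = []
    skipped = []
    for gene in expr.trait_ids:
        peaks = peaks_by_gene.get(gene, [])
        if len(peaks) < min_eqtls:
            skipped.append(gene)
            continue
        idx = genotypes.marker_indices(peaks)
        evec = expr.column(gene)
        e_eff = np.empty(len(idx))
        e_w = np.empty(len(idx))
        for k, j in enumerate(idx):
            e_eff[k], e_w[k] = marker_effect(evec, genotypes.values[:, j])
        for cond in growth.trait_ids:
            gv = growth.column(cond)
            g_eff = np.empty(len(idx))
            g_w = np.empty(len(idx))
            try:
                for k, j in enumerate(idx):
                    g_eff[k], g_w[k] = marker_effect(gv, genotypes.values[:, j])
            except ValidationError:
                continue
            r_w, p = weighted_correlation(e_eff, g_eff, 1.0 / (e_w * g_w))
            rows.append(
                {
                    "gene_id": gene,
                    "condition_id": cond,
                    "n_eqtls": len(idx),
                    "r_weighted": r_w,
                    "p": p,
                }
            )
    table = pd.DataFrame(rows, columns=["gene_id", "condition_id", "n_eqtls", "r_weighted", "p"])
    if len(table):
        ok = table["p"].notna()
        table["q"] = np.nan
        if ok.any():
            table.loc[ok, "q"] = multipletests(table.loc[ok, "p"], method="fdr_bh")[1]
        table["sig"] = table["q"] <= fdr
    table.attrs["skipped_genes"] = skipped
    return table


# ---------------------------------------------------------------------------
# Minimal LOD scan (plumbing; QTL discovery proper is an input, not a goal)
# ---------------------------------------------------------------------------

def lod_from_r(r: np.ndarray, n: int) -> np.ndarray:
    """LOD = -(n/2) * log10(1 - r^2)."""
    r2 = np.clip(np.asarray(r, float) ** 2, 0, 1 - 1e-15)
    return -(n / 2.0) * np.log10(1.0 - r2)


@dataclass
class LodScan:
    lod: np.ndarray
    peak_index: int
    peak_marker_id: str
    ci_start_bp: int
    ci_end_bp: int
    n: int
    threshold: float | None = None


def lod_drop_interval(
    lod: np.ndarray, markers: pd.DataFrame, peak: int, drop: float = 1.5
) -> tuple[int, int]:
    """1.5-LOD-drop support interval around a peak, within its chromosome."""
    chrom = markers["chrom"].iloc[peak]
    on_chr = np.nonzero((markers["chrom"] == chrom).to_numpy())[0]
    lo = hi = peak
    cut = lod[peak] - drop
    left = on_chr[on_chr < peak][::-1]
    for j in left:
        if lod[j] < cut:
            break
        lo = j
    right = on_chr[on_chr > peak]
    for j in right:
        if lod[j] < cut:
            break
        hi = j
    return int(markers["pos_bp"].iloc[lo]), int(markers["pos_bp"].iloc[hi])


def lod_scan(
    trait: np.ndarray,
    genotypes: GenotypeMatrix,
    n_perm: int = 0,
    seed: int = 0,
    drop: float = 1.5,
) -> LodScan:
    """Single-marker LOD curve, peak, and 1.5-LOD-drop interval.

    An optional trait-permutation threshold (95th percentile of the
    genome-wide maximum LOD under permutation) assesses significance.
    """
    t = np.asarray(trait, float)
    ok = ~np.isnan(t)
    n = int(ok.sum())
    if n < 10:
        raise ValidationError(f"need >= 10 complete observations, got {n}")
    G = genotypes.values[ok].astype(float)
    tv = t[ok]
    Gc = G - G.mean(axis=0)
    tc = tv - tv.mean()
    den = np.sqrt((Gc**2).sum(axis=0) * (tc**2).sum())
    with np.errstate(divide="ignore", invalid="ignore"):
        r = np.where(den > 0, Gc.T @ tc / den, 0.0)
    lod = lod_from_r(r, n)
    peak = int(np.argmax(lod))
    ci = lod_drop_interval(lod, genotypes.markers, peak, drop)
    thr = None
    if n_perm > 0:
        rng = np.random.default_rng(seed)
        maxima = np.empty(n_perm)
        norm_g = np.sqrt((Gc**2).sum(axis=0))
        for b in range(n_perm):
            tp = tc[rng.permutation(n)]
            rp = Gc.T @ tp / (norm_g * np.sqrt((tp**2).sum()))
            maxima[b] = lod_from_r(rp, n).max()
        thr = float(np.quantile(maxima, 0.95))
    return LodScan(lod, peak, genotypes.markers["id"].iloc[peak], ci[0], ci[1], n, thr)
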