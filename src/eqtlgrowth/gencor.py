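"""Genetic correlations between gene expression and growth.

Because expression and growth were measured in independent experiments on
the same genotypes, a plain Pearson correlation across segregants estimates
the genetically driven association between a gene's expression and growth
in a condition. Significance comes from the t-transform of r; the false
discovery rate is estimated with Storey q-values (pi0 from the smoother).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import PhenotypeMatrix, ValidationError


def pearson_p(r: np.ndarray, n: np.ndarray | int) -> np.ndarray:
    """Two-sided p-value of Pearson r via the t-transform with n-2 df."""
    r = np.asarray(r, float)
    n = np.broadcast_to(np.asarray(n), r.shape).astype(float)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt((n - 2) / np.clip(1 - r**2, 1e-300, None))
    p = 2 * stats.t.sf(np.abs(t), np.clip(n - 2, 1, None))
    return np.where(n >= 3, p, np.nan)


def _corr_matrix_vs_vector(E: np.ndarray, x: np.ndarray) -> np.ndarray:
    """Pearson r of every column of E against x (no missing values)."""
    Ec = E - E.mean(axis=0)
    xc = x - x.mean()
    num = Ec.T @ xc
    den = np.sqrt((Ec**2).sum(axis=0) * (xc**2).sum())
    with np.errstate(divide="ignore", invalid="ignore"):
        return np.clip(np.where(den > 0, num / den, np.nan), -1, 1)


def qvalues(pvals: np.ndarray, pi0: float | None = None) -> np.ndarray:
    """Storey q-values.

    pi0 (the proportion of true nulls) is estimated by evaluating
    pi0(lambda) = #{p > lambda} / (m (1 - lambda)) over
    lambda in {0, 0.05, ..., 0.95} and extrapolating a cubic least-squares
    fit to the largest lambda. Pass ``pi0=1`` for Benjamini-Hochberg
    behaviour.
    """
    p = np.asarray(pvals, float)
    if p.size == 0:
        return p.copy()
    ok = ~np.isnan(p)
    q = np.full_like(p, np.nan)
    pv = p[ok]
    if pv.size == 0:
        return q
    if np.nanmin(pv) < 0 or np.nanmax(pv) > 1:
        raise ValidationError("p-values must lie in [0, 1]")
    m = pv.size
    if pi0 is None:
        lams = np.arange(0.0, 0.96, 0.05)
        pi0_lam = np.array([(pv > lam).mean() / (1 - lam) for lam in lams])
        if m < 100 or pi0_lam.min() == 0:
            pi0_hat = 1.0
        else:
            coef = np.polyfit(lams, pi0_lam, 3)
            pi0_hat = float(np.polyval(coef, lams.max()))
        pi0 = float(np.clip(pi0_hat, 1.0 / m, 1.0))
    order = np.argsort(pv, kind="mergesort")
    ranked = pv[order]
    qv = pi0 * ranked * m / np.arange(1, m + 1)
    qv = np.minimum.accumulate(qv[::-1])[::-1]
    qv = np.clip(qv, 0, 1)
    out = np.empty(m)
    out[order] = qv
    q[ok] = out
    return q


def genetic_correlations(
    expr: PhenotypeMatrix,
    growth: PhenotypeMatrix,
    fdr: float = 0.05,
    fdr_family: str = "per-condition",
    min_pairs: int = 3,
) -> pd.DataFrame:
    """One record per gene x condition: r, n_pairs, p, q, sig.

    Growth missing values are handled pairwise-complete. ``fdr_family``
    controls the q-value test family: ``"per-condition"`` (the default;
    significant-gene counts are reported per condition) or ``"global"``.
    """
    if expr.segregant_ids != growth.segregant_ids:
        raise ValidationError("expression and growth must share segregant order")
    if fdr_family not in ("per-condition", "global"):
        raise ValidationError("fdr_family must be 'per-condition' or 'global'")
    frames = []
    for c, cond in enumerate(growth.trait_ids):
        y = growth.values[:, c]
        mask = ~np.isnan(y)
        n = int(mask.sum())
        if n >= min_pairs:
            r = _corr_matrix_vs_vector(expr.values[mask], y[mask])
            p = pearson_p(r, n)
        else:
            r = np.full(expr.n_traits, np.nan)
            p = np.full(expr.n_traits, np.nan)
        frames.append(
            pd.DataFrame(
                {
                    "gene_id": expr.trait_ids,
                    "condition_id": cond,
                    "r": r,
                    "n_pairs": n,
                    "p": p,
                    "low_n": n < min_pairs,
                }
            )
        )
    table = pd.concat(frames, ignore_index=True)
    if fdr_family == "global":
        table["q"] = qvalues(table["p"].to_numpy())
    else:
        table["q"] = np.nan
        for cond, idx in table.groupby("condition_id").groups.items():
            table.loc[idx, "q"] = qvalues(table.loc[idx, "p"].to_numpy())
    table["sig"] = table["q"] <= fdr
    return table


def significant_summary(table: pd.DataFrame, fdr: float = 0.05) -> pd.DataFrame:
    """Per-condition count and median |r| of significant correlations."""
    rows = []
    for cond, grp in table.groupby("condition_id"):
        sig = grp[grp["q"] <= fdr]
        rows.append(
            {
                "condition_id": cond,
                "n_sig": len(sig),
                "median_abs_r": float(sig["r"].abs().median()) if len(sig) else np.nan,
            }
        )
    return pd.DataFrame(rows)


def downsample_analysis(
    expr: PhenotypeMatrix,
    growth: PhenotypeMatrix,
    sizes: tuple[int, ...],
    reps: int,
    seed: int,
    fdr: float = 0.05,
) -> pd.DataFrame:
    """Recompute genetic correlations on random segregant subsets.

    For each panel size and repetition (sampling without replacement) the
    per-condition number and median magnitude of significant correlations
    is recorded; the summary reports the median over repetitions.
    """
    n = expr.n_segregants
    for s in sizes:
        if s > n:
            raise ValidationError(f"subsample size {s} exceeds panel size {n}")
    rng = np.random.default_rng(seed)
    rows = []
    for size in sizes:
        for rep in range(reps):
            keep = np.sort(rng.choice(n, size=size, replace=False))
            ids = [expr.segregant_ids[i] for i in keep]
            sub = genetic_correlations(
                expr.subset_segregants(ids), growth.subset_segregants(ids), fdr=fdr
            )
            summ = significant_summary(sub, fdr)
            summ["size"] = size
            summ["rep"] = rep
            rows.append(summ)
    detail = pd.concat(rows, ignore_index=True)
    med = (
        detail.groupby(["size", "condition_id"])
        .agg(median_n_sig=("n_sig", "median"), median_abs_r=("median_abs_r", "median"))
        .reset_index()
    )
    med.attrs["detail"] = detail
    return med
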