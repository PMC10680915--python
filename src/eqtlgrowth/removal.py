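"""Effect removal: which marker sets carry the genetic correlations?

For gene/condition pairs with a significant genetic correlation, the
effects of a chosen marker set (the gene's local eQTL, its trans-eQTLs, or
all trans-eQTL hotspot markers) are regressed out of BOTH the expression
and growth vectors, and the correlation recomputed on the residuals. Large
drops in |r| identify the removed loci as drivers. Paired Wilcoxon
signed-rank tests compare |r| before vs after per set, and size-matched
random marker sets give the drop expected from linkage alone.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import linalg, stats

from .datatypes import GenotypeMatrix, PhenotypeMatrix, ValidationError
from .gencor import pearson_p


def _independent_columns(X: np.ndarray, tol: float = 1e-8) -> np.ndarray:
    """Indices of a maximal linearly independent column subset (pivoted QR)."""
    if X.shape[1] == 0:
        return np.array([], dtype=int)
    _, R, piv = linalg.qr(X, mode="economic", pivoting=True)
    d = np.abs(np.diag(R))
    rank = int((d > tol * d[0]).sum()) if d.size and d[0] > 0 else 0
    return np.sort(piv[:rank])


def regress_out_markers(
    pheno: np.ndarray, genotype_columns: np.ndarray
) -> np.ndarray:
    """OLS residuals of a phenotype on a set of marker genotypes jointly.

    Includes an intercept; collinear genotype columns are deduplicated by
    rank detection before the fit. Missing phenotype entries stay missing.
    An empty marker set returns the phenotype unchanged.
    """
    y = np.asarray(pheno, float)
    Gm = np.atleast_2d(np.asarray(genotype_columns, float))
    if Gm.shape[0] != y.shape[0]:
        Gm = Gm.T
    if Gm.shape[1] == 0:
        return y.copy()
    ok = ~np.isnan(y)
    keep = _independent_columns(Gm[ok] - Gm[ok].mean(axis=0))
    Gm = Gm[:, keep]
    n_obs = int(ok.sum())
    if Gm.shape[1] >= n_obs - 1:
        raise ValidationError(
            f"{Gm.shape[1]} markers with only {n_obs} observations; "
            "joint OLS removal is not defined (regularized removal is out of scope)"
        )
    X = np.column_stack([np.ones(n_obs), Gm[ok]])
    beta, *_ = np.linalg.lstsq(X, y[ok], rcond=None)
    out = np.full_like(y, np.nan)
    out[ok] = y[ok] - X @ beta
    return out


def _pair_r(e: np.ndarray, g: np.ndarray) -> float:
    ok = ~np.isnan(e) & ~np.isnan(g)
    if ok.sum() < 3 or e[ok].std() == 0 or g[ok].std() == 0:
        return np.nan
    return float(np.corrcoef(e[ok], g[ok])[0, 1])


def removal_comparison(
    expr: PhenotypeMatrix,
    growth: PhenotypeMatrix,
    genotypes: GenotypeMatrix,
    eqtl_table: pd.DataFrame,
    hotspot_table: pd.DataFrame,
    gencor_table: pd.DataFrame,
    fdr: float = 0.05,
    n_random_sets: int = 0,
    seed: int = 0,
) -> pd.DataFrame:
    """Before/after genetic correlations under three marker-set removals.

    Eligible pairs have a genetic correlation significant at ``fdr`` and a
    gene with at least one local eQTL and one trans-eQTL. Sets removed per
    pair: the gene's local eQTL marker(s), the gene's trans-eQTL markers,
    and all hotspot peak markers (removed from every pair). With
    ``n_random_sets > 0``, size-matched random marker sets estimate the
    chance drop per set kind.
    """
    G = genotypes.values.astype(float)
    n_mark = genotypes.n_markers
    local = {
        g: genotypes.marker_indices(grp["peak_marker_id"])
        for g, grp in eqtl_table[eqtl_table["qtl_class"] == "local-eQTL"].groupby("trait_id")
    }
    trans = {
        g: genotypes.marker_indices(grp["peak_marker_id"])
        for g, grp in eqtl_table[eqtl_table["qtl_class"] == "trans-eQTL"].groupby("trait_id")
    }
    hot_idx = genotypes.marker_indices(hotspot_table["peak_marker_id"])
    sig = gencor_table[(gencor_table["q"] <= fdr) & gencor_table["r"].notna()]
    eligible = sig[sig["gene_id"].isin(set(local) & set(trans))]
    if not len(eligible):
        return pd.DataFrame(
            columns=["gene_id", "condition_id", "set_name", "r_before", "r_after", "pct_drop"]
        )
    # All-hotspot removal shares one projection across every pair.
    expr_hot = np.column_stack(
        [regress_out_markers(expr.values[:, j], G[:, hot_idx])
         for j in range(expr.n_traits)]
    )
    growth_hot = np.column_stack(
        [regress_out_markers(growth.values[:, c], G[:, hot_idx])
         for c in range(growth.n_traits)]
    )
    rng = np.random.default_rng(seed)
    rows = []
    for gene, grp in eligible.groupby("gene_id"):
        gi = expr.trait_ids.index(gene)
        evec = expr.values[:, gi]
        sets = {
            "local": local[gene],
            "trans": trans[gene],
            "hotspots": hot_idx,
        }
        resid_e = {
            "local": regress_out_markers(evec, G[:, sets["local"]]),
            "trans": regress_out_markers(evec, G[:, sets["trans"]]),
            "hotspots": expr_hot[:, gi],
        }
        for _, rec in grp.iterrows():
            cond = rec["condition_id"]
            ci = growth.trait_ids.index(cond)
            gvec = growth.values[:, ci]
            r_before = _pair_r(evec, gvec)
            for set_name, idx in sets.items():
                if set_name == "hotspots":
                    r_after = _pair_r(resid_e[set_name], growth_hot[:, ci])
                else:
                    gr = regress_out_markers(gvec, G[:, idx])
                    r_after = _pair_r(resid_e[set_name], gr)
                drop = (
                    (abs(r_before) - abs(r_after)) / abs(r_before) * 100
                    if r_before not in (0, np.nan) and np.isfinite(r_before) and r_before != 0
                    else np.nan
                )
                rows.append(
                    {
                        "gene_id": gene,
                        "condition_id": cond,
                        "set_name": set_name,
                        "set_size": len(idx),
                        "r_before": r_before,
                        "r_after": r_after,
                        "pct_drop": drop,
                    }
                )
    table = pd.DataFrame(rows)

    # Paired Wilcoxon on |r| before vs after, per set.
    tests = []
    for set_name, grp in table.groupby("set_name"):
        ok = grp["r_before"].notna() & grp["r_after"].notna()
        a = grp.loc[ok, "r_before"].abs()
        b = grp.loc[ok, "r_after"].abs()
        if ok.sum() >= 5 and (a != b).any():
            stat, p = stats.wilcoxon(a, b)
        else:
            stat, p = np.nan, np.nan
        tests.append(
            {
                "set_name": set_name,
                "n_pairs": int(ok.sum()),
                "median_pct_drop": float(grp["pct_drop"].median()),
                "wilcoxon_stat": stat,
                "wilcoxon_p": p,
            }
        )
    table.attrs["tests"] = pd.DataFrame(tests)

    # Size-matched random-set expectation.
    if n_random_sets > 0:
        pairs = list(
            eligible[["gene_id", "condition_id"]].itertuples(index=False, name=None)
        )
        genes_u = sorted({g for g, _ in pairs})
        conds_u = sorted({c for _, c in pairs})
        r_before_map = {
            (g, c): _pair_r(expr.column(g), growth.column(c)) for g, c in pairs
        }
        rand_rows = []
        for set_name, grp in table.groupby("set_name"):
            size = int(grp["set_size"].median())
            drops = []
            for _ in range(n_random_sets):
                ridx = rng.choice(n_mark, size=size, replace=False)
                er = {g: regress_out_markers(expr.column(g), G[:, ridx]) for g in genes_u}
                gr = {c: regress_out_markers(growth.column(c), G[:, ridx]) for c in conds_u}
                for g, c in pairs:
                    rb = r_before_map[(g, c)]
                    ra = _pair_r(er[g], gr[c])
                    if rb and np.isfinite(rb) and np.isfinite(ra):
                        drops.append((abs(rb) - abs(ra)) / abs(rb) * 100)
            rand_rows.append(
                {
                    "set_name": set_name,
                    "set_size": size,
                    "median_pct_drop_random": float(np.median(drops)) if drops else np.nan,
                }
            )
        table.attrs["random_expectation"] = pd.DataFrame(rand_rows)
    return table
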