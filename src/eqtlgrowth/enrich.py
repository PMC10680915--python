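"""Sign-split gene-set enrichment, trait clustering, signature averages.

Significant genetic correlations for a condition are split by sign, each
direction is tested for enrichment of every gene-set term with a one-sided
Fisher's exact test, and terms significant in both directions keep only the
direction with the larger |log2 fold enrichment|. Conditions are clustered
on the signed fold-enrichment profiles of terms passing a display cutoff
(k-means); average correlation coefficients over externally defined gene
groups (growth-rate / stress-response signatures) summarize condition-level
expression programmes.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.cluster import KMeans

from .datatypes import ValidationError


def sign_split_enrichment(
    correlations: pd.DataFrame,
    gene_sets: dict[str, set[str]],
    universe: list[str],
    alpha_fdr: float = 0.05,
    p_display: float = 1e-3,
    p_strict: float = 1e-5,
) -> pd.DataFrame:
    """Fisher enrichment of each term among positive / negative hits.

    ``correlations`` needs columns gene_id, condition_id, r, q. For each
    condition, genes with q <= alpha_fdr are split by the sign of r and
    each direction tested for enrichment (one-sided) of every term against
    the tested-gene universe. Records at p < p_display are returned; the
    attached summary counts records passing p < p_strict.
    """
    uni = [g for g in universe]
    uni_set = set(uni)
    n_uni = len(uni)
    sets = {t: set(gs) & uni_set for t, gs in gene_sets.items()}
    rows = []
    for cond, grp in correlations.groupby("condition_id"):
        sig = grp[(grp["q"] <= alpha_fdr) & grp["r"].notna()]
        for direction, sub in (("positive", sig[sig["r"] > 0]), ("negative", sig[sig["r"] < 0])):
            genes = set(sub["gene_id"]) & uni_set
            n_sig = len(genes)
            if n_sig == 0:
                continue
            for term, members in sets.items():
                t_size = len(members)
                if t_size == 0:
                    continue
                k = len(genes & members)
                expected = n_sig * t_size / n_uni
                fold = k / expected if expected > 0 else np.nan
                table = [
                    [k, n_sig - k],
                    [t_size - k, n_uni - n_sig - t_size + k],
                ]
                _, p = stats.fisher_exact(table, alternative="greater")
                rows.append(
                    {
                        "condition_id": cond,
                        "term_id": term,
                        "direction": direction,
                        "k": k,
                        "n_sig": n_sig,
                        "term_size": t_size,
                        "expected": expected,
                        "fold": fold,
                        "log2_fold": np.log2(fold) if fold > 0 else -np.inf,
                        "fet_p": p,
                    }
                )
    all_records = pd.DataFrame(
        rows,
        columns=["condition_id", "term_id", "direction", "k", "n_sig", "term_size",
                 "expected", "fold", "log2_fold", "fet_p"],
    )
    out = all_records[all_records["fet_p"] < p_display].reset_index(drop=True)
    out.attrs["n_strict"] = int((all_records["fet_p"] < p_strict).sum())
    out.attrs["n_strict_resolved"] = int(
        (resolve_bidirectional(all_records)["fet_p"] < p_strict).sum()
    ) if len(all_records) else 0
    return out


def resolve_bidirectional(records: pd.DataFrame) -> pd.DataFrame:
    """Keep one direction per (condition, term).

    When a term appears in both directions, the direction with the larger
    |log2 fold enrichment| wins; an exact tie keeps the positive direction.
    """
    if not len(records):
        return records.copy()

    def pick(grp: pd.DataFrame) -> pd.Series:
        if len(grp) == 1:
            return grp.iloc[0]
        mag = grp["log2_fold"].abs()
        best = mag.max()
        tied = grp[mag == best]
        if len(tied) > 1:
            pos = tied[tied["direction"] == "positive"]
            return pos.iloc[0] if len(pos) else tied.iloc[0]
        return tied.iloc[0]

    out = (
        records.groupby(["condition_id", "term_id"], group_keys=False)
        .apply(pick, include_groups=False)
        .reset_index()
    )
    return out[records.columns]


def fold_matrix(records: pd.DataFrame, conditions: list[str]) -> pd.DataFrame:
    """Signed fold-enrichment matrix (conditions x terms) for clustering.

    Negative-direction folds enter with a negative sign; missing entries
    are zero-filled. Resolve bidirectional conflicts first.
    """
    resolved = resolve_bidirectional(records)
    terms = sorted(resolved["term_id"].unique())
    M = pd.DataFrame(0.0, index=conditions, columns=terms)
    for _, rec in resolved.iterrows():
        signed = rec["fold"] if rec["direction"] == "positive" else -rec["fold"]
        M.loc[rec["condition_id"], rec["term_id"]] = signed
    return M


def cluster_traits(
    fold_mat: pd.DataFrame, k: int, seed: int = 0, n_init: int = 10
) -> tuple[pd.Series, float]:
    """k-means clustering of conditions on enrichment profiles."""
    if k > len(fold_mat):
        raise ValidationError(f"k={k} exceeds number of traits {len(fold_mat)}")
    km = KMeans(n_clusters=k, n_init=n_init, random_state=int(seed) % (2**31 - 1))
    labels = km.fit_predict(np.nan_to_num(fold_mat.to_numpy(float)))
    return pd.Series(labels, index=fold_mat.index, name="cluster"), float(km.inertia_)


def signature_average(
    correlations: pd.DataFrame, gene_groups: dict[str, set[str]]
) -> pd.DataFrame:
    """Mean genetic-correlation coefficient per gene group per condition."""
    rows = []
    for cond, grp in correlations.groupby("condition_id"):
        by_gene = grp.set_index("gene_id")["r"]
        for name, members in gene_groups.items():
            present = [g for g in by_gene.index if g in members]
            rows.append(
                {
                    "condition_id": cond,
                    "group": name,
                    "n_genes": len(present),
                    "mean_r": float(by_gene.loc[present].mean()) if present else np.nan,
                    "empty": len(present) == 0,
                }
            )
    return pd.DataFrame(rows)
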