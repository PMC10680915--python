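"""Hotspot-marker effect assignment and hotspot-effect correlations.

Trans-eQTL hotspots are genomic locations whose alleles change the
expression of many genes. Their joint effect on a trait is estimated by a
forward-stepwise procedure over the hotspot peak markers: at each step the
marker with the strongest significant correlation (p < 0.05) with the
current residualized trait is retained, its correlation recorded as its
effect, and its effect regressed out; markers never retained get effect 0.
The "hotspot correlation" of a gene/condition pair is then the Pearson
correlation between the gene's and the condition's hotspot-effect vectors
(zeros included). Random marker sets of the same size provide the null.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .datatypes import ValidationError
from .gencor import pearson_p


@dataclass
class HotspotEffectVector:
    trait_id: str
    effects: np.ndarray  # one entry per hotspot marker; 0 where never retained
    retention_order: list[int] = field(default_factory=list)


def _r_crit(n: int, p: float) -> float:
    """|r| threshold equivalent to a two-sided correlation p-value < p."""
    tstar = stats.t.isf(p / 2.0, n - 2)
    return tstar / np.sqrt(n - 2 + tstar**2)


def stepwise_effects_matrix(
    traits: np.ndarray, hotspot_geno: np.ndarray, stepwise_p: float = 0.05
) -> tuple[np.ndarray, list[list[int]]]:
    """Vectorized stepwise hotspot-effect assignment for many traits.

    ``traits`` is ``(n, T)`` with no missing values; ``hotspot_geno`` is
    ``(n, m)``. Returns the ``(T, m)`` effect matrix and per-trait retention
    orders. Ties on |r| break toward the lowest marker index.
    """
    T = np.asarray(traits, float)
    H = np.asarray(hotspot_geno, float)
    n, n_traits = T.shape
    m = H.shape[1]
    if n < 10:
        raise ValidationError(f"need >= 10 complete observations, got {n}")
    if m < 1:
        raise ValidationError("need at least one hotspot marker")
    if (T.std(axis=0) == 0).any():
        raise ValidationError("constant trait supplied to stepwise procedure")
    rc = _r_crit(n, stepwise_p)
    Hc = H - H.mean(axis=0)
    hss = (Hc**2).sum(axis=0)
    hnorm = np.sqrt(hss)
    R = T - T.mean(axis=0)  # residualized traits, kept centered
    effects = np.zeros((n_traits, m))
    retained = np.zeros((n_traits, m), bool)
    orders: list[list[int]] = [[] for _ in range(n_traits)]
    active = np.ones(n_traits, bool)
    for _ in range(m):
        if not active.any():
            break
        ai = np.nonzero(active)[0]
        Ra = R[:, ai]
        rnorm = np.sqrt((Ra**2).sum(axis=0))
        dead = rnorm == 0
        with np.errstate(divide="ignore", invalid="ignore"):
            C = (Hc.T @ Ra) / (hnorm[:, None] * rnorm[None, :])
        C = np.nan_to_num(C)
        C[retained[ai].T] = 0.0
        best = np.abs(C).argmax(axis=0)
        best_r = C[best, np.arange(len(ai))]
        sig = (np.abs(best_r) > rc) & ~dead
        for k, t in enumerate(ai):
            if not sig[k]:
                active[t] = False
                continue
            j = best[k]
            effects[t, j] = best_r[k]
            retained[t, j] = True
            orders[t].append(int(j))
            b = (Hc[:, j] @ R[:, t]) / hss[j]
            R[:, t] = R[:, t] - b * Hc[:, j]
    return effects, orders


def stepwise_hotspot_effects(
    trait: np.ndarray, hotspot_geno: np.ndarray, stepwise_p: float = 0.05,
    trait_id: str = "",
) -> HotspotEffectVector:
    """Stepwise effect assignment for a single trait (missing rows dropped)."""
    t = np.asarray(trait, float)
    ok = ~np.isnan(t)
    eff, orders = stepwise_effects_matrix(
        t[ok][:, None], np.asarray(hotspot_geno, float)[ok], stepwise_p
    )
    return HotspotEffectVector(trait_id, eff[0], orders[0])


def hotspot_correlation(
    gene_effects: np.ndarray | HotspotEffectVector,
    growth_effects: np.ndarray | HotspotEffectVector,
) -> tuple[float, float]:
    """Pearson correlation between two hotspot-effect vectors, zeros included."""
    v1 = gene_effects.effects if isinstance(gene_effects, HotspotEffectVector) else np.asarray(gene_effects, float)
    v2 = growth_effects.effects if isinstance(growth_effects, HotspotEffectVector) else np.asarray(growth_effects, float)
    if v1.shape != v2.shape:
        raise ValidationError("effect vectors must cover the same hotspot set")
    if v1.std() == 0 or v2.std() == 0:
        return np.nan, np.nan
    r = float(np.clip(np.corrcoef(v1, v2)[0, 1], -1, 1))
    return r, float(pearson_p(np.array(r), v1.size))


def hotspot_effect_tables(
    expr_values: np.ndarray,
    growth_values: np.ndarray,
    hotspot_geno: np.ndarray,
    gene_ids: list[str],
    condition_ids: list[str],
    stepwise_p: float = 0.05,
) -> tuple[np.ndarray, np.ndarray]:
    """Effect matrices (genes x hotspots, conditions x hotspots).

    Expression is complete so all genes run in one vectorized batch; growth
    traits run one at a time on their complete rows.
    """
    gene_eff, _ = stepwise_effects_matrix(expr_values, hotspot_geno, stepwise_p)
    cond_eff = np.zeros((len(condition_ids), hotspot_geno.shape[1]))
    for c in range(len(condition_ids)):
        y = growth_values[:, c]
        ok = ~np.isnan(y)
        eff, _ = stepwise_effects_matrix(y[ok][:, None], hotspot_geno[ok], stepwise_p)
        cond_eff[c] = eff[0]
    return gene_eff, cond_eff


def hotspot_correlation_table(
    gene_eff: np.ndarray,
    cond_eff: np.ndarray,
    gene_ids: list[str],
    condition_ids: list[str],
    fdr: float = 0.05,
) -> pd.DataFrame:
    """Hotspot correlations for all gene x condition pairs with BH FDR."""
    rows = []
    for c, cond in enumerate(condition_ids):
        v2 = cond_eff[c]
        for g, gene in enumerate(gene_ids):
            r, p = hotspot_correlation(gene_eff[g], v2)
            rows.append({"gene_id": gene, "condition_id": cond, "r": r, "p": p})
    table = pd.DataFrame(rows)
    ok = table["p"].notna()
    table["q"] = np.nan
    if ok.any():
        table.loc[ok, "q"] = multipletests(table.loc[ok, "p"], method="fdr_bh")[1]
    table["sig"] = table["q"] <= fdr
    return table


# ---------------------------------------------------------------------------
# Random-marker-set nulls
# ---------------------------------------------------------------------------

def random_marker_sets(
    n_markers: int, set_size: int, n_sets: int, rng: np.random.Generator
) -> np.ndarray:
    if set_size > n_markers:
        raise ValidationError(f"set_size {set_size} exceeds marker count {n_markers}")
    return np.stack(
        [np.sort(rng.choice(n_markers, size=set_size, replace=False)) for _ in range(n_sets)]
    )


def empirical_p(observed: float, null: np.ndarray, direction: str = "greater") -> float:
    """Add-one empirical p-value: (#null at least as extreme + 1) / (n + 1)."""
    null = np.asarray(null, float)
    null = null[~np.isnan(null)]
    if null.size == 0:
        raise ValidationError("need at least one null value")
    if direction == "greater":
        k = int((null >= observed).sum())
    elif direction == "less":
        k = int((null <= observed).sum())
    else:
        raise ValidationError("direction must be 'greater' or 'less'")
    return (k + 1) / (null.size + 1)


def random_markerset_null(
    statistic,
    n_markers: int,
    set_size: int,
    n_sets: int,
    seed: int,
    marker_sets: np.ndarray | None = None,
) -> np.ndarray:
    """Apply ``statistic(marker_indices)`` to random marker sets.

    ``statistic`` returns a scalar or per-trait vector; the result is
    stacked into ``(n_sets, ...)``. Pass explicit ``marker_sets`` to
    evaluate chosen sets (e.g., the true hotspot set) instead of random
    ones.
    """
    if marker_sets is None:
        rng = np.random.default_rng(seed)
        marker_sets = random_marker_sets(n_markers, set_size, n_sets, rng)
    out = [np.asarray(statistic(np.asarray(ms))) for ms in marker_sets]
    return np.stack(out)
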