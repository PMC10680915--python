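"""Mediation of a hotspot's growth effect through gene expression.

For a hotspot peak marker, a candidate mediator gene, and a growth
condition, two linear models are fit by OLS:

    mediator = alpha * genotype + e1
    outcome  = beta * genotype + gamma * mediator + e2

so the marker's total effect decomposes exactly (on complete data) into a
direct part ``beta`` and a mediated part ``alpha * gamma``; the proportion
mediated is ``alpha*gamma / (beta + alpha*gamma)``, which can leave [0, 1]
under suppression and is reported unclipped with a sign flag. Inference
uses a non-parametric case-resampling bootstrap of segregant triples with a
two-sided percentile test on ``alpha * gamma``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .datatypes import ValidationError


@dataclass
class MediationResult:
    gene_id: str
    hotspot_marker: str
    condition_id: str
    alpha: float
    beta: float
    gamma: float
    prop_mediated: float
    total_effect: float
    n: int
    suppression: bool
    identifiable: bool = True
    p_boot: float | None = None
    ci_prop: tuple[float, float] | None = None


def _complete_triples(g, m, y):
    g = np.asarray(g, float)
    m = np.asarray(m, float)
    y = np.asarray(y, float)
    ok = ~np.isnan(g) & ~np.isnan(m) & ~np.isnan(y)
    return g[ok], m[ok], y[ok]


def _fit_coefs(g: np.ndarray, m: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    """alpha from m ~ g; (beta, gamma) from y ~ g + m, all with intercepts."""
    gc = g - g.mean()
    alpha = float((gc @ m) / (gc @ gc))
    X = np.column_stack([np.ones(g.size), g, m])
    coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    return alpha, float(coef[1]), float(coef[2])


def mediation_fit(
    marker_genotype: np.ndarray,
    mediator: np.ndarray,
    outcome: np.ndarray,
    gene_id: str = "",
    hotspot_marker: str = "",
    condition_id: str = "",
) -> MediationResult:
    """Point estimates of the mediation decomposition (no p-value yet)."""
    g, m, y = _complete_triples(marker_genotype, mediator, outcome)
    n = g.size
    if n < 10:
        raise ValidationError(f"need >= 10 complete triples, got {n}")
    if g.std() == 0:
        raise ValidationError("marker genotype is constant")
    identifiable = True
    if m.std() == 0 or abs(np.corrcoef(g, m)[0, 1]) >= 1 - 1e-12:
        identifiable = False  # gamma cannot be separated from beta
    alpha, beta, gamma = _fit_coefs(g, m, y)
    total = beta + alpha * gamma
    prop = alpha * gamma / total if total != 0 else np.nan
    suppression = bool(np.sign(beta) * np.sign(alpha * gamma) < 0)
    return MediationResult(
        gene_id, hotspot_marker, condition_id, alpha, beta, gamma,
        float(prop), float(total), n, suppression, identifiable,
    )


def mediation_bootstrap(
    marker_genotype: np.ndarray,
    mediator: np.ndarray,
    outcome: np.ndarray,
    n_boot: int = 1000,
    seed: int | np.random.Generator = 0,
    result: MediationResult | None = None,
) -> MediationResult:
    """Case-resampling bootstrap inference for the mediated effect.

    Resamples segregant triples with replacement, refits both models, and
    tests ``alpha * gamma`` against zero with the two-sided add-one
    percentile convention ``p = 2 * min(#{<=0}+1, #{>=0}+1) / (n_boot+1)``
    capped at 1. Degenerate resamples with a constant marker are redrawn.
    Also attaches a percentile CI for the proportion mediated.
    """
    if result is None:
        result = mediation_fit(marker_genotype, mediator, outcome)
    g, m, y = _complete_triples(marker_genotype, mediator, outcome)
    n = g.size
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    # Vectorized resampling: per-row moments give alpha and the closed-form
    # two-predictor OLS for (beta, gamma).
    idx = rng.integers(0, n, size=(n_boot, n))
    redraws = 0
    for _ in range(100):
        Gb = g[idx]
        bad = Gb.std(axis=1) == 0
        if not bad.any():
            break
        redraws += int(bad.sum())
        idx[bad] = rng.integers(0, n, size=(int(bad.sum()), n))
    Gb = g[idx]
    Mb = m[idx]
    Yb = y[idx]
    Gc = Gb - Gb.mean(axis=1, keepdims=True)
    Mc = Mb - Mb.mean(axis=1, keepdims=True)
    Yc = Yb - Yb.mean(axis=1, keepdims=True)
    var_g = (Gc**2).mean(axis=1)
    var_m = (Mc**2).mean(axis=1)
    cov_gm = (Gc * Mc).mean(axis=1)
    cov_gy = (Gc * Yc).mean(axis=1)
    cov_my = (Mc * Yc).mean(axis=1)
    alpha_b = cov_gm / var_g
    det = var_g * var_m - cov_gm**2
    ok = det > 1e-12 * np.maximum(var_g * var_m, 1e-300)
    beta_b = np.where(ok, (cov_gy * var_m - cov_my * cov_gm) / np.where(ok, det, 1), np.nan)
    gamma_b = np.where(ok, (cov_my * var_g - cov_gy * cov_gm) / np.where(ok, det, 1), np.nan)
    prods = np.where(ok, alpha_b * gamma_b, 0.0)
    tot = beta_b + alpha_b * gamma_b
    with np.errstate(divide="ignore", invalid="ignore"):
        props = np.where(ok & (tot != 0), alpha_b * gamma_b / tot, np.nan)
    n_le = int((prods <= 0).sum())
    n_ge = int((prods >= 0).sum())
    p = min(1.0, 2.0 * (min(n_le, n_ge) + 1) / (n_boot + 1))
    result.p_boot = p
    finite = props[np.isfinite(props)]
    if finite.size:
        result.ci_prop = (
            float(np.quantile(finite, 0.025)),
            float(np.quantile(finite, 0.975)),
        )
    result.n_redraws = redraws  # type: ignore[attr-defined]
    return result


def mediation_scan(
    marker_genotype: np.ndarray,
    expr_values: np.ndarray,
    gene_ids: list[str],
    outcome: np.ndarray,
    condition_id: str,
    hotspot_marker: str,
    n_boot: int = 1000,
    seed: int = 0,
    fdr: float = 0.05,
) -> pd.DataFrame:
    """Mediation of one hotspot/condition pair through many candidate genes.

    Runs fit + bootstrap per gene and applies Benjamini-Hochberg FDR over
    the bootstrap p-values.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for j, gene in enumerate(gene_ids):
        res = mediation_fit(
            marker_genotype, expr_values[:, j], outcome, gene, hotspot_marker, condition_id
        )
        if not res.identifiable:
            continue
        res = mediation_bootstrap(
            marker_genotype, expr_values[:, j], outcome, n_boot, rng, res
        )
        rows.append(
            {
                "gene_id": gene,
                "hotspot_marker": hotspot_marker,
                "condition_id": condition_id,
                "alpha": res.alpha,
                "beta": res.beta,
                "gamma": res.gamma,
                "prop_mediated": res.prop_mediated,
                "total_effect": res.total_effect,
                "suppression": res.suppression,
                "p_boot": res.p_boot,
            }
        )
    table = pd.DataFrame(rows)
    if len(table):
        table["q"] = multipletests(table["p_boot"], method="fdr_bh")[1]
        table["sig"] = table["q"] <= fdr
    return table
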