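"""Pleiotropy versus linkage: a bivariate two-QTL scan with bootstrap.

For an expression trait and a growth trait mapping to the same genomic
interval, every ordered marker pair (lambda1, lambda2) is scored under a
bivariate Gaussian model in which trait t has mean ``alpha_t + beta_t *
g_lambda_t`` and the two residuals share an unstructured 2x2 covariance
(maximized in closed form: per-trait OLS plus the residual cross-covariance
MLE). The diagonal of the pair grid is the single pleiotropic-QTL model;
the log10-likelihood-ratio statistic compares the best pair against the
best diagonal entry, and its null distribution comes from a parametric
bootstrap under the fitted pleiotropy model. Profile LOD traces per trait
reproduce the usual two-QTL diagnostics: a maximum profile LOD of zero
means the two-QTL model fits no better than one shared QTL.

A one-generation haploid cross has no family structure, so no kinship
random effect is included in the bivariate model.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .datatypes import ValidationError

LN10 = np.log(10.0)


def prune_markers(G: np.ndarray, r_threshold: float = 0.95) -> np.ndarray:
    """Greedy left-to-right pruning of consecutive near-identical markers.

    Keeps a marker iff its correlation with the most recently retained
    marker is below ``r_threshold``; markers must already be ordered by
    genome position. Returns retained column indices.
    """
    G = np.asarray(G, float)
    if G.shape[1] == 0:
        return np.array([], dtype=int)
    kept = [0]
    for j in range(1, G.shape[1]):
        a = G[:, kept[-1]]
        b = G[:, j]
        if a.std() == 0 or b.std() == 0:
            continue
        if abs(np.corrcoef(a, b)[0, 1]) < r_threshold:
            kept.append(j)
    return np.array(kept, dtype=int)


@dataclass
class ColocScan:
    marker_ids: list[str]
    loglik10: np.ndarray  # (m, m) log10-likelihood surface; rows = trait-1 position
    lrt: float
    profile_lod_1: np.ndarray
    profile_lod_2: np.ndarray
    best_pair: tuple[int, int]
    pleio_index: int
    n: int
    verdict: str = "not-tested"  # pleiotropy-not-rejected | distinct-QTLs | not-tested
    p_boot: float | None = None
    # fitted pleiotropy model, used by the parametric bootstrap
    _fit: dict = field(default_factory=dict, repr=False)


def _residual_matrix(y: np.ndarray, Gc: np.ndarray, denom: np.ndarray) -> np.ndarray:
    """Residuals of y on each (centred) marker column with an intercept."""
    yc = y - y.mean()
    b = (Gc * yc[:, None]).sum(axis=0) / denom
    return yc[:, None] - Gc * b[None, :]


def _surface(y1: np.ndarray, y2: np.ndarray, Gc: np.ndarray, denom: np.ndarray, n: int):
    E1 = _residual_matrix(y1, Gc, denom)
    E2 = _residual_matrix(y2, Gc, denom)
    s11 = (E1**2).mean(axis=0)
    s22 = (E2**2).mean(axis=0)
    S12 = (E1.T @ E2) / n
    det = np.clip(s11[:, None] * s22[None, :] - S12**2, 1e-300, None)
    ll10 = -(n / 2.0) * (2 * np.log(2 * np.pi) + np.log(det) + 2) / LN10
    return ll10, s11, s22, S12


def two_qtl_scan(
    expr_trait: np.ndarray,
    growth_trait: np.ndarray,
    G: np.ndarray,
    marker_ids: list[str] | None = None,
    min_markers: int = 3,
) -> ColocScan:
    """Full pair-grid scan for one expression/growth trait pair.

    Rows with a missing value in either trait are dropped. Intervals with
    fewer than ``min_markers`` markers are returned untested.
    """
    y1 = np.asarray(expr_trait, float)
    y2 = np.asarray(growth_trait, float)
    G = np.asarray(G, float)
    if marker_ids is None:
        marker_ids = [f"m{j}" for j in range(G.shape[1])]
    ok = ~np.isnan(y1) & ~np.isnan(y2)
    m = G.shape[1]
    if m < min_markers:
        return ColocScan(list(marker_ids), np.zeros((m, m)), 0.0, np.zeros(m),
                         np.zeros(m), (0, 0), 0, int(ok.sum()), "not-tested")
    y1, y2, Gs = y1[ok], y2[ok], G[ok]
    n = y1.size
    Gc = Gs - Gs.mean(axis=0)
    denom = (Gc**2).sum(axis=0)
    if (denom == 0).any():
        raise ValidationError("constant marker inside the scan interval")
    ll10, s11, s22, S12 = _surface(y1, y2, Gc, denom, n)
    diag = np.diag(ll10)
    pleio_idx = int(np.argmax(diag))
    best_flat = int(np.argmax(ll10))
    best_pair = np.unravel_index(best_flat, ll10.shape)
    lrt = float(ll10.max() - diag.max())
    prof1 = ll10.max(axis=1) - diag.max()
    prof2 = ll10.max(axis=0) - diag.max()
    # store the fitted pleiotropy model for the bootstrap
    j = pleio_idx
    g = Gs[:, j]
    b1 = (Gc[:, j] @ (y1 - y1.mean())) / denom[j]
    b2 = (Gc[:, j] @ (y2 - y2.mean())) / denom[j]
    mu1 = y1.mean() - b1 * Gs[:, j].mean()
    mu2 = y2.mean() - b2 * Gs[:, j].mean()
    Sigma = np.array([[s11[j], S12[j, j]], [S12[j, j], s22[j]]])
    scan = ColocScan(
        list(marker_ids), ll10, lrt, prof1, prof2,
        (int(best_pair[0]), int(best_pair[1])), pleio_idx, n, "pleiotropy-not-rejected",
    )
    scan._fit = {"g": g, "beta": (b1, b2), "mu": (mu1, mu2), "Sigma": Sigma,
                 "Gc": Gc, "denom": denom, "Gs": Gs}
    return scan


def parametric_bootstrap_p(
    scan: ColocScan,
    n_boot: int = 1000,
    seed: int | np.random.Generator = 0,
    alpha: float = 0.05,
) -> float:
    """Bootstrap p for the two-QTL vs pleiotropy likelihood ratio.

    Trait pairs are simulated from the fitted single-QTL pleiotropy model
    (same genotypes, fitted effects, fitted 2x2 residual covariance) and the
    scan statistic recomputed; ``p = (#boot >= observed + 1)/(n_boot + 1)``.
    The scan verdict becomes ``distinct-QTLs`` when p <= alpha.
    """
    if scan.verdict == "not-tested" or not scan._fit:
        raise ValidationError("scan was not tested; cannot bootstrap")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    fit = scan._fit
    g = fit["g"]
    b1, b2 = fit["beta"]
    mu1, mu2 = fit["mu"]
    L = np.linalg.cholesky(fit["Sigma"] + 1e-12 * np.eye(2))
    Gc, denom = fit["Gc"], fit["denom"]
    n = scan.n
    mean1 = mu1 + b1 * g
    mean2 = mu2 + b2 * g
    exceed = 0
    for _ in range(n_boot):
        eps = rng.standard_normal((n, 2)) @ L.T
        y1 = mean1 + eps[:, 0]
        y2 = mean2 + eps[:, 1]
        ll10, *_ = _surface(y1, y2, Gc, denom, n)
        stat = float(ll10.max() - np.diag(ll10).max())
        if stat >= scan.lrt:
            exceed += 1
    p = (exceed + 1) / (n_boot + 1)
    scan.p_boot = p
    scan.verdict = "distinct-QTLs" if p <= alpha else "pleiotropy-not-rejected"
    return p
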