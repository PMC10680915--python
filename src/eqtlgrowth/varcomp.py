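"""Single-GRM REML variance components for marker sets.

The fraction of growth variance explained by a marker set is estimated
under the mixed model ``y = mu + u + e`` with ``u ~ N(0, sigma_g^2 K)`` and
``e ~ N(0, sigma_e^2 I)``, where ``K = Z Z' / m`` is the genetic
relatedness matrix of the ``m`` column-standardized markers. The restricted
likelihood is maximized over the variance ratio with one spectral
decomposition followed by a one-dimensional optimization of the rotated
likelihood (the EMMA device), which is fast and admits a brute-force
grid-search oracle. Heritability partitioning ranks hotspots by the number
of genes they affect and traces variance captured by growing hotspot sets;
random marker sets of equal size provide the chance expectation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize

from .datatypes import GenotypeMatrix, ValidationError
from .hotspots import empirical_p, random_marker_sets


@dataclass
class GRM:
    values: np.ndarray
    n_markers: int

    def validate(self) -> "GRM":
        K = self.values
        if K.ndim != 2 or K.shape[0] != K.shape[1]:
            raise ValidationError("GRM must be square")
        if np.abs(K - K.T).max() > 1e-10:
            raise ValidationError("GRM must be symmetric")
        return self


@dataclass
class VarianceEstimate:
    sigma2_g: float
    sigma2_e: float
    fraction: float
    loglik: float
    n: int
    n_markers: int
    identifiable: bool = True


def build_grm(genotypes: GenotypeMatrix | np.ndarray, marker_subset) -> GRM:
    """K = Z Z' / m with Z the column-standardized genotype submatrix.

    Standardization uses observed marker means and SDs (allele frequencies
    are not assumed to be exactly 0.5). Constant markers in the subset are
    dropped with a warning; duplicated markers only rescale K.
    """
    G = genotypes.values if isinstance(genotypes, GenotypeMatrix) else np.asarray(genotypes)
    idx = np.asarray(marker_subset, dtype=int)
    if idx.size == 0:
        raise ValidationError("marker subset must be non-empty")
    Z = G[:, idx].astype(float)
    sd = Z.std(axis=0, ddof=0)
    keep = sd > 0
    if not keep.all():
        warnings.warn(f"dropping {int((~keep).sum())} constant marker(s) from GRM")
        Z = Z[:, keep]
        sd = sd[keep]
        if Z.shape[1] == 0:
            raise ValidationError("all markers in the subset are constant")
    Z = (Z - Z.mean(axis=0)) / sd
    m = Z.shape[1]
    return GRM(Z @ Z.T / m, m).validate()


def _reml_loglik_terms(delta: float, xi: np.ndarray, eta2: np.ndarray) -> tuple[float, float]:
    """Profiled restricted log-likelihood (up to a constant) and sigma_g^2."""
    d = xi + delta
    k = xi.size  # n - p rotated coordinates
    sg2 = float((eta2 / d).sum() / k)
    ll = -0.5 * (k * np.log(2 * np.pi * sg2) + np.log(d).sum() + k)
    return ll, sg2


def rotated_problem(yv: np.ndarray, Kv: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Spectral coordinates (xi, eta^2) of the intercept-projected model.

    Double-centres K, rotates the centred phenotype into the eigenbasis,
    and discards one kernel coordinate for the constant vector. The
    restricted likelihood depends on equal eigenvalues only through their
    summed eta^2, and the centred phenotype has no component along the
    constant vector, so the kernel's total eta^2 is lumped onto the
    retained zero-eigenvalue coordinates.
    """
    Kc = Kv - Kv.mean(axis=0, keepdims=True)
    Kc = Kc - Kc.mean(axis=1, keepdims=True)
    xi_all, U = np.linalg.eigh(Kc)
    eta2_all = (U.T @ (yv - yv.mean())) ** 2
    order = np.argsort(xi_all)
    xi_s = np.clip(xi_all[order], 0.0, None)
    eta2_s = eta2_all[order].copy()
    tol = max(1e-12, float(xi_s[-1]) * 1e-12)
    q = max(int((xi_s < tol).sum()), 1)
    kernel_sum = eta2_s[:q].sum()
    xi = xi_s[1:]
    eta2 = eta2_s[1:].copy()
    if q >= 2:
        eta2[: q - 1] = 0.0
        eta2[q - 2] = kernel_sum
    return xi, eta2


def reml_h2(y: np.ndarray, K: GRM | np.ndarray) -> VarianceEstimate:
    """REML variance fraction for one trait under a single GRM.

    Missing phenotype rows must be removed (with matching GRM subsetting)
    before calling; use :func:`reml_h2_masked` for convenience. The model
    has an intercept as its only fixed effect.
    """
    Kv = K.values if isinstance(K, GRM) else np.asarray(K, float)
    m = K.n_markers if isinstance(K, GRM) else Kv.shape[0]
    yv = np.asarray(y, float)
    if np.isnan(yv).any():
        raise ValidationError("y must be complete; subset K to observed rows first")
    n = yv.size
    if Kv.shape != (n, n):
        raise ValidationError("GRM dimension does not match phenotype length")
    identifiable = bool(np.abs(Kv - np.eye(n)).max() > 1e-8)
    xi, eta2 = rotated_problem(yv, Kv)

    def neg_ll(log_delta: float) -> float:
        return -_reml_loglik_terms(10.0**log_delta, xi, eta2)[0]

    res = optimize.minimize_scalar(neg_ll, bounds=(-8.0, 8.0), method="bounded",
                                   options={"xatol": 1e-8})
    candidates = [res.x, -8.0, 8.0]
    best = min(candidates, key=neg_ll)
    delta = 10.0**best
    ll, sg2 = _reml_loglik_terms(delta, xi, eta2)
    se2 = delta * sg2
    frac = sg2 / (sg2 + se2)
    return VarianceEstimate(sg2, se2, float(frac), float(ll), n, m, identifiable)


def reml_h2_masked(y: np.ndarray, K: GRM) -> VarianceEstimate:
    """REML after listwise removal of missing phenotype rows."""
    yv = np.asarray(y, float)
    ok = ~np.isnan(yv)
    sub = GRM(K.values[np.ix_(ok, ok)], K.n_markers)
    return reml_h2(yv[ok], sub)


def marker_set_h2(
    growth_values: np.ndarray,
    condition_ids: list[str],
    genotypes: GenotypeMatrix,
    marker_subset,
    set_name: str = "set",
) -> pd.DataFrame:
    """Variance fraction of one marker set for every condition."""
    K = build_grm(genotypes, marker_subset)
    rows = []
    for c, cond in enumerate(condition_ids):
        est = reml_h2_masked(growth_values[:, c], K)
        rows.append(
            {
                "condition_id": cond,
                "set_name": set_name,
                "n_markers": est.n_markers,
                "sigma2_g": est.sigma2_g,
                "sigma2_e": est.sigma2_e,
                "fraction": est.fraction,
                "loglik": est.loglik,
                "n": est.n,
            }
        )
    return pd.DataFrame(rows)


def hotspot_variance_curve(
    growth_values: np.ndarray,
    condition_ids: list[str],
    genotypes: GenotypeMatrix,
    hotspot_idx_ranked: np.ndarray,
) -> pd.DataFrame:
    """Variance captured by the top-k hotspots, k = 2..K_total.

    Hotspots must be pre-ranked by the number of genes they affect
    (descending). Also reports, per condition, the smallest k whose
    fraction reaches 50% and 80% of the all-hotspot fraction.
    """
    idx = np.asarray(hotspot_idx_ranked, int)
    if idx.size < 2:
        raise ValidationError("need at least two hotspots")
    rows = []
    for k in range(2, idx.size + 1):
        part = marker_set_h2(growth_values, condition_ids, genotypes, idx[:k], f"top{k}")
        part["k"] = k
        rows.append(part)
    curve = pd.concat(rows, ignore_index=True)
    summaries = []
    for cond, grp in curve.groupby("condition_id"):
        grp = grp.sort_values("k")
        full = grp["fraction"].iloc[-1]
        k50 = grp.loc[grp["fraction"] >= 0.5 * full, "k"].min()
        k80 = grp.loc[grp["fraction"] >= 0.8 * full, "k"].min()
        summaries.append(
            {"condition_id": cond, "fraction_all": full, "k50": int(k50), "k80": int(k80)}
        )
    curve.attrs["summary"] = pd.DataFrame(summaries)
    return curve


def random_set_h2(
    growth_values: np.ndarray,
    condition_ids: list[str],
    genotypes: GenotypeMatrix,
    set_size: int,
    n_sets: int,
    seed: int,
    observed_fractions: np.ndarray | None = None,
    marker_sets: np.ndarray | None = None,
) -> pd.DataFrame:
    """Null distribution of variance fractions from random marker sets.

    Returns the per-set, per-condition fractions; when
    ``observed_fractions`` is given (one per condition, e.g., the hotspot
    fractions) the attached summary holds add-one empirical exceedance
    p-values.
    """
    if marker_sets is None:
        rng = np.random.default_rng(seed)
        marker_sets = random_marker_sets(genotypes.n_markers, set_size, n_sets, rng)
    frames = []
    for s, ms in enumerate(marker_sets):
        part = marker_set_h2(growth_values, condition_ids, genotypes, ms, f"random{s}")
        part["set_index"] = s
        frames.append(part)
    null = pd.concat(frames, ignore_index=True)
    if observed_fractions is not None:
        rows = []
        for c, cond in enumerate(condition_ids):
            nd = null.loc[null["condition_id"] == cond, "fraction"].to_numpy()
            rows.append(
                {
                    "condition_id": cond,
                    "observed": float(observed_fractions[c]),
                    "null_mean": float(nd.mean()),
                    "null_q95": float(np.quantile(nd, 0.95)),
                    "p_emp": empirical_p(float(observed_fractions[c]), nd),
                }
            )
        null.attrs["summary"] = pd.DataFrame(rows)
    return null
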