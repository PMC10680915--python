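"""GRM construction and spectral REML heritability."""

import numpy as np
import pytest

from eqtlgrowth.datatypes import ValidationError
from eqtlgrowth.varcomp import (
    GRM,
    build_grm,
    hotspot_variance_curve,
    marker_set_h2,
    reml_h2,
    reml_h2_masked,
)


def brute_force_h2(y, K, n_grid=400):
    """Independent oracle: restricted likelihood evaluated with dense
    matrix algebra over a delta grid (coarse pass + local refinement)."""
    y = np.asarray(y, float)
    n = y.size
    X = np.ones((n, 1))

    def reml_ll(delta):
        V = K + delta * np.eye(n)
        Vi = np.linalg.inv(V)
        XtViX = X.T @ Vi @ X
        P = Vi - Vi @ X @ np.linalg.inv(XtViX) @ X.T @ Vi
        sg2 = float(y @ P @ y) / (n - 1)
        sign, ld_V = np.linalg.slogdet(V)
        _, ld_X = np.linalg.slogdet(XtViX)
        return -0.5 * ((n - 1) * np.log(2 * np.pi * sg2) + ld_V + ld_X + (n - 1))

    grid = np.logspace(-4, 4, n_grid)
    lls = np.array([reml_ll(d) for d in grid])
    j = int(np.argmax(lls))
    lo = grid[max(j - 1, 0)]
    hi = grid[min(j + 1, n_grid - 1)]
    fine = np.logspace(np.log10(lo), np.log10(hi), 200)
    lls_f = np.array([reml_ll(d) for d in fine])
    d = fine[int(np.argmax(lls_f))]
    return 1.0 / (1.0 + d)


def test_grm_single_marker_closed_form():
    vals = np.array([[1], [1], [-1], [-1]], dtype=np.int8)
    K = build_grm(vals, [0]).values
    assert set(np.round(np.unique(K), 9)) == {-1.0, 1.0}
    assert (K[0, 1], K[0, 2]) == (1.0, -1.0)


def test_grm_duplicate_markers_scale_invariant(cross):
    K1 = build_grm(cross, [3]).values
    K2 = build_grm(cross, [3, 3]).values
    np.testing.assert_allclose(K1, K2, atol=1e-12)


def test_grm_offdiagonal_mean_near_zero(rng):
    G = rng.choice([-1, 1], size=(500, 5000)).astype(np.int8)
    K = build_grm(G, np.arange(5000)).values
    off = K[~np.eye(500, dtype=bool)]
    assert abs(off.mean()) < 0.01
    assert abs(np.diag(K).mean() - 1.0) < 0.2


def test_grm_constant_marker_dropped(rng):
    G = rng.choice([-1, 1], size=(50, 3)).astype(np.int8)
    G[:, 1] = 1
    with pytest.warns(UserWarning, match="constant"):
        K = build_grm(G, [0, 1, 2])
    assert K.n_markers == 2


def test_reml_matches_grid_search_oracle(rng):
    """Spectral REML equals the dense-matrix grid search, |dh2| < 1e-3."""
    n = 100
    for i in range(20):
        G = rng.choice([-1.0, 1.0], size=(n, 60))
        K = build_grm(G, np.arange(60))
        h2_true = rng.uniform(0.1, 0.8)
        u = rng.multivariate_normal(np.zeros(n), h2_true * K.values)
        y = u + rng.normal(0, np.sqrt(1 - h2_true), n)
        est = reml_h2(y, K)
        oracle = brute_force_h2(y, K.values)
        assert abs(est.fraction - oracle) < 1e-3
        assert 0.0 <= est.fraction <= 1.0
        assert est.sigma2_g >= 0 and est.sigma2_e >= 0


def test_reml_loglik_dominates_grid(rng):
    """The returned optimum beats every grid point of the same rotated
    likelihood (oracle dominance)."""
    from eqtlgrowth.varcomp import _reml_loglik_terms, rotated_problem

    n = 120
    G = rng.choice([-1.0, 1.0], size=(n, 40))
    K = build_grm(G, np.arange(40))
    y = rng.normal(size=n)
    est = reml_h2(y, K)
    xi, eta2 = rotated_problem(y, K.values)
    best_ll = est.loglik
    for d in np.logspace(-6, 6, 200):
        ll, _ = _reml_loglik_terms(d, xi, eta2)
        assert ll <= best_ll + 1e-6


def test_reml_null_recovery(rng):
    """Noise traits with causal-free GRMs rarely show h2 above 0.1."""
    n = 500
    low = 0
    reps = 60
    G = rng.choice([-1.0, 1.0], size=(n, 100))
    K = build_grm(G, np.arange(100))
    for _ in range(reps):
        y = rng.normal(size=n)
        if reml_h2(y, K).fraction < 0.1:
            low += 1
    assert low / reps >= 0.9


def test_reml_identity_grm_flagged():
    est = reml_h2(np.random.default_rng(0).normal(size=40), GRM(np.eye(40), 1))
    assert not est.identifiable


def test_variance_curve_saturates_with_top_two(cross):
    """Condition driven only by the two top hotspots: curve flat after k=2
    and the endpoint equals the all-hotspot fit."""
    rng = np.random.default_rng(70)
    hot = np.linspace(5, cross.n_markers - 5, 10).astype(int)
    H = cross.values[:, hot].astype(float)
    y = 0.5 * H[:, 0] + 0.4 * H[:, 1] + rng.normal(0, 0.75, cross.n_segregants)
    curve = hotspot_variance_curve(y[:, None], ["c"], cross, hot)
    fr = curve.sort_values("k")["fraction"].to_numpy()
    assert np.all(np.abs(np.diff(fr[1:])) < 0.05)  # flat after k = 2
    full = marker_set_h2(y[:, None], ["c"], cross, hot, "all")["fraction"].iloc[0]
    assert fr[-1] == pytest.approx(full, abs=1e-9)
    assert curve.attrs["summary"]["k50"].iloc[0] == 2


def test_variance_curve_spread_effects_need_many_hotspots(cross):
    """Effects spread evenly over all hotspots saturate late."""
    rng = np.random.default_rng(71)
    hot = np.linspace(5, cross.n_markers - 5, 12).astype(int)
    H = cross.values[:, hot].astype(float)
    late = 0
    reps = 10
    for _ in range(reps):
        eff = rng.choice([-1, 1], 12) * 0.22
        y = H @ eff + rng.normal(0, 0.7, cross.n_segregants)
        curve = hotspot_variance_curve(y[:, None], ["c"], cross, hot)
        if curve.attrs["summary"]["k50"].iloc[0] > 12 / 4:
            late += 1
    assert late / reps >= 0.9


def test_reml_masked_handles_missing(cross):
    rng = np.random.default_rng(72)
    y = rng.normal(size=cross.n_segregants)
    y[:10] = np.nan
    K = build_grm(cross, np.arange(20))
    est = reml_h2_masked(y, K)
    assert est.n == cross.n_segregants - 10
    with pytest.raises(ValidationError):
        reml_h2(y, K)
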