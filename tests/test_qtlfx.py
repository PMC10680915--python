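"""Marker effects, Fisher-z CIs, weighted correlations, LOD scan."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from eqtlgrowth.datatypes import ValidationError
from eqtlgrowth.qtlfx import (
    lod_from_r,
    lod_scan,
    marker_effect,
    qtl_effect_correlations,
    weighted_correlation,
)


def test_fisher_ci_width_closed_form(rng):
    """r = 0, n = 103 -> width = 2 tanh(1.96/sqrt(100)) ~ 0.387."""
    g = rng.choice([-1.0, 1.0], 103)
    gc = g - g.mean()
    y = rng.normal(size=103)
    y -= gc * (gc @ y) / (gc @ gc)  # force exact r = 0
    r, width = marker_effect(y, g)
    assert abs(r) < 1e-12
    expected = 2 * np.tanh(1.959963984540054 / np.sqrt(100))
    assert width == pytest.approx(expected, abs=1e-9)


def test_marker_effect_sign_symmetry_and_degenerate(rng):
    g = rng.choice([-1.0, 1.0], 60)
    y = 0.5 * g + rng.normal(0, 1, 60)
    r1, w1 = marker_effect(y, g)
    r2, w2 = marker_effect(y, -g)
    assert r1 == pytest.approx(-r2)
    assert w1 == pytest.approx(w2)
    r3, w3 = marker_effect(g, g)  # trait equals genotype
    assert r3 == pytest.approx(1.0)
    assert w3 == 1e-6  # documented floor for |r| = 1
    with pytest.raises(ValidationError):
        marker_effect(np.ones(20), g[:20])


def test_weighted_correlation_reduces_to_pearson(rng):
    x = rng.normal(size=25)
    y = rng.normal(size=25)
    r_w, p_w = weighted_correlation(x, y, np.ones(25))
    r = np.corrcoef(x, y)[0, 1]
    assert r_w == pytest.approx(r, abs=1e-12)
    # vanishing third weight -> correlation of the remaining two points
    r3, _ = weighted_correlation(x[:3], y[:3], np.array([1.0, 1.0, 1e-12]))
    assert abs(r3) == pytest.approx(1.0, abs=1e-5)


def test_weighted_correlation_brute_force_oracle(rng):
    """Direct weighted-moment formula evaluated independently."""
    for _ in range(10):
        x = rng.normal(size=20)
        y = rng.normal(size=20)
        w = rng.uniform(0.1, 5.0, 20)
        r_w, _ = weighted_correlation(x, y, w)
        sw = w.sum()
        mx = sum(wi * xi for wi, xi in zip(w, x)) / sw
        my = sum(wi * yi for wi, yi in zip(w, y)) / sw
        cov = sum(wi * (xi - mx) * (yi - my) for wi, xi, yi in zip(w, x, y)) / sw
        vx = sum(wi * (xi - mx) ** 2 for wi, xi in zip(w, x)) / sw
        vy = sum(wi * (yi - my) ** 2 for wi, yi in zip(w, y)) / sw
        assert r_w == pytest.approx(cov / np.sqrt(vx * vy), abs=1e-12)


@settings(max_examples=30, deadline=None)
@given(st.floats(0.1, 100.0))
def test_weighted_correlation_scale_invariant(c):
    rng = np.random.default_rng(5)
    x = rng.normal(size=12)
    y = rng.normal(size=12)
    w = rng.uniform(0.5, 2.0, 12)
    r1, p1 = weighted_correlation(x, y, w)
    r2, p2 = weighted_correlation(x, y, c * w)
    assert r1 == pytest.approx(r2, abs=1e-12)
    assert p1 == pytest.approx(p2, abs=1e-12)


def test_qtl_effect_correlation_proportional_effects(genome):
    """Gene and condition built from the same six markers with
    proportional effects give r_weighted near 1."""
    from eqtlgrowth import simulate as sim
    from eqtlgrowth.datatypes import PhenotypeMatrix
    import pandas as pd

    gm = sim.simulate_cross(genome, 1000, genome.total_bp // 300, seed=40)
    rng = np.random.default_rng(41)
    picks = np.linspace(5, gm.n_markers - 5, 6).astype(int)
    eff = np.array([0.5, 0.4, 0.3, 0.2, 0.1, 0.05])
    G = gm.values[:, picks].astype(float)
    e = G @ eff + rng.normal(0, 0.6, 1000)
    w = G @ (1.2 * eff) + rng.normal(0, 0.6, 1000)
    expr = PhenotypeMatrix(e[:, None], ["gene"], gm.segregant_ids)
    growth = PhenotypeMatrix(w[:, None], ["cond"], gm.segregant_ids, kind="growth")
    eqtl = pd.DataFrame(
        {
            "trait_id": "gene",
            "peak_marker_id": [gm.marker_ids[j] for j in picks],
            "chrom": 1, "peak_pos_bp": 1, "ci_start_bp": 1, "ci_end_bp": 1,
            "lod": 10.0, "effect_r": eff, "qtl_class": "trans-eQTL",
        }
    )
    table = qtl_effect_correlations(expr, growth, gm, eqtl)
    assert len(table) == 1
    assert table["r_weighted"].iloc[0] >= 0.95
    assert table["n_eqtls"].iloc[0] == 6


def test_qtl_effect_correlation_requires_three_eqtls(desk_std, desk_data):
    table = qtl_effect_correlations(
        desk_std["expr"], desk_std["growth"], desk_data["genotypes"], desk_data["eqtls"]
    )
    assert (table["n_eqtls"] >= 3).all()
    few = set(desk_data["eqtls"].groupby("trait_id").size()[lambda s: s < 3].index)
    assert few <= set(table.attrs["skipped_genes"])


def test_collinear_three_point_weighted_correlation():
    x = np.array([1.0, 2.0, 3.0])
    y = 2.0 * x
    r, p = weighted_correlation(x, y, np.array([1.0, 2.0, 0.5]))
    assert r == pytest.approx(1.0)
    assert np.isfinite(p)


def test_lod_closed_forms(rng):
    assert lod_from_r(np.array(0.0), 100) == 0.0
    assert lod_from_r(np.array(np.sqrt(0.1)), 100) == pytest.approx(
        50 * np.log10(1 / 0.9), abs=1e-9
    )


def test_lod_scan_recovers_strong_qtl(genome):
    """Peak of a strong simulated QTL lands within +/-5 markers of truth."""
    from eqtlgrowth import simulate as sim

    gm = sim.simulate_cross(genome, 500, genome.total_bp // 400, seed=50)
    rng = np.random.default_rng(51)
    hits = 0
    reps = 40
    true_j = gm.n_markers // 3
    for b in range(reps):
        y = 0.5 * gm.values[:, true_j] + rng.normal(0, np.sqrt(1 - 0.25), 500)
        scan = lod_scan(y, gm)
        if abs(scan.peak_index - true_j) <= 5:
            hits += 1
    assert hits / reps >= 0.95
    scan = lod_scan(y, gm)
    assert scan.ci_start_bp <= gm.markers["pos_bp"].iloc[scan.peak_index] <= scan.ci_end_bp
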