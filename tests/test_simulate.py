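"""Synthetic cross generator: map function, architecture, phenotypes."""

import numpy as np
import pandas as pd
import pytest

from eqtlgrowth import simulate as sim
from eqtlgrowth.datatypes import ValidationError


def two_marker_genome(cm_apart: float):
    """One chromosome holding two markers cm_apart centimorgans apart."""
    bp = max(int(cm_apart / 0.4 * 1000), 2)
    return sim.GenomeModel(chrom_lengths_bp=(bp + 10,)), bp


def test_zero_distance_markers_are_identical():
    genome = sim.GenomeModel(chrom_lengths_bp=(1000,))
    markers = pd.DataFrame(
        {"id": ["a", "b"], "chrom": [1, 1], "pos_bp": [100, 200], "pos_cM": [0.5, 0.5]}
    )
    gm = sim.simulate_cross(genome, 500, 100, seed=0, markers=markers)
    np.testing.assert_array_equal(gm.values[:, 0], gm.values[:, 1])


def test_haldane_recombination_fraction_at_50_cM():
    genome = sim.GenomeModel(chrom_lengths_bp=(200_000,))
    markers = pd.DataFrame(
        {"id": ["a", "b"], "chrom": [1, 1], "pos_bp": [1, 125_001],
         "pos_cM": [0.0, 50.0]}
    )
    gm = sim.simulate_cross(genome, 10_000, 1, seed=1, markers=markers)
    observed = (gm.values[:, 0] != gm.values[:, 1]).mean()
    expected = 0.5 * (1 - np.exp(-1.0))  # ~0.3161
    assert abs(observed - expected) < 0.015


def test_cross_chromosome_independence_and_allele_frequency():
    genome = sim.GenomeModel(chrom_lengths_bp=(50_000, 50_000))
    gm = sim.simulate_cross(genome, 10_000, 25_000, seed=2)
    first = gm.values[:, 0].astype(float)
    other_chrom = np.nonzero((gm.markers["chrom"] == 2).to_numpy())[0][0]
    assert abs(np.corrcoef(first, gm.values[:, other_chrom].astype(float))[0, 1]) < 0.05
    freqs = (gm.values == 1).mean(axis=0)
    assert np.all(np.abs(freqs - 0.5) < 0.03)


def test_invalid_simulation_inputs_raise():
    genome = sim.GenomeModel(chrom_lengths_bp=(1000,))
    with pytest.raises(ValidationError):
        sim.simulate_cross(genome, 10, 0, seed=0)
    with pytest.raises(ValidationError):
        sim.simulate_cross(genome, 0, 100, seed=0)
    with pytest.raises(ValidationError):
        sim.GenomeModel(chrom_lengths_bp=(0,))


def test_null_architecture_gives_pure_noise(cross):
    cfg = sim.ArchitectureConfig(n_hotspots=0, frac_local=0.0)
    arch = sim.build_architecture(cross, 20, 3, cfg, seed=3)
    assert all(idx.size == 0 for idx, _, _ in arch.gene_effects.values())
    assert np.allclose(arch.noise_sd_gene, 1.0)
    expr, _ = sim.generate_phenotypes(cross, arch, seed=4)
    # phenotypes carry covariate structure + noise only; no marker effect
    scores = np.stack(
        [arch.genetic_score(cross, g) for g in arch.gene_ids], axis=1
    )
    assert np.allclose(scores, 0.0)


def test_all_gqtls_at_hotspots_when_fraction_is_one(cross):
    cfg = sim.ArchitectureConfig(frac_gqtl_at_hotspots=1.0)
    arch = sim.build_architecture(cross, 50, 6, cfg, seed=5)
    hot = set(arch.hotspot_marker_idx.tolist())
    for cond in arch.condition_ids:
        idx, _ = arch.cond_effects[cond]
        assert set(idx.tolist()) <= hot


def test_realized_heritability_matches_target(genome):
    """Regression of phenotype on the true generative score recovers h2."""
    gm = sim.simulate_cross(genome, 1000, genome.total_bp // 500, seed=6)
    arch = sim.build_architecture(gm, 60, 4, seed=7)
    expr, growth = sim.generate_phenotypes(gm, arch, seed=8)
    worst = 0.0
    for j, g in enumerate(arch.gene_ids):
        if arch.gene_h2[j] == 0:
            continue
        score = arch.genetic_score(gm, g)
        resid = expr.values[:, j] - arch.batch_offsets[arch.batch] \
            - arch.od_coef[j] * (arch.od600 - arch.od600.mean())
        r2 = np.corrcoef(score, resid)[0, 1] ** 2
        h2_hat = r2 * resid.var() / 1.0  # phenotype variance ~ 1 by construction
        worst = max(worst, abs(h2_hat - arch.gene_h2[j]))
    assert worst < 0.05 + 0.05  # sampling noise allowance at n=1000


def test_zero_noise_phenotypes_equal_genetic_scores(cross):
    arch = sim.build_architecture(cross, 30, 3, seed=9)
    arch.noise_sd_gene[:] = 0.0
    arch.noise_sd_cond[:] = 0.0
    arch.batch_offsets[:] = 0.0
    arch.od_coef[:] = 0.0
    arch.missing_rate = 0.0
    expr, growth = sim.generate_phenotypes(cross, arch, seed=10)
    for j, g in enumerate(arch.gene_ids):
        np.testing.assert_allclose(
            expr.values[:, j], arch.genetic_score(cross, g), atol=1e-12
        )
    for j, c in enumerate(arch.condition_ids):
        np.testing.assert_allclose(
            growth.values[:, j], arch.genetic_score(cross, c), atol=1e-12
        )


def test_shared_locus_construction_yields_positive_correlation(genome):
    """A gene and a condition driven by the same hotspot with the same
    sign must show a positive, significant genetic correlation."""
    gm = sim.simulate_cross(genome, 1000, genome.total_bp // 400, seed=20)
    arch = sim.build_architecture(gm, 10, 2, sim.ArchitectureConfig(n_hotspots=2), seed=21)
    j = int(arch.hotspot_marker_idx[0])
    g0, c0 = arch.gene_ids[0], arch.condition_ids[0]
    arch.gene_effects[g0] = (np.array([j]), np.array([0.5]), np.array([False]))
    arch.cond_effects[c0] = (np.array([j]), np.array([0.5]))
    arch.noise_sd_gene[0] = np.sqrt(1 - 0.25)
    arch.noise_sd_cond[0] = np.sqrt(1 - 0.25)
    expr, growth = sim.generate_phenotypes(gm, arch, seed=22)
    e = expr.values[:, 0] - arch.batch_offsets[arch.batch] \
        - arch.od_coef[0] * (arch.od600 - arch.od600.mean())
    w = growth.values[:, 0]
    ok = ~np.isnan(w)
    r = np.corrcoef(e[ok], w[ok])[0, 1]
    assert r > 0.1  # expected ~0.25; significance is clear at n=1000


def test_regeneration_identity_from_truth_frame(cross, desk_data):
    """The truth file plus the seed reproduce the phenotypes exactly."""
    arch = desk_data["arch"]
    frame = arch.to_frame()
    back = sim.TraitArchitecture.from_frame(frame, cross)
    e1, w1 = sim.generate_phenotypes(cross, arch, seed=13)
    e2, w2 = sim.generate_phenotypes(cross, back, seed=13)
    np.testing.assert_allclose(e1.values, e2.values, atol=1e-12)
    np.testing.assert_array_equal(np.isnan(w1.values), np.isnan(w2.values))
    np.testing.assert_allclose(
        w1.values[~np.isnan(w1.values)], w2.values[~np.isnan(w2.values)], atol=1e-12
    )


def test_causal_marker_correlation_converges_to_effect(genome):
    """At a causal marker, corr(phenotype, genotype) approaches the
    standardized effect size as n grows."""
    gm = sim.simulate_cross(genome, 4000, genome.total_bp // 300, seed=30)
    arch = sim.build_architecture(gm, 5, 1, sim.ArchitectureConfig(n_hotspots=1), seed=31)
    g0 = arch.gene_ids[0]
    j = int(arch.hotspot_marker_idx[0])
    arch.gene_effects[g0] = (np.array([j]), np.array([0.4]), np.array([False]))
    arch.noise_sd_gene[0] = np.sqrt(1 - 0.16)
    arch.batch_offsets[:] = 0.0
    arch.od_coef[:] = 0.0
    expr, _ = sim.generate_phenotypes(gm, arch, seed=32)
    r = np.corrcoef(expr.values[:, 0], gm.values[:, j].astype(float))[0, 1]
    assert abs(r - 0.4) < 0.05


def test_truth_qtl_tables_are_valid_and_cover_truth(desk_data):
    from eqtlgrowth.datatypes import validate_hotspot_table, validate_qtl_table

    eqtl, gqtl, hotspot = desk_data["eqtls"], desk_data["gqtls"], desk_data["hotspots"]
    validate_qtl_table(eqtl)
    validate_qtl_table(gqtl)
    validate_hotspot_table(hotspot)
    arch = desk_data["arch"]
    n_true = sum(idx.size for idx, _, _ in arch.gene_effects.values())
    # detected-only catalog: a subset of the true effects, never extras
    assert 0 < len(eqtl) <= n_true
    mk = desk_data["genotypes"]
    for _, row in eqtl.sample(25, random_state=0).iterrows():
        idx, _, _ = arch.gene_effects[row["trait_id"]]
        assert mk.marker_indices([row["peak_marker_id"]])[0] in idx
    assert (eqtl["lod"] >= 2.5).all()
    assert (hotspot["n_target_genes"].to_numpy()
            == [len(arch.hotspot_targets[int(j)]) for j in
                desk_data["genotypes"].marker_indices(hotspot["peak_marker_id"])]).all()
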