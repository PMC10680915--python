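"""Sign-split enrichment, bidirectional resolution, clustering, signatures."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from eqtlgrowth.datatypes import ValidationError
from eqtlgrowth.enrich import (
    cluster_traits,
    fold_matrix,
    resolve_bidirectional,
    sign_split_enrichment,
    signature_average,
)

UNIVERSE = [f"g{i}" for i in range(2000)]


def corr_frame(sig_pos, sig_neg=(), cond="c1"):
    rows = []
    sig_pos, sig_neg = set(sig_pos), set(sig_neg)
    for g in UNIVERSE:
        if g in sig_pos:
            r, q = 0.5, 0.01
        elif g in sig_neg:
            r, q = -0.5, 0.01
        else:
            r, q = 0.0, 0.9
        rows.append({"gene_id": g, "condition_id": cond, "r": r, "q": q})
    return pd.DataFrame(rows)


def test_perfect_overlap_maximal_fold():
    term = set(UNIVERSE[:100])
    recs = sign_split_enrichment(
        corr_frame(term), {"T": term}, UNIVERSE, p_display=1.0
    )
    row = recs[(recs["term_id"] == "T") & (recs["direction"] == "positive")].iloc[0]
    assert row["fold"] == pytest.approx(len(UNIVERSE) / 100)
    assert row["fet_p"] < 1e-100


def test_disjoint_sets_zero_fold():
    recs = sign_split_enrichment(
        corr_frame(UNIVERSE[:100]), {"T": set(UNIVERSE[100:200])}, UNIVERSE,
        p_display=1.01,
    )
    row = recs[recs["direction"] == "positive"].iloc[0]
    assert row["fold"] == 0
    assert row["fet_p"] == pytest.approx(1.0)


def test_fet_matches_hypergeometric_tail():
    """FET p equals direct hypergeometric tail summation."""
    # k=30 of 100 significant; term 200 of 2000 universe
    term = set(UNIVERSE[:30]) | set(UNIVERSE[500:670])
    sig = set(UNIVERSE[:30]) | set(UNIVERSE[1000:1070])
    recs = sign_split_enrichment(corr_frame(sig), {"T": term}, UNIVERSE, p_display=1.01)
    p = recs[recs["direction"] == "positive"]["fet_p"].iloc[0]
    # oracle: sum hypergeometric pmf over k..min(K, n)
    M, K, n = 2000, 200, 100
    oracle = sum(stats.hypergeom.pmf(x, M, K, n) for x in range(30, min(K, n) + 1))
    assert p == pytest.approx(oracle, rel=1e-9)


def test_fet_equals_tail_sum_on_small_margins(rng):
    from scipy.stats import fisher_exact, hypergeom

    for _ in range(20):
        M = int(rng.integers(10, 50))
        K = int(rng.integers(1, M))
        n = int(rng.integers(1, M))
        k = int(rng.integers(max(0, K + n - M), min(K, n) + 1))
        table = [[k, n - k], [K - k, M - n - K + k]]
        _, p = fisher_exact(table, alternative="greater")
        oracle = sum(hypergeom.pmf(x, M, K, n) for x in range(k, min(K, n) + 1))
        assert p == pytest.approx(oracle, rel=1e-8, abs=1e-12)


def test_expected_count_identity():
    term = set(UNIVERSE[:150])
    recs = sign_split_enrichment(
        corr_frame(UNIVERSE[:80]), {"T": term}, UNIVERSE, p_display=1.01
    )
    row = recs[recs["direction"] == "positive"].iloc[0]
    assert row["expected"] == pytest.approx(80 * 150 / 2000)


def test_resolve_bidirectional_rules():
    recs = pd.DataFrame(
        [
            {"condition_id": "c", "term_id": "t1", "direction": "positive",
             "log2_fold": 1.2, "fet_p": 1e-4, "fold": 2.3},
            {"condition_id": "c", "term_id": "t1", "direction": "negative",
             "log2_fold": -0.8, "fet_p": 1e-4, "fold": 0.6},
            {"condition_id": "c", "term_id": "t2", "direction": "negative",
             "log2_fold": 0.9, "fet_p": 1e-4, "fold": 1.9},
            # symmetric tie on t3 -> positive kept
            {"condition_id": "c", "term_id": "t3", "direction": "positive",
             "log2_fold": 1.0, "fet_p": 1e-4, "fold": 2.0},
            {"condition_id": "c", "term_id": "t3", "direction": "negative",
             "log2_fold": 1.0, "fet_p": 1e-4, "fold": 2.0},
        ]
    )
    out = resolve_bidirectional(recs)
    t1 = out[out["term_id"] == "t1"]
    assert len(t1) == 1 and t1["direction"].iloc[0] == "positive"
    assert len(out[out["term_id"] == "t2"]) == 1  # unchanged single direction
    t3 = out[out["term_id"] == "t3"]
    assert t3["direction"].iloc[0] == "positive"


def test_cluster_separable_opposite_profiles(rng):
    profiles = rng.normal(size=(1, 20))
    M = pd.DataFrame(
        np.vstack([np.repeat(profiles, 4, axis=0) + rng.normal(0, 0.05, (4, 20)),
                   np.repeat(-profiles, 4, axis=0) + rng.normal(0, 0.05, (4, 20))]),
        index=[f"t{i}" for i in range(8)],
    )
    labels, _ = cluster_traits(M, 2, seed=1)
    assert len(set(labels.iloc[:4])) == 1
    assert len(set(labels.iloc[4:])) == 1
    assert labels.iloc[0] != labels.iloc[7]


def test_cluster_degenerate_and_errors(rng):
    M = pd.DataFrame(rng.normal(size=(5, 6)), index=[f"t{i}" for i in range(5)])
    labels, wss = cluster_traits(M, 5, seed=0)
    assert sorted(labels) == [0, 1, 2, 3, 4]
    assert wss == pytest.approx(0.0, abs=1e-9)
    with pytest.raises(ValidationError):
        cluster_traits(M, 6)


def test_signature_average_identities(rng):
    genes = UNIVERSE[:100]
    rs = rng.normal(size=100)
    corr = pd.DataFrame({"gene_id": genes, "condition_id": "c", "r": rs, "q": 0.5})
    groups = {"all": set(genes), "first": set(genes[:40]), "rest": set(genes[40:]),
              "empty": set()}
    out = signature_average(corr, groups).set_index("group")
    assert out.loc["all", "mean_r"] == pytest.approx(rs.mean(), abs=1e-12)
    # partition identity: sum of size x group-mean = universe total
    total = (
        out.loc["first", "n_genes"] * out.loc["first", "mean_r"]
        + out.loc["rest", "n_genes"] * out.loc["rest", "mean_r"]
    )
    assert total == pytest.approx(rs.sum(), abs=1e-9)
    assert bool(out.loc["empty", "empty"])
    assert np.isnan(out.loc["empty", "mean_r"])
    # brute-force per-gene average oracle
    brute = np.mean([rs[genes.index(g)] for g in genes[:40]])
    assert out.loc["first", "mean_r"] == pytest.approx(brute, abs=1e-12)


def test_planted_archetypes_recovered(desk_data, desk_std):
    """Condition groups with opposite hotspot responses cluster apart."""
    from sklearn.metrics import adjusted_rand_score

    from eqtlgrowth.gencor import genetic_correlations

    gencor = genetic_correlations(desk_std["expr"], desk_std["growth"])
    recs = sign_split_enrichment(
        gencor, desk_data["gene_sets"], desk_std["expr"].trait_ids
    )
    fm = fold_matrix(recs, desk_std["growth"].trait_ids)
    scores = []
    for seed in range(5):
        labels, _ = cluster_traits(fm, 2, seed=seed)
        scores.append(adjusted_rand_score(desk_data["arch"].archetype, labels))
    assert np.mean(scores) > 0.8
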