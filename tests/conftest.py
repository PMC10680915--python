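"""Shared fixtures: a small simulated cross with known architecture.

Everything is generated programmatically at test time; session scope keeps
the expensive simulations to one run per session.
"""

from __future__ import annotations

import numpy as np
import pytest

from eqtlgrowth import simulate as sim
from eqtlgrowth.preprocess import correct_expression, standardize


@pytest.fixture(scope="session")
def genome():
    return sim.GenomeModel()


@pytest.fixture(scope="session")
def cross(genome):
    """200 segregants x ~500 markers."""
    return sim.simulate_cross(genome, 200, genome.total_bp // 500, seed=11)


@pytest.fixture(scope="session")
def desk_data(genome, cross):
    """Default desk-scale dataset with full ground truth."""
    arch = sim.build_architecture(cross, 300, 8, seed=12)
    expr, growth = sim.generate_phenotypes(cross, arch, seed=13)
    eqtl, gqtl, hotspot = sim.truth_qtl_tables(cross, expr, growth, arch)
    return {
        "genotypes": cross,
        "arch": arch,
        "expression": expr,
        "growth": growth,
        "eqtls": eqtl,
        "gqtls": gqtl,
        "hotspots": hotspot,
        "gene_sets": sim.gene_set_fixtures(arch),
    }


@pytest.fixture(scope="session")
def desk_std(desk_data):
    """Covariate-corrected, standardized phenotypes of the desk dataset."""
    corrected, _ = correct_expression(desk_data["expression"])
    return {
        "expr": standardize(corrected),
        "growth": standardize(desk_data["growth"]),
    }


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
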