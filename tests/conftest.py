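import numpy as np
import pytest
from hypothesis import settings

from gdagnet import (
    INSTRUMENT,
    TRAIT,
    DEFAULT_EDGE_WEIGHTS,
    FATTY_ACIDS,
    SimulationConfig,
    joint_covariance,
    learn_structure,
)

settings.register_profile("ci", derandomize=True, max_examples=40, deadline=None)
settings.load_profile("ci")


#: Abstract unit-variance instruments on the two dietary source metabolites,
#: used whenever a test needs the oracle (population-covariance) pipeline.
SOURCE_INSTRUMENTS = {
    "IV_Palmitoleate": {"Palmitoleate": 0.6},
    "IV_Margarate": {"Margarate": 0.6},
}


def fixture_tiers():
    return {i: INSTRUMENT for i in SOURCE_INSTRUMENTS} | {t: TRAIT for t in FATTY_ACIDS}


@pytest.fixture(scope="session")
def fixture_joint_cov():
    return joint_covariance(FATTY_ACIDS, DEFAULT_EDGE_WEIGHTS, SOURCE_INSTRUMENTS)


@pytest.fixture(scope="session")
def oracle_result(fixture_joint_cov):
    """Structure learned from exact population moments of the default cohort."""
    return learn_structure(cov=fixture_joint_cov, tiers=fixture_tiers(), max_cond=None)


@pytest.fixture(scope="session")
def small_cohort():
    """A small simulated cohort shared by read-only tests."""
    from gdagnet import simulate_cohort

    config = SimulationConfig(n_samples=400, n_snps=60, block_size=6, seed=7)
    genotypes, traits, truth = simulate_cohort(config)
    return config, genotypes, traits, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


def random_dag(rng, n_nodes, p_edge=0.35):
    """A random DAG over string-named nodes via an upper-triangular mask."""
    from gdagnet import CausalGraph

    names = [f"v{i}" for i in range(n_nodes)]
    edges = [
        (names[i], names[j])
        for i in range(n_nodes)
        for j in range(i + 1, n_nodes)
        if rng.random() < p_edge
    ]
    return CausalGraph(nodes=names, edges=edges)
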