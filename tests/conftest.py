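import numpy as np
import pytest

from poolqtl import (
    CrossConfig,
    simulate_cross,
    select_pool,
    simulate_pool_counts,
)


@pytest.fixture(scope="session")
def default_population():
    """The default scaled cross (3 x 300 kb, 900 markers, 4 QTLs), seed 0."""
    return simulate_cross(CrossConfig(seed=0))


@pytest.fixture(scope="session")
def selected_counts(default_population):
    pop = default_population
    idx = select_pool(pop, 22)
    return simulate_pool_counts(pop, idx)


@pytest.fixture(scope="session")
def null_counts(default_population):
    pop = default_population
    idx = select_pool(pop, 237, mode="random")
    return simulate_pool_counts(pop, idx, seed=pop.config.seed + 1000)


@pytest.fixture(scope="session")
def tiny_config():
    """A one-chromosome cross small enough for exhaustive checks."""
    return CrossConfig(
        chromosomes=(("chrI", 50_000),),
        marker_spacing_bp=1_000,
        qtls=(("chrI", 25_000, 1.0),),
        n_segregants=100,
        pool_sizes=(22, 32, 60),
        seed=7,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
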