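import numpy as np
import pytest

from lncestro.config import benchmark_config
from lncestro.simdata import SimulatedStudy, simulate_study


@pytest.fixture(scope="session")
def bench_study() -> SimulatedStudy:
    """The seeded 500-gene benchmark study, shared read-only across tests."""
    return simulate_study(benchmark_config(seed=1))


@pytest.fixture(scope="session")
def tiny_config():
    """A fast study small enough for end-to-end pipeline tests."""
    return benchmark_config(seed=11, n_genes=60, n_up=10, n_down=15)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
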