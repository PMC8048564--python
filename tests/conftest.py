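import numpy as np
import pytest

from mlhgrn import RunConfig
from mlhgrn.simulate import (
    simulate_expression,
    simulate_genome_and_peaks,
    simulate_network_truth,
)


@pytest.fixture(scope="session")
def default_truth():
    """The standard benchmark: 20 direct targets (5 TFs), 50 layer-3, 200 decoys."""
    return simulate_network_truth(20, 0.25, 50, 200, seed=1)


@pytest.fixture(scope="session")
def default_matrix(default_truth):
    return simulate_expression(default_truth, 25)


@pytest.fixture(scope="session")
def default_dap(default_truth):
    return simulate_genome_and_peaks(default_truth)


@pytest.fixture(scope="session")
def small_truth():
    """A fast 8-gene benchmark for unit-level checks."""
    return simulate_network_truth(8, 0.25, 10, 30, seed=7)


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def config():
    return RunConfig()
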