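import numpy as np
import pytest

from mitodelim import SimConfig, distance_matrix, simulate


@pytest.fixture(scope="session")
def default_dataset():
    """Synthetic two-group dataset at the standard study conditions."""
    return simulate(SimConfig(seed=1))


@pytest.fixture(scope="session")
def default_dm(default_dataset):
    return distance_matrix(default_dataset.alignment)


@pytest.fixture(scope="session")
def small_dataset():
    """A reduced dataset for fast unit tests of downstream stages."""
    return simulate(
        SimConfig(
            length=200,
            group_sizes=(14, 8),
            n_diagnostic=4,
            seed=7,
        )
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
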