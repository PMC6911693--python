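import numpy as np
import pytest

from pseudits.synthetic_data import SimConfig, simulate_ancestors, simulate_dataset


@pytest.fixture(scope="session")
def ancestors():
    """(short_ref, long_ref, regions) from a fixed-seed simulation."""
    return simulate_ancestors(SimConfig(seed=11))


@pytest.fixture(scope="session")
def small_dataset():
    """A small simulated study used by several integration tests."""
    return simulate_dataset(SimConfig(seed=7, n_accessions=10))


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
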