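import numpy as np
import pytest

from phagecodon import simulate as sim
from phagecodon.codon import adaptiveness_weights


@pytest.fixture(scope="session")
def host_table():
    return sim.synthetic_host_table()


@pytest.fixture(scope="session")
def weights(host_table):
    return adaptiveness_weights(host_table)


@pytest.fixture(scope="session")
def small_config():
    """A scaled-down generator config for fast end-to-end tests."""
    return sim.SimConfig(seed=4242, n_genomes=5)


@pytest.fixture(scope="session")
def small_dataset(small_config, host_table):
    return sim.generate_dataset(small_config, host_table)


@pytest.fixture()
def rng():
    return np.random.default_rng(20260922)
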