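import numpy as np
import pytest

from nexosim.network import NetworkConfig, build_network, test_network_config


@pytest.fixture(scope="session")
def small_net():
    """The reduced 3-column, 30-neuron network used throughout the suite."""
    return build_network(test_network_config(), rng_seed=0)


@pytest.fixture(scope="session")
def tiny_net():
    """A very small dense network (3 columns x 4 neurons) for operator tests."""
    cfg = NetworkConfig(
        composition=((2, "RS", 2), (4, "FS", 1), (5, "IB", 1)),
        densities={"RS": 0.6, "IB": 0.6, "FS": 0.6, "LTS": 0.6},
        inter_column_scale=0.5,
    )
    return build_network(cfg, rng_seed=1)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
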