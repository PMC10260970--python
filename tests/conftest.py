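import numpy as np
import pytest

from fosnet import FunctionalNetwork
from fosnet.regions import default_registry


@pytest.fixture(scope="session")
def registry():
    return default_registry()


@pytest.fixture(scope="session")
def nodes30(registry):
    return registry.all_nodes()[:30]


def make_network(nodes, weights):
    return FunctionalNetwork(nodes=list(nodes), weights=np.asarray(weights, dtype=float))


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
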