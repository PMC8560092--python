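import numpy as np
import pytest

from pkacn.network import (
    build_base_network,
    build_extended_network,
    default_parameters,
)


@pytest.fixture(scope="session")
def base_net():
    return build_base_network()


@pytest.fixture(scope="session")
def ext_net():
    return build_extended_network(0.85)


@pytest.fixture()
def defaults():
    return default_parameters()


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
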