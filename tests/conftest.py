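import numpy as np
import pytest

from vkbl import build_network, default_parameters


@pytest.fixture(scope="session")
def params05():
    """Default rates with the control parameter well below the onset."""
    return default_parameters(0.05)


@pytest.fixture(scope="session")
def network05(params05):
    return build_network(params05)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20120411)
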