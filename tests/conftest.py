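import numpy as np
import pytest

from onca import landscape as L


@pytest.fixture(scope="session")
def stack64():
    return L.generate_layers(1, 64, 64)


@pytest.fixture(scope="session")
def truth64(stack64):
    return L.default_truth(stack64)


@pytest.fixture(scope="session")
def stack32():
    return L.generate_layers(3, 32, 32)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
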