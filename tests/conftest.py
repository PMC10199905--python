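import numpy as np
import pytest

from emoload.montage import generate_montage


@pytest.fixture(scope="session")
def low32():
    return generate_montage("low32")


@pytest.fixture(scope="session")
def high24():
    return generate_montage("high24")


@pytest.fixture(scope="session")
def shared():
    return generate_montage("shared")


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)
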