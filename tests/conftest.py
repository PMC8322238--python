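import numpy as np
import pytest

from musictrf.compare import grid_layout


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def grid8():
    return grid_layout(8, 8)


@pytest.fixture(scope="session")
def grid4():
    return grid_layout(4, 4)
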