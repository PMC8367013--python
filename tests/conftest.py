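import numpy as np
import pytest


@pytest.fixture
def toy_Y():
    """3x2 worked example used throughout: row variances 2, 2, 2."""
    return np.array([[1.0, 3.0], [2.0, 4.0], [5.0, 7.0]])


@pytest.fixture
def toy_nu():
    return np.array([0.0, 1.0, 2.0])


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
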