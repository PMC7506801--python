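import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_xy(rng):
    """A 30x8 regression problem with 3 informative columns."""
    X = rng.uniform(1.0, 10.0, size=(30, 8)) + rng.normal(size=(30, 8))
    b = np.array([3.0, 0.0, 5.0, 0.0, 0.0, 1.5, 0.0, 0.0])
    y = X @ b + rng.normal(scale=0.5, size=30)
    return X, y
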