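import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture
def linear_data(rng):
    """n > p full-rank design with a strong linear signal."""
    X = rng.standard_normal((50, 5))
    beta = np.array([1.0, -2.0, 0.5, 0.0, 3.0])
    y = X @ beta + 0.1 * rng.standard_normal(50)
    return X, y, beta
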