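import numpy as np
import pytest

from ssvslab.design import standardize


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture(scope="session")
def small_design():
    """20 x 3 design with one strong, one moderate, one null predictor."""
    rng = np.random.default_rng(42)
    X = rng.standard_normal((20, 3))
    y = 1.2 * X[:, 0] + 0.5 * X[:, 1] + rng.standard_normal(20)
    return standardize(X, y)


@pytest.fixture(scope="session")
def regression_design():
    """60 x 6 design with known sparse signal, comfortable n > p."""
    rng = np.random.default_rng(7)
    X = rng.standard_normal((60, 6))
    beta = np.array([1.5, 0.0, 0.8, 0.0, 0.0, 0.4])
    y = X @ beta + rng.standard_normal(60)
    return standardize(X, y)
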