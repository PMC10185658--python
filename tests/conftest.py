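import numpy as np
import pytest

from isnsig.networks import DataMatrix


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def small_data(rng):
    """12 individuals x 4 correlated features."""
    cov = np.array([[1.0, 0.6, 0.3, 0.1],
                    [0.6, 1.0, 0.4, 0.2],
                    [0.3, 0.4, 1.0, 0.5],
                    [0.1, 0.2, 0.5, 1.0]])
    chol = np.linalg.cholesky(cov)
    values = rng.standard_normal((12, 4)) @ chol.T
    return DataMatrix(values, [f"i{n}" for n in range(12)],
                      ["a", "b", "c", "d"])
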