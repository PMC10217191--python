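import numpy as np
import pytest

from gaussfm import LabeledDataset


@pytest.fixture
def toy_linear() -> LabeledDataset:
    """Two orthogonal unit samples: x1=(1,0), y1=1; x2=(0,1), y2=-1.

    Hand-worked quadratic coefficients: beta = 1, alpha = (-1, 1),
    M = diag(0.5, 0.5); exact minimizer (1, -1) with objective value 0.
    """
    return LabeledDataset(
        np.array([[1.0, 0.0], [0.0, 1.0]]), np.array([1.0, -1.0]), "regression"
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
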