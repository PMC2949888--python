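import numpy as np
import pytest

from neffnet import double_standardize
from neffnet.io import ExpressionMatrix


@pytest.fixture
def toy_corr_2():
    """Two experiments with pairwise correlation 0.25."""
    return np.array([[1.0, 0.25], [0.25, 1.0]])


@pytest.fixture
def toy_corr_3():
    """Three experiments: corr_12 = 0.25, corr_13 = corr_23 = 0.75."""
    return np.array(
        [[1.0, 0.25, 0.75], [0.25, 1.0, 0.75], [0.75, 0.75, 1.0]]
    )


@pytest.fixture
def make_matrix():
    """Factory: random gaussian ExpressionMatrix of a given shape."""

    def _make(p, n, seed=0):
        rng = np.random.default_rng(seed)
        return ExpressionMatrix(
            rng.standard_normal((p, n)),
            [f"g{i}" for i in range(p)],
            [f"e{j}" for j in range(n)],
        )

    return _make


@pytest.fixture
def make_std_matrix(make_matrix):
    """Factory: doubly standardized matrix, converged to near machine
    precision so the gene/experiment moment identity holds exactly."""

    def _make(p, n, seed=0, tol=1e-10):
        X = make_matrix(p, n, seed)
        Xs, _ = double_standardize(X, tol=tol, max_iter=2000)
        return Xs

    return _make
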