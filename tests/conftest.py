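import numpy as np
import pytest

from sparsect.imaging_core import ImageGrid, _forward_diff


@pytest.fixture
def rng():
    return np.random.default_rng(20260923)


@pytest.fixture
def step_image():
    """n=2 image [[0,1],[2,3]] whose forward differences are known by hand."""
    return ImageGrid(np.array([[0.0, 1.0], [2.0, 3.0]]))


@pytest.fixture
def piecewise_truth():
    """An 8x8 piecewise-constant image with two nested plateaus."""
    t = np.zeros((8, 8))
    t[2:6, 2:6] = 1.0
    t[3:5, 3:5] = 0.5
    return ImageGrid(t)


def dense_difference_matrix(n: int) -> np.ndarray:
    """The (2n^2, n^2) matrix of the forward-difference operator.

    Built column-by-column by applying the operator to basis images; used
    only as an oracle for normal-equation solves and adjoint checks.
    """
    N = n * n
    D = np.zeros((2 * N, N))
    eye = np.eye(N)
    for k in range(N):
        D[:, k] = _forward_diff(eye[:, k].reshape(n, n)).reshape(-1)
    return D
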