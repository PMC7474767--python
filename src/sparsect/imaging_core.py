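"""Core imaging types and operators.

Images live on an n x n grid; the unknown of the reconstruction problem is
the flattened pixel vector f of length n^2.  Pixels are enumerated in
row-major order: pixel p = i*n + j (0-based) sits at row i, column j, so the
1-based index used in the mathematical description is p = (i-1)*n + j.

Gradient fields carry one 2-vector per pixel: the forward difference of the
image in the row direction and in the column direction.  They are the
natural home of the auxiliary splitting variable v and the Lagrange
multipliers lambda of the alternating-direction solver.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass(frozen=True)
class ImageGrid:
    """An n x n grayscale image.

    Values are dimensionless intensities, nominally in [0, 1] for phantoms
    but unrestricted during solver iterations.
    """

    values: np.ndarray

    def __post_init__(self) -> None:
        arr = np.asarray(self.values, dtype=float)
        if arr.ndim == 1:
            n = int(round(np.sqrt(arr.size)))
            if n * n != arr.size:
                raise ValueError("flat image length is not a perfect square")
            arr = arr.reshape(n, n)
        if arr.ndim != 2 or arr.shape[0] != arr.shape[1]:
            raise ValueError(f"image must be square, got shape {arr.shape}")
        object.__setattr__(self, "values", arr)

    @property
    def n(self) -> int:
        return self.values.shape[0]

    def flatten(self) -> np.ndarray:
        """Flatten to the length-n^2 pixel vector (row-major)."""
        return self.values.reshape(-1)

    @classmethod
    def from_flat(cls, flat: np.ndarray) -> "ImageGrid":
        return cls(np.asarray(flat, dtype=float))

    @classmethod
    def zeros(cls, n: int) -> "ImageGrid":
        return cls(np.zeros((n, n)))


@dataclass(frozen=True)
class GradientField:
    """Per-pixel 2-vectors over an n x n grid.

    ``pairs[p] = (row-step component, column-step component)`` for pixel p
    in row-major order.  Stored internally with shape (n, n, 2).
    """

    data: np.ndarray

    def __post_init__(self) -> None:
        arr = np.asarray(self.data, dtype=float)
        if arr.ndim == 2 and arr.shape[1] == 2:
            n = int(round(np.sqrt(arr.shape[0])))
            if n * n != arr.shape[0]:
                raise ValueError("pair count is not a perfect square")
            arr = arr.reshape(n, n, 2)
        if arr.ndim != 3 or arr.shape[0] != arr.shape[1] or arr.shape[2] != 2:
            raise ValueError(f"gradient field must have shape (n, n, 2), got {arr.shape}")
        object.__setattr__(self, "data", arr)

    @property
    def n(self) -> int:
        return self.data.shape[0]

    @property
    def pairs(self) -> np.ndarray:
        """View of shape (n^2, 2), pixel-major."""
        return self.data.reshape(-1, 2)

    @classmethod
    def zeros(cls, n: int) -> "GradientField":
        return cls(np.zeros((n, n, 2)))

    def magnitudes(self) -> np.ndarray:
        """Euclidean norm of each per-pixel pair, shape (n^2,)."""
        return np.linalg.norm(self.pairs, axis=1)


# ---------------------------------------------------------------------------
# Difference operators.  Forward differences with Neumann (replicate)
# boundaries: the out-of-range difference at the last row/column is zero, so
# the gradient of a constant image vanishes identically.
# ---------------------------------------------------------------------------


def _forward_diff(values: np.ndarray) -> np.ndarray:
    n = values.shape[0]
    g = np.zeros((n, n, 2))
    g[:-1, :, 0] = values[1:, :] - values[:-1, :]
    g[:, :-1, 1] = values[:, 1:] - values[:, :-1]
    return g


def _adjoint_diff(g: np.ndarray) -> np.ndarray:
    # Adjoint of _forward_diff: a negative divergence.  Components at the
    # last row/column of g carry zero coefficient in <Df, g> and do not
    # contribute.
    n = g.shape[0]
    out = np.zeros((n, n))
    out[1:, :] += g[:-1, :, 0]
    out[:-1, :] -= g[:-1, :, 0]
    out[:, 1:] += g[:, :-1, 1]
    out[:, :-1] -= g[:, :-1, 1]
    return out


def forward_difference(f: ImageGrid) -> GradientField:
    """Per-pixel forward differences D f.

    The pair at pixel (i, j) is ``(f[i+1, j] - f[i, j], f[i, j+1] - f[i, j])``
    with zeros where the neighbour falls off the grid.
    """
    return GradientField(_forward_diff(f.values))


def adjoint_difference(g: GradientField) -> ImageGrid:
    """The adjoint D^T of :func:`forward_difference`.

    Satisfies ``<Df, g> == <f, D^T g>`` for all f, g under the same boundary
    convention; needed for the gradient of the data-fitting subproblem.
    """
    return ImageGrid(_adjoint_diff(g.data))


def tv_norm(f: ImageGrid) -> float:
    """Isotropic total variation: sum over pixels of ||D_p f||_2."""
    return float(forward_difference(f).magnitudes().sum())


def grad_l0_count(f: ImageGrid, tol: float = 0.0) -> int:
    """Number of pixels whose gradient magnitude exceeds ``tol``.

    The direct sparsity measure that total variation relaxes; ``tol`` exists
    for reporting on inexact iterates, the solver itself produces exact
    zeros.
    """
    if tol < 0:
        raise ValueError("tol must be nonnegative")
    return int(np.count_nonzero(forward_difference(f).magnitudes() > tol))


def augmented_lagrangian_value(f, v, lam, sys, params) -> float:
    """Value of the augmented Lagrangian objective.

        (beta/2)||Phi f - u||^2 + sum_p ( ||v_p|| + alpha*[v_p != 0] )
        + (mu/2)||Df - v + lam||^2 + (gamma/2)||f||^2

    ``[v_p != 0]`` is an exact zero test: the prox map of the solver sets
    pairs to exact zero, so no tolerance is needed here.

    Parameters
    ----------
    f : ImageGrid
    v, lam : GradientField
    sys : ProjectionSystem
    params : SolverParams (uses alpha, beta, mu, gamma)
    """
    if not (f.n == v.n == lam.n):
        raise ValueError("dimension mismatch between f, v, lam")
    if sys.phi.shape[1] != f.n * f.n:
        raise ValueError("projection system does not match image size")
    resid = sys.phi @ f.flatten() - sys.u
    vmag = v.magnitudes()
    coupling = _forward_diff(f.values) - v.data + lam.data
    return float(
        0.5 * params.beta * resid @ resid
        + vmag.sum()
        + params.alpha * np.count_nonzero(vmag)
        + 0.5 * params.mu * np.sum(coupling * coupling)
        + 0.5 * params.gamma * f.flatten() @ f.flatten()
    )
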