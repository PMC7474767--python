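"""Synthetic phantoms and random limited-projection systems.

The experiments this package reproduces use the modified (high-contrast)
Shepp-Logan head phantom and a dense random sensing matrix in place of a
physical ray-driven projector: Phi has i.i.d. standard-normal entries and
m = round(sampling_ratio * n^2) rows, with sampling_ratio = 0.3 the
limited-data regime of interest.  Measurements are corrupted by Gaussian
noise scaled to the mean projection value,

    u = Phi f + noise_scale * mean(Phi f) * randn(m),

with noise_scale = 0.02 the study's condition.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .imaging_core import ImageGrid


@dataclass(frozen=True)
class ProjectionSystem:
    """A sensing matrix with noisy measurements.

    phi : (m, n^2) sensing matrix.
    u : length-m noisy measurement vector.
    noise_scale : the relative noise factor used to build u (metadata).
    epsilon : recorded ||e||_2 of the realized noise (metadata; the solver
        works with the quadratic penalty, never a hard constraint).
    """

    phi: np.ndarray
    u: np.ndarray
    noise_scale: float = 0.0
    epsilon: float = 0.0

    def __post_init__(self) -> None:
        phi = np.asarray(self.phi, dtype=float)
        u = np.asarray(self.u, dtype=float)
        if phi.ndim != 2:
            raise ValueError("phi must be a matrix")
        n = int(round(np.sqrt(phi.shape[1])))
        if n * n != phi.shape[1]:
            raise ValueError("phi column count must be a perfect square n^2")
        if u.shape != (phi.shape[0],):
            raise ValueError("u length must equal the number of rows of phi")
        object.__setattr__(self, "phi", phi)
        object.__setattr__(self, "u", u)

    @property
    def m(self) -> int:
        return self.phi.shape[0]

    @property
    def n(self) -> int:
        return int(round(np.sqrt(self.phi.shape[1])))


# Modified Shepp-Logan ellipse table (intensity, semi-axis a, semi-axis b,
# center x, center y, rotation in degrees), on the [-1, 1]^2 square.  This is
# the widely used high-contrast parameterization.
MODIFIED_SHEPP_LOGAN: tuple[tuple[float, float, float, float, float, float], ...] = (
    (1.00, 0.6900, 0.9200, 0.00, 0.0000, 0.0),
    (-0.80, 0.6624, 0.8740, 0.00, -0.0184, 0.0),
    (-0.20, 0.1100, 0.3100, 0.22, 0.0000, -18.0),
    (-0.20, 0.1600, 0.4100, -0.22, 0.0000, 18.0),
    (0.10, 0.2100, 0.2500, 0.00, 0.3500, 0.0),
    (0.10, 0.0460, 0.0460, 0.00, 0.1000, 0.0),
    (0.10, 0.0460, 0.0460, 0.00, -0.1000, 0.0),
    (0.10, 0.0460, 0.0230, -0.08, -0.6050, 0.0),
    (0.10, 0.0230, 0.0230, 0.00, -0.6060, 0.0),
    (0.10, 0.0230, 0.0460, 0.06, -0.6050, 0.0),
)


@dataclass(frozen=True)
class PhantomSpec:
    """An additive set of ellipses on the unit square.

    Each ellipse is (intensity, semi-axis a, semi-axis b, center x,
    center y, rotation degrees); a pixel's value is the sum of intensities
    of the ellipses containing its center, so pixels outside all ellipses
    are exactly zero.
    """

    ellipses: tuple[tuple[float, float, float, float, float, float], ...] = field(
        default=MODIFIED_SHEPP_LOGAN
    )


def render_phantom(spec: PhantomSpec, n: int) -> ImageGrid:
    """Render an ellipse set on an n x n grid.

    Pixel centers sample the continuous phantom at cell midpoints of a
    uniform grid on [-1, 1]^2, with no anti-aliasing; x increases with the
    column index and y decreases with the row index (image convention).
    """
    if n < 2:
        raise ValueError("n must be at least 2")
    coords = (np.arange(n) + 0.5) * (2.0 / n) - 1.0
    x = coords[None, :]
    y = -coords[:, None]
    img = np.zeros((n, n))
    for inten, a, b, x0, y0, deg in spec.ellipses:
        th = np.deg2rad(deg)
        c, s = np.cos(th), np.sin(th)
        xr = (x - x0) * c + (y - y0) * s
        yr = -(x - x0) * s + (y - y0) * c
        img += inten * ((xr / a) ** 2 + (yr / b) ** 2 <= 1.0)
    return ImageGrid(img)


def shepp_logan_phantom(n: int) -> ImageGrid:
    """The modified Shepp-Logan head phantom on an n x n grid, values in [0, 1]."""
    img = render_phantom(PhantomSpec(), n).values
    # intensity sums that cancel exactly leave O(1e-16) round-off residue
    return ImageGrid(np.clip(img, 0.0, 1.0))


def random_projection_system(
    f: ImageGrid,
    sampling_ratio: float = 0.3,
    noise_scale: float = 0.02,
    seed: int = 0,
) -> ProjectionSystem:
    """Draw a random Gaussian sensing matrix and noisy measurements of ``f``.

    m = round(sampling_ratio * n^2) rows of i.i.d. Gaussian entries with
    variance 1/n^2, so each row has unit Euclidean norm in expectation (the
    normalized compressed-sensing convention; with raw unit-variance entries
    the fidelity weight beta of the reconstruction objective would be off by
    a factor ~n^2 and no printed parameter setting is meaningful).  Noise is
    noise_scale * mean(Phi f) * (standard-normal vector), where mean(Phi f)
    is the arithmetic mean of the noiseless projections.  Fully reproducible
    from ``seed``.
    """
    if sampling_ratio <= 0 or sampling_ratio > 1:
        raise ValueError("sampling_ratio must lie in (0, 1]")
    if noise_scale < 0:
        raise ValueError("noise_scale must be nonnegative")
    n2 = f.n * f.n
    m = int(round(sampling_ratio * n2))
    rng = np.random.default_rng(seed)
    phi = rng.standard_normal((m, n2)) / np.sqrt(n2)
    clean = phi @ f.flatten()
    e = noise_scale * clean.mean() * rng.standard_normal(m)
    return ProjectionSystem(
        phi=phi,
        u=clean + e,
        noise_scale=noise_scale,
        epsilon=float(np.linalg.norm(e)),
    )


def save_system(path, sys: ProjectionSystem) -> None:
    """Persist a projection system to a compressed .npz container."""
    np.savez_compressed(
        path, phi=sys.phi, u=sys.u,
        noise_scale=sys.noise_scale, epsilon=sys.epsilon,
    )


def load_system(path) -> ProjectionSystem:
    with np.load(path) as z:
        return ProjectionSystem(
            phi=z["phi"], u=z["u"],
            noise_scale=float(z["noise_scale"]), epsilon=float(z["epsilon"]),
        )
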