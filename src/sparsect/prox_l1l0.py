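"""Closed-form proximal map of the combined l1 + l0 gradient penalty.

For a single pixel, the auxiliary-variable subproblem of the
alternating-direction iteration is

    minimize over z in R^2:   g(z) = ||z||_2 + alpha*||z||_0 + (mu/2)||z - w||_2^2

with ||z||_0 = 1 for nonzero z and 0 otherwise.  Despite the nonconvex l0
term this problem has a closed-form global minimizer whenever
2*mu*alpha > 1: a hard-threshold at

    kappa = (1 + sqrt(2*mu*alpha)) / mu

composed with isotropic shrinkage,

    prox(w) = max(1 - 1/(mu*||w||_2), 0) * H_kappa(w),

where H_kappa zeroes any vector with ||w||_2 <= kappa and passes it through
otherwise.  On the boundary ||w||_2 == kappa the objective has two global
minimizers and the sparser one (zero) is chosen.  With alpha = 0 the
threshold degenerates to 1/mu and the map reduces to plain isotropic
soft-shrinkage, recovering the classical total-variation update.

A brute-force grid-search oracle over the same objective is provided for
independent verification.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass(frozen=True)
class ProxParams:
    """Parameters of the per-pixel prox map.

    mu : quadratic coupling weight, > 0.
    alpha : l0 weight, >= 0.  If positive, 2*mu*alpha > 1 is required: the
        closed form is only valid under that hypothesis, and rejecting the
        regime loudly beats returning a non-minimizer.
    """

    mu: float
    alpha: float

    def __post_init__(self) -> None:
        if self.mu <= 0:
            raise ValueError("mu must be positive")
        if self.alpha < 0:
            raise ValueError("alpha must be nonnegative")
        if self.alpha > 0 and 2.0 * self.mu * self.alpha <= 1.0:
            raise ValueError(
                "the closed-form prox requires 2*mu*alpha > 1 when alpha > 0 "
                f"(got 2*mu*alpha = {2.0 * self.mu * self.alpha:g})"
            )

    @property
    def kappa(self) -> float:
        """Hard threshold (1 + sqrt(2*mu*alpha)) / mu; equals 1/mu at alpha=0."""
        return (1.0 + np.sqrt(2.0 * self.mu * self.alpha)) / self.mu


def hard_threshold(w: np.ndarray, kappa: float) -> np.ndarray:
    """Zero ``w`` if ||w||_2 <= kappa (non-strict), else return it unchanged."""
    if kappa <= 0:
        raise ValueError("kappa must be positive")
    w = np.asarray(w, dtype=float)
    if np.linalg.norm(w) <= kappa:
        return np.zeros_like(w)
    return w.copy()


def prox_l1l0_pair(w: np.ndarray, params: ProxParams) -> np.ndarray:
    """Global minimizer of ||z|| + alpha*||z||_0 + (mu/2)||z - w||^2 for one pair."""
    w = np.asarray(w, dtype=float)
    nw = np.linalg.norm(w)
    if nw <= params.kappa:
        return np.zeros_like(w)
    return max(1.0 - 1.0 / (params.mu * nw), 0.0) * w


def prox_field(w, params: ProxParams):
    """Apply the prox map to every pair of a gradient field (pairs independent)."""
    from .imaging_core import GradientField

    mags = w.magnitudes().reshape(w.n, w.n)
    scale = np.maximum(1.0 - 1.0 / (params.mu * np.maximum(mags, 1e-300)), 0.0)
    scale[mags <= params.kappa] = 0.0
    return GradientField(w.data * scale[:, :, None])


def _pair_objective(z: np.ndarray, w: np.ndarray, mu: float, alpha: float) -> float:
    nz = np.linalg.norm(z)
    return nz + (alpha if nz > 0 else 0.0) + 0.5 * mu * float(np.sum((z - w) ** 2))


def brute_force_prox_oracle(
    w: np.ndarray,
    mu: float,
    alpha: float,
    grid_halfwidth: float | None = None,
    grid_step: float = 1e-3,
) -> np.ndarray:
    """Grid-search minimizer of the per-pair objective, for verification only.

    Searches a square of the given halfwidth centred at ``w`` plus the exact
    candidate z = 0 (always evaluated); ties break toward zero.  The default
    halfwidth 1.5*(||w||+1) covers both candidate minimizers: the origin and
    the shrunken multiple of w.
    """
    w = np.asarray(w, dtype=float)
    if not np.all(np.isfinite(w)):
        raise ValueError("w must be finite")
    if grid_halfwidth is None:
        grid_halfwidth = 1.5 * (np.linalg.norm(w) + 1.0)
    if grid_step >= grid_halfwidth:
        raise ValueError("grid_step must be smaller than grid_halfwidth")

    ax = np.arange(-grid_halfwidth, grid_halfwidth + grid_step / 2, grid_step)
    z0, z1 = np.meshgrid(w[0] + ax, w[1] + ax, indexing="ij")
    nz = np.sqrt(z0**2 + z1**2)
    obj = nz + alpha * (nz > 0) + 0.5 * mu * ((z0 - w[0]) ** 2 + (z1 - w[1]) ** 2)
    best = np.unravel_index(np.argmin(obj), obj.shape)
    best_z = np.array([z0[best], z1[best]])
    best_val = float(obj[best])
    # the exact zero candidate, with ties broken toward it
    zero_val = 0.5 * mu * float(w @ w)
    if zero_val <= best_val:
        return np.zeros(2)
    return best_z
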