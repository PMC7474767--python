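"""Reconstruction quality metrics and the benchmark protocols.

Five standard criteria compare a reconstruction against the ground truth:
relative error, RMSE, NRMSD, NMAD and SSIM.  The benchmark runner repeats
the random-system experiment over a list of seeds for the l1-only baseline
(alpha = 0) and the combined l1+l0 method (alpha = 1), reporting per-seed
rows and across-seed means; the error-curve runner records the relative
error after every outer iteration for both methods on one shared system.
"""

from __future__ import annotations

import io
import time
from dataclasses import dataclass

import numpy as np
import pandas as pd
from skimage.metrics import structural_similarity

from .imaging_core import ImageGrid
from .nada_ht_solver import SolverParams, nada_ht_reconstruct
from .phantom_sim import random_projection_system, shepp_logan_phantom


@dataclass(frozen=True)
class MetricsReport:
    relative_error: float
    rmse: float
    nrmsd: float
    nmad: float
    ssim: float
    iterations: int = 0
    wall_time_seconds: float = 0.0  # informational only


def _check_dims(recon: ImageGrid, truth: ImageGrid) -> None:
    if recon.n != truth.n:
        raise ValueError("image dimensions disagree")


def relative_error(recon: ImageGrid, truth: ImageGrid) -> float:
    """||recon - truth||_2 / ||truth||_2."""
    _check_dims(recon, truth)
    denom = np.linalg.norm(truth.flatten())
    if denom == 0:
        raise ValueError("truth image has zero norm")
    return float(np.linalg.norm(recon.flatten() - truth.flatten()) / denom)


def rmse(recon: ImageGrid, truth: ImageGrid) -> float:
    """Root-mean-square error ||recon - truth||_2 / n over the n x n grid."""
    _check_dims(recon, truth)
    return float(np.linalg.norm(recon.flatten() - truth.flatten()) / truth.n)


def nrmsd(recon: ImageGrid, truth: ImageGrid) -> float:
    """Root-square deviation normalized by the truth's spread about its mean."""
    _check_dims(recon, truth)
    centered = truth.flatten() - truth.flatten().mean()
    denom = np.linalg.norm(centered)
    if denom == 0:
        raise ValueError("truth image is constant")
    return float(np.linalg.norm(recon.flatten() - truth.flatten()) / denom)


def nmad(recon: ImageGrid, truth: ImageGrid) -> float:
    """Sum of absolute deviations normalized by the truth's absolute sum."""
    _check_dims(recon, truth)
    denom = np.abs(truth.flatten()).sum()
    if denom == 0:
        raise ValueError("truth image has zero absolute sum")
    return float(np.abs(recon.flatten() - truth.flatten()).sum() / denom)


def ssim_index(recon: ImageGrid, truth: ImageGrid) -> float:
    """Mean local structural similarity, standard parameterization.

    11 x 11 Gaussian window with sigma = 1.5, stability constants
    (0.01*L)^2 and (0.03*L)^2 with dynamic range L = 1 for [0, 1] images.
    """
    _check_dims(recon, truth)
    if recon.n < 11:
        raise ValueError("image smaller than the 11x11 SSIM window")
    return float(
        structural_similarity(
            truth.values,
            recon.values,
            win_size=11,
            gaussian_weights=True,
            sigma=1.5,
            use_sample_covariance=False,
            data_range=1.0,
        )
    )


def metrics_report(
    recon: ImageGrid,
    truth: ImageGrid,
    iterations: int = 0,
    wall_time_seconds: float = 0.0,
) -> MetricsReport:
    return MetricsReport(
        relative_error=relative_error(recon, truth),
        rmse=rmse(recon, truth),
        nrmsd=nrmsd(recon, truth),
        nmad=nmad(recon, truth),
        ssim=ssim_index(recon, truth),
        iterations=iterations,
        wall_time_seconds=wall_time_seconds,
    )


# ---------------------------------------------------------------------------
# Benchmark protocols
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class BenchmarkConfig:
    """Settings of the repeated random-system experiment.

    For each seed a fresh sensing matrix and noise realization are drawn,
    and the reconstruction is run once per alpha setting (0 labels the
    l1-only baseline, positive values the combined l1+l0 method).
    """

    n: int = 128
    sampling_ratio: float = 0.3
    noise_scale: float = 0.02
    alphas: tuple[float, ...] = (0.0, 1.0)
    beta: float = 2.0**8
    mu: float = 2.0**4
    gamma: float = 1e-8
    iters: int = 200
    inner_iters: int = 1
    seeds: tuple[int, ...] = tuple(range(10))

    def solver_params(self, alpha: float, seed: int) -> SolverParams:
        return SolverParams(
            alpha=alpha,
            beta=self.beta,
            mu=self.mu,
            gamma=self.gamma,
            max_outer_iters=self.iters,
            inner_iters=self.inner_iters,
            seed=seed,
        )


def _method_label(alpha: float) -> str:
    return "l1" if alpha == 0 else "l1+l0"


def run_benchmark(config: BenchmarkConfig, progress: bool = False) -> pd.DataFrame:
    """Run the full seed x alpha grid and tabulate the quality metrics.

    Returns per-seed rows plus one ``mean`` row per alpha setting.  Fully
    reproducible from the seed list (wall time aside).
    """
    truth = shepp_logan_phantom(config.n)
    rows = []
    iterator = config.seeds
    if progress:
        from tqdm import tqdm

        iterator = tqdm(config.seeds, desc="seeds")
    for seed in iterator:
        sys = random_projection_system(
            truth, config.sampling_ratio, config.noise_scale, seed
        )
        for alpha in config.alphas:
            t0 = time.perf_counter()
            recon, _ = nada_ht_reconstruct(sys, config.solver_params(alpha, seed))
            dt = time.perf_counter() - t0
            rep = metrics_report(recon, truth, iterations=config.iters, wall_time_seconds=dt)
            rows.append(
                {
                    "seed": seed,
                    "method": _method_label(alpha),
                    "alpha": alpha,
                    "time_s": rep.wall_time_seconds,
                    "error": rep.relative_error,
                    "rmse": rep.rmse,
                    "nrmsd": rep.nrmsd,
                    "nmad": rep.nmad,
                    "ssim": rep.ssim,
                }
            )
    df = pd.DataFrame(rows)
    means = (
        df.groupby(["method", "alpha"], as_index=False)[
            ["time_s", "error", "rmse", "nrmsd", "nmad", "ssim"]
        ]
        .mean()
        .assign(seed="mean")
    )
    return pd.concat([df, means[df.columns]], ignore_index=True)


@dataclass(frozen=True)
class CurveConfig:
    """Settings of the per-iteration error-curve experiment."""

    n: int = 128
    sampling_ratio: float = 0.3
    noise_scale: float = 0.02
    beta: float = 2.0**8
    mu: float = 2.0**4
    gamma: float = 1e-8
    iters: int = 200
    inner_iters: int = 1
    alpha_l0: float = 1.0
    seed: int = 0


def error_curve(config: CurveConfig) -> pd.DataFrame:
    """Relative error after every outer iteration, both methods, one system.

    Columns: iteration (1-based), error_l1 (alpha = 0) and error_l1l0
    (alpha = alpha_l0) on the same sensing matrix and noise realization.
    """
    truth = shepp_logan_phantom(config.n)
    sys = random_projection_system(
        truth, config.sampling_ratio, config.noise_scale, config.seed
    )
    histories = {}
    for label, alpha in (("error_l1", 0.0), ("error_l1l0", config.alpha_l0)):
        params = SolverParams(
            alpha=alpha,
            beta=config.beta,
            mu=config.mu,
            gamma=config.gamma,
            max_outer_iters=config.iters,
            inner_iters=config.inner_iters,
            seed=config.seed,
        )
        _, state = nada_ht_reconstruct(sys, params, ground_truth=truth)
        histories[label] = state.error_history
    return pd.DataFrame(
        {
            "iteration": np.arange(1, config.iters + 1),
            "error_l1": histories["error_l1"],
            "error_l1l0": histories["error_l1l0"],
        }
    )


def write_csv_with_header(df: pd.DataFrame, path, settings: dict) -> None:
    """Write a CSV prefixed by '# key = value' provenance comment lines."""
    buf = io.StringIO()
    for key, val in settings.items():
        buf.write(f"# {key} = {val}\n")
    df.to_csv(buf, index=False)
    with open(path, "w") as fh:
        fh.write(buf.getvalue())
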