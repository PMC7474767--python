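# sparsect

Limited-data CT image reconstruction with combined **l1 (total variation)**
and **l0 gradient-count** regularization, solved by an alternating-direction
method whose nonconvex per-pixel subproblem has an exact closed-form
hard-threshold/shrinkage solution.

## The problem

In computed tomography one often has far fewer projection measurements than
pixels — m ≪ n² — so the linear model u = Φf + e is underdetermined and
reconstruction needs a prior. Total variation (the l1-norm of per-pixel
gradient magnitudes) is the classical choice for piecewise-constant images,
but it over-smooths and blurs edges. `sparsect` implements the combined
model

    min_f  (β/2)‖Φf − u‖₂² + Σ_p ( ‖D_p f‖₂ + α·‖D_p f‖₀ ) + (γ/2)‖f‖₂²

where D_p f ∈ R² is the forward difference at pixel p and ‖·‖₀ counts
nonzero gradient pairs. The l0 term rewards gradient sparsity directly and
preserves edges; despite being nonconvex, the v-subproblem that arises
after variable splitting is solved *exactly* per pixel: with
κ = (1 + √(2μα))/μ and w = D_p f + λ_p,

    v_p  =  max{ 1 − 1/(μ‖w‖₂), 0 } · H_κ(w),

where H_κ zeroes w when ‖w‖₂ ≤ κ and passes it through otherwise (valid
whenever 2μα > 1). Setting α = 0 recovers the classical TV
alternating-direction scheme, which serves as the built-in baseline.

The package provides the solver, a modified Shepp–Logan phantom generator,
random Gaussian projection systems with measurement-scaled noise, the five
standard quality metrics (relative error, RMSE, NRMSD, NMAD, SSIM), a
repeated-seed benchmark, per-iteration error curves, and a CLI. It is aimed
at researchers studying sparse regularization for inverse imaging problems.

## Worked example

Reconstruct a 64×64 phantom from 30% random Gaussian projections with 2%
measurement-scaled noise, comparing the l1-only baseline (α = 0) against
the combined method (α = 1):

```python
from sparsect import (SolverParams, metrics_report, nada_ht_reconstruct,
                      random_projection_system, shepp_logan_phantom)

truth = shepp_logan_phantom(64)
system = random_projection_system(truth, sampling_ratio=0.3,
                                  noise_scale=0.02, seed=0)
print("m =", system.m)
for alpha in (0.0, 1.0):
    params = SolverParams(alpha=alpha, max_outer_iters=200)
    recon, state = nada_ht_reconstruct(system, params, ground_truth=truth)
    rep = metrics_report(recon, truth, iterations=200)
    print(f"alpha={alpha:.0f}  error={rep.relative_error:.3f}  "
          f"rmse={rep.rmse:.4f}  nmad={rep.nmad:.3f}  ssim={rep.ssim:.3f}")
```

Output:

```
m = 1229
alpha=0  error=0.409  rmse=0.1021  nmad=0.499  ssim=0.515
alpha=1  error=0.049  rmse=0.0122  nmad=0.046  ssim=0.956
```

Within the same 200-iteration budget the l1-only reconstruction is still on
its slow decline (41% relative error, SSIM 0.52), while the l1+l0 method
has already collapsed onto the piecewise-constant image (4.9% error, SSIM
0.96): the hard threshold zeroes spurious small gradients outright instead
of merely shrinking them, which both sharpens edges and accelerates the
error decay. `state.error_history` holds the full per-iteration curve.

The same experiment from the shell:

```sh
sparsect phantom --n 64 --out phantom.png
sparsect simulate --n 64 --sampling-ratio 0.3 --seed 0 --out system.npz
sparsect reconstruct --system system.npz --truth phantom.png \
    --alpha 1 --iters 200 --out recon.png --history-out history.csv
sparsect benchmark --n 128 --seeds 0,1,2 --out table.csv   # full-scale table
sparsect curve --n 128 --seed 0 --out curve.csv            # error-vs-iteration
```

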