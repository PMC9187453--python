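# sl0ct — sparse-view CT reconstruction with smoothed-L0 regularized ART

`sl0ct` reconstructs 2-D tomographic images from few projection angles,
the regime where the classical analytic inversion (filtered back
projection, FBP) produces streaks and noise. It implements an annealed
**smoothed-L0 regularized algebraic reconstruction** ("L0-ART") and the
three standard algorithms it is compared against — FBP, plain ART
(Kaczmarz), and (weighted) total-variation regularized ART — plus
analytic phantoms, a parallel-beam projector with exact ray–pixel chord
lengths, sinogram noise models, evaluation metrics, and a paired
benchmark harness. It is aimed at people studying iterative CT
reconstruction algorithms; all inputs are generated synthetically, so no
scanner data is needed.

## The model

A D×D image `x` is observed through line integrals `p = A x`, where each
row of the sparse system matrix `A` holds the intersection lengths of
one ray (view angle × detector bin) with every pixel. With far fewer
rays than pixels the system is underdetermined, and reconstruction
exploits the fact that CT images are *gradient-sparse*: most entries of
the discrete gradient `Ψx` are zero. The ideal objective counts nonzero
coefficients,

    min_x  ‖Ψx‖₀   subject to  A x = p ,

which is combinatorial. `sl0ct` replaces the count with a smooth
surrogate: with `v(t, β) = 1 − exp(−t²/2β²)`,

    H(x, β, κ) = Σᵢ v((Ψx)ᵢ, β) + κ ‖A x − p‖₂² ,

and `Σᵢ v → ‖Ψx‖₀` as the scale `β → 0`. The solver minimizes `H` with
damped fixed-point steps on its Euler–Lagrange residual

    R(x) = Ψᵀ diag(Λ(Ψx, β)) Ψx + 2κ Aᵀ(A x − p) ,   Λ(t) = v′(t,β)/t ,

inside an outer loop that anneals `β ← γβ` (default γ = 0.7), so the
surrogate tightens gradually toward the true sparsity count instead of
dropping the iterate into a bad local minimum. Both loops stop on
relative-change tolerances (`μ_o`, `μ_in`). Reconstruction quality is
scored by the STD metric — the population standard deviation of the
difference image between reconstruction and reference (lower is better)
— along with RMSE, PSNR and wall time.

## Worked example

Compare FBP, TV and L0-ART on a 64×64 piecewise-constant abdominal
phantom scanned from only 30 angles with 1 % Gaussian sinogram noise,
three paired noise realizations:

```
$ sl0ct benchmark --algos fbp,tv,l0art --grid-side 64 --n-angles 30 \
      --n-detectors 95 --n-repeats 3 --seed 1 -o bench_demo
 algo  mean_std   sd_std  mean_rmse  mean_time_s  n_runs
  fbp  0.051216 0.000203   0.051560     0.001367       3
   tv  0.027910 0.000426   0.027923     0.280943       3
l0art  0.021784 0.000207   0.021784     0.116186       3
```

On phantom values in [0, 1], FBP leaves a mean STD of 0.051 (streak
artifacts from the 30-view undersampling), TV regularization roughly
halves it, and L0-ART lowers it further to 0.022 — the sharper-than-TV
sparsity surrogate preserves edges while flattening the piecewise-
constant regions — in less time than the TV iteration. The same
comparison is available programmatically via `sl0ct.benchmark(...)`.

The package also ships a small cohort-statistics worked example
(`sl0ct cohort-stats`): postoperative adverse-event counts for two
50-patient arms stratified by CD4+ T-cell count give incidences of 24 %
vs 8 %, and a two-proportion chi-square test yields χ² = 4.76,
p = 0.029.

Other entry points: `sl0ct simulate` (phantom + sinogram generation),
`sl0ct reconstruct --algo fbp|art|tv|wtv|l0art`, `sl0ct evaluate`.
Images and sinograms travel as a plain-text array format (bit-exact
round trip) or 16-bit PNG/TIFF with a JSON sidecar.

## Benchmark CSV schema

`benchmark` writes one row per (algorithm, repeat) with columns
`algo, std_metric, rmse, psnr, wall_time_s, params_digest, repeat`; the
summary table aggregates `mean_std, sd_std, mean_rmse, mean_time_s,
n_runs` per algorithm.
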