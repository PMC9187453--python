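# Methods

## Imaging model

The forward model is 2-D parallel-beam tomography. A square D×D image
with pixel size `h` (origin at the grid center, angles counterclockwise
from the +x axis, detector array centered on the rotation axis) is
observed through a sparse matrix `A` of exact ray–pixel intersection
lengths, computed by Siddon-style traversal: for each ray the parametric
crossings with all grid lines are merged and sorted, and each segment
length is assigned to the pixel containing the segment midpoint. Chord
lengths therefore carry physical units, and the forward projection of
the all-ones image equals the geometric path length of each ray through
the grid — an invariant the tests assert exactly. Rays that miss the
grid keep all-zero rows so the sinogram shape is always
`n_angles × n_detectors`. Forward and back projection are exact adjoints
by construction (one sparse matrix and its transpose).

Parallel-beam geometry is a deliberate simplification: clinical
scanners are fan/helical, but every algorithmic question studied here
(undersampling, regularization, annealing) is geometry-agnostic, and
parallel beam is the standard setting in algorithm studies. Fan-beam,
cone-beam, detector blur and polychromatic physics are out of scope.

## Phantoms and noise

All inputs are synthetic. Two analytic ellipse phantoms are provided:
the standard modified Shepp-Logan head phantom (ten-ellipse table,
values in [0, 1]) and an abdominal-like phantom — body oval, two organ
ellipses, a thick-walled hollow viscus (bright annulus around a darker
lumen, mimicking a thickened gastric wall), and 2–4 seeded
high-contrast lesions. Both are piecewise constant, i.e. sparse in the
discrete-gradient domain (< 15 % of pixels carry nonzero gradient):
this is precisely the premise the gradient-sparsity regularizers
exploit, so results on these phantoms show how the algorithms behave
when their sparsity assumption holds. Real CT slices contain smooth
attenuation gradients and textured tissue that are *not* exactly
gradient-sparse; the benchmark therefore bounds the best case, and no
claim about clinical images follows from it.

Sinogram noise is either additive Gaussian with standard deviation
`level × max(p)` (default level 0.01, i.e. 1 % of the maximum line
integral — a visibly noisy but not pathological regime for
sparse-view simulations) or a Poisson transmission model: counts
`I₀ exp(−p)` with `I₀ = level` incident photons, Poisson-drawn, then
log-transformed back, with zero counts clamped to one count to keep the
log finite (standard practice).

The benchmark's study conditions are a 64×64 grid, 30 evenly spaced
views over [0, π), 95 detector bins of unit spacing (enough to cover
the grid diagonal of 64√2 ≈ 90.5), 1 % Gaussian noise, and 5 paired
repeats. These sizes make one full five-algorithm benchmark run in a
few seconds while leaving the sparse-view effect (6× fewer views than
the 180-view dense reference) clearly visible.

## Reconstruction algorithms

**FBP.** Each view is ramp-filtered in the frequency domain (Ram-Lak by
default; Shepp-Logan and Hann apodizations available), with zero
padding to the next power of two ≥ 2 × detector count, then
backprojected with linear interpolation and π/n_angles angular
weighting. The implementation is checked for linearity, rotation
covariance, and accuracy against an independent discrete Radon
inversion from scikit-image at identical settings.

**ART.** Sequential Kaczmarz row action,
`x ← x + λ (pᵢ − aᵢ·x)/‖aᵢ‖² aᵢ`, sweeping rows in a fixed order for
determinism, skipping zero rows, with optional nonnegativity clamping
per sweep. On consistent systems started from zero it converges to the
minimum-norm (pseudo-inverse) solution, which the tests verify.

**TV / WTV.** ASD-POCS-style alternation: one ART sweep, then
`n_tv_steps` (default 10) normalized steepest-descent steps on smoothed
isotropic TV `Σ √(Δx² + Δy² + ε²)` with step length
`tv_step × ‖ART update‖` (default factor 0.2 — the standard adaptive
coupling that keeps the regularization step commensurate with the data
step). WTV multiplies each pixel's gradient contribution by
`w = exp(−(|∇x|/δ)²)` (default δ = 0.05), recomputed once per sweep, so
strong edges are exempted from smoothing; δ → ∞ recovers plain TV
exactly. The literature contains many TV/WTV variants; these are the
most common published forms, and every knob is surfaced in the
parameter objects and config.

**L0-ART.** The energy is
`H(x, β, κ) = Σ v((Ψx)ᵢ, β) + κ‖Ax − p‖²` with the Gaussian surrogate
`v(t, β) = 1 − exp(−t²/2β²)` — the canonical smoothed-L0 family; the
`Λ` weights use the analytic limit `1/β²` at `t = 0`, so no division by
zero arises. The gradient (Euler–Lagrange residual)
`R = ΨᵀΛΨx + 2κAᵀ(Ax − p)` is verified against central finite
differences of `H`. Ψ is the forward-difference gradient by default
(CT images are gradient-sparse); the identity option turns the solver
into classical smoothed-L0 sparse recovery, which enables an exact
exhaustive-search oracle test at small sizes.

The driver nests two loops. The outer loop multiplies β by γ (default
0.7) and stops when the relative iterate change falls below
μ_o = 10⁻³ or after 30 iterations; starting from
`β₀ = 2 max|Ψx_init|` the surrogate begins nearly quadratic and is
annealed toward the counting norm. The inner loop runs damped steps
`x ← x − ηR(x)` until relative change < μ_in = 10⁻³ or 50 iterations.

Numerical choices that matter:

- **Step size.** The base step is curvature-matched,
  `η = step_size / (‖Ψ‖²/β² + 2κ σ_max²(A))`, with `σ_max` estimated by
  20 deterministic power iterations and `‖Ψ‖² ≤ 8` for the gradient
  (1 for the identity). The `1/β²` term is essential: the surrogate's
  second derivative grows like `1/β²` as β anneals, so any fixed step
  eventually overshoots; the curvature-matched step shrinks in
  proportion and keeps the fixed-point iteration stable at every
  annealing stage. `step_size` (default 1.0) scales this estimate.
- **Backtracking.** A step that would increase the energy is halved up
  to 10 times; if the energy still increases on 5 consecutive attempts
  the solver raises a divergence error carrying the full trace. An
  outer pass that accepts no step is not treated as convergence — the
  annealing continues so the rescaled step can recover.
- **Initialization.** FBP by default (well-conditioned and cheap);
  backprojection (scaled to match the data in least squares) and zeros
  are options. For generic sparse recovery the minimum-norm
  least-squares solution is used — the minimum-energy
  measurement-consistent starting point — optionally followed by exact
  re-projection of every iterate onto `{x : Ax = p}` (classical SL0
  behavior; dense pseudo-inverse, so small systems only).
- **Degenerate inputs.** An all-zero sinogram short-circuits to the
  zero image with a logged note; zero rows are skipped everywhere.

Defaults: κ = 1, γ = 0.7, μ_o = μ_in = 10⁻³, max_outer = 30,
max_inner = 50. κ balances the (dimensionless, ≤ 2D²) surrogate sum
against the squared data residual; κ = 1 with unit-spaced geometry
keeps the data term dominant early (large residuals) and lets the
sparsity term take over as the fit tightens, which is the intended
annealing behavior.

## Evaluation

The STD metric is the population standard deviation of the difference
image `f = a − a₀`: `STD = √(Σ(f − f̄)²/D²)` with `f̄ = Σf/D²`. The
mean is divided by D² (the only reading that makes the quantity a
standard deviation) and the population normalization D² matches the
outer divisor. Mean-centering makes the metric blind to a constant
offset — by design it measures structured error (noise, streaks),
not calibration. RMSE and PSNR (capped at 99 dB for exact matches) are
standard auxiliaries; STD ≤ RMSE always. Wall time is recorded per run
but never asserted, being hardware-dependent.

The benchmark harness runs each algorithm on *identical* seeded noisy
sinograms (noise seeds spawned deterministically from the master seed
per repeat), so comparisons are paired; averaging is over repeats.

## Cohort worked example

The cohort module reproduces a small two-arm incidence computation:
per-complication counts (gastrointestinal dysfunction, wound infection,
anastomotic leakage, pulmonary infection, pleural effusion) are summed
treating each counted case as a distinct patient — with the bundled
example (12/50 vs 4/50) this yields exactly 24 % vs 8 %. The comparison
is a Pearson chi-square on the 2×2 events/non-events table without
Yates correction (the conventional large-sample two-proportion test;
the correction is available via a flag). This is a deliberate,
documented choice of test for a proportion comparison; the module makes
no broader claims about the cohort, whose raw data are not available.

## Known limitations

- Parallel-beam only; no fan/helical geometry, scatter, or spectral
  effects.
- The gradient transform uses forward differences with replicate
  borders; other sparsifying transforms (wavelets) are not implemented.
- The smoothed-L0 energy is nonconvex: the annealing schedule is a
  heuristic for tracking good minima, and no recovery guarantee is
  claimed. The exhaustive-search oracle test covers only small
  identity-transform instances.
- Exact data projection (`data_projection="exact"`) densifies the
  system and is infeasible for realistic CT sizes; the penalty form is
  the CT path.
- Benchmark conclusions are established on piecewise-constant phantoms
  at the stated problem sizes and transfer to real data only insofar as
  the gradient-sparsity assumption holds.
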