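# Methods

## Image-formation model

A fluorescence image is modelled as counts `y_i ~ Poisson((H x)_i + b_i)`:
the unknown object `x` (expected photons emitted per pixel) is blurred by
the microscope PSF through the imaging operator `H`, a known nonnegative
background `b` is added, and photon-counting noise acts independently per
pixel.  `H` is realized as a periodic (circular) convolution via FFT: the
kernel, sum-normalized so that `H` preserves total flux and `H^T 1 = 1`, is
embedded at the origin of the object grid and applied as a component-wise
product in frequency space.  All solver arithmetic is double precision; a
`single_precision` switch stores iterates in float32 (transforms and
reductions stay double).

## PSF models

* **Confocal**: radially symmetric Gaussian, lateral width `sigma_r` (nm),
  optional axial width `sigma_z` for 3D stacks.  `FWHM = 2 sqrt(2 ln 2)
  sigma`, so the default `sigma_r = 93 nm` corresponds to a 219 nm lateral
  FWHM.
* **CW-STED**: the confocal Gaussian multiplied by a Lorentzian-type
  suppression, `h(r) = g(r) (1 + saturation * psi^2 r^2)^(-p)`, acting
  laterally only (the depletion doughnut confines in-plane).  `psi` (nm^-1)
  encodes the doughnut shape near the focus, `saturation` is the peak
  depletion intensity over the marker's effective saturation intensity;
  `saturation = 0` recovers the confocal model exactly and the peak value
  is invariant in `saturation`.  The exponent `p` (default 1) is a model
  degree of freedom: with `p = 1` the printed parameter set
  (`sigma_r = 93 nm`, `psi = 3.22e-3 nm^-1`, `saturation = 7`) yields a
  153 nm FWHM.  When an effective STED resolution is known independently,
  `sted_lorentz_exponent_for_fwhm` solves for `p` in closed form; the
  benchmark STED preset pins the model to a 100 nm FWHM this way
  (`p ≈ 3.29`), treating the measured resolution as a calibration input on
  the same footing as the photon scale.  This is a pragmatic effective
  model, not a vectorial diffraction computation.

Kernels are rasterized by centre-point evaluation on odd-sized grids
(differences from pixel-area integration are far below the noise at 20 nm
pixels), in two normalizations: `sum_to_one` for deconvolution and
`peak_preserving` for simulation, where narrowing the STED PSF at constant
peak reduces the total collected signal — the physically correct photon
budget when comparing modalities on the same specimen.

PSF parameters are estimated from 1D intensity profiles through
sub-resolved structures by weighted nonlinear least squares (weights
`sqrt(max(count, 1))`, the Poisson standard deviation); the saturation fit
is log-parametrized with a coarse multi-start to avoid the flat-gradient
region near zero, and clamps to zero (with a diagnostic flag) when the
profile is broader than the confocal envelope allows.

## Objectives

The maximum-likelihood data fit is the generalized Kullback-Leibler
(Csiszar I-) divergence

    f0(x) = sum_i [ y_i ln(y_i/(Hx+b)_i) + (Hx+b)_i - y_i ],

with the `y_i = 0` term equal to `(Hx+b)_i` exactly (masked, not
epsilon-padded).  Its gradient is `H^T 1 - H^T(y/(Hx+b))`.  The MAP
objective adds `beta/2 ||x||^2` (Tikhonov); its split-gradient
decomposition `V1(x) = x` feeds the SGP scaling.  With `beta = 0` the MAP
path is bit-identical to the ML path.

## Solvers

**Richardson-Lucy**: `x <- (x/w) * H^T(y/(Hx+b))` with `w = H^T 1`.  With
`b = 0` and no boundary correction it conserves flux (`sum x_k = sum y`)
exactly, and its KL data fit is non-increasing.

**Scaled gradient projection (SGP)** accelerates the same minimization:

1. diagonal scaling `D = clip(x/(w + beta V1(x)), L1, L2)`;
2. step length `alpha_k` from the two scaled Barzilai-Borwein rules with
   adaptive alternation: when `alpha_BB2/alpha_BB1 <= tau_k`, take the
   minimum of the last `M` BB2 values and relax `tau` by 0.9, else take BB1
   and tighten by 1.1.  A BB rule with nonpositive denominator is replaced
   by `alpha_max` inside the alternation (so the healthy rule wins); only
   when both fail does the previous step persist.  `tau_k` may transiently
   exceed 1 after a run of BB1 choices; since `alpha_BB2 <= alpha_BB1`
   the BB2 branch then fires and shrinks it back;
3. projection `z = P+(x - alpha D grad f)`; a fixed point of this map
   (max-abs difference below `1e-12 max|x|`) is a constrained minimizer and
   stops the iteration;
4. monotone Armijo backtracking along `d = z - x` (sufficient-decrease
   parameter 1e-4, shrink factor 0.4).  Feasibility is automatic because
   `z` is feasible and the step is a convex combination.

Defaults: `alpha_0 = 1.3`, `alpha in [1e-5, 1e5]`, `D in [1e-10, 1e10]`,
`M = 3`, `tau_0 = 0.5`.  Global convergence requires only the step and
scaling bounds, which the solver asserts per iteration; the alternation is
a speed heuristic.  Two robustness guards temper it: a degenerate
(nonpositive-curvature) BB rule is replaced by `alpha_max` so the healthy
rule wins the alternation, and the step may not collapse by more than a
factor `alpha_damping` (default 10) per iteration — after an
over-aggressive projection the model can graze zero, BB then reports
enormous curvature, and an undamped collapse to `alpha_min` stalls the
iteration for tens of iterations; the line search already protects
monotone descent, so damping the collapse is safe.  The KL part of the line-search objective is evaluated
from `Hx + lambda H d`, so backtracking costs no extra FFTs; the
incrementally updated model is refreshed from scratch every 50 iterations
to cap drift.  The starting point is a constant array carrying the
background-corrected total flux `sum(y - b)` clipped at zero — flux-
consistent and free of structural bias.

**Stopping.** Two rules: relative objective decrease below `tol` (default
1e-3, the rule used on real acquisitions; because BB steps make
single-iteration progress erratic, the criterion must hold for
`tol_consecutive` = 3 iterations in a row before it is trusted), and — on
simulated data, where the object is known — the minimum of the KL
divergence to the scaled truth (the semiconvergence point).  The KL-stop runs a fixed patience (default
50 iterations) past the running minimum and returns the snapshot taken at
the minimum; on the benchmark problems this reproduces the argmin of
full-length traces exactly.

## Evaluation metric

Restoration quality on simulated data is the generalized KL divergence of
the scaled truth from the iterate, `KL(flux_scale * xbar || x_k)`, with
`flux_scale = tau * sum(simulation kernel)` — the expected photons emitted
per unit phantom intensity, the scale a converged reconstruction attains.
Because projection methods produce exact zeros (the unregularized
minimizers are sparse "night-sky" solutions), a zeroed pixel on the truth
support would make the strict divergence +inf for every later iterate and
erase the semiconvergence minimum; the iterate is therefore floored at
`1e-8` times the truth peak inside the metric, so wrongly-zeroed pixels
contribute a large-but-finite penalty.  `floor_rel = 0` recovers the
strict divergence.  An image-side variant (comparing `H x_k` with
`H truth`) was evaluated and rejected: its trace minimum degenerates to
the starting point on the benchmark problems.  The headline statistic is
the percentage reduction in optimal (KL-minimizing) iteration count of SGP
relative to RL on identical inputs, averaged over noise and phantom
realizations.

## Synthetic data

**Phantoms** mimic a microtubule cytoskeleton: filaments start at uniform
positions with uniform initial directions and grow in 40 nm steps, the
direction performing a wrapped-Gaussian random walk (turning-angle std
`1/sqrt(persistence)`, default persistence 100, i.e. ~0.1 rad per step — a
gently curving, visually microtubule-like path).  Filaments reflect at the
arena walls rather than terminating, so each realizes its full length
budget (default 3 um) and the filament concentration is independent of
image size when the count scales with area (default 0.6 filaments/um^2,
giving a ~13% nonzero-pixel fraction).  Each filament is a 30 nm-radius
tube with a per-filament intensity uniform in [0, 1] (heterogeneous
labelling); overlapping tubes add, since emission densities add.  Tubes
are rasterized by 4x-supersampled distance-to-centreline coverage, so a
tube spans about three 20 nm pixels across with partial edges.  Turning
model, step length and length budget are not constrained by any published
value; they were fixed once at these visually realistic settings.

**Simulation**: the phantom is convolved with the peak-preserving PSF,
scaled by the photon factor `tau`, and Poisson-corrupted
(`numpy` PCG64 generator, recorded in the dataset metadata; bit-reproducible
from the seed).  `tau` lumps emission rate, collection efficiency and dwell
time; it is calibrated by bisection (to 0.01 dB) against the adopted SNR
definition

    SNR = 10 log10( sum(s^2) / sum(s + b) ),  s = tau * H xbar,

total signal power over total Poisson variance.  The definition is exposed
as a plain function and swappable.  Consistency check: calibrating `tau`
to 13 dB on the confocal arm gives ~11.4 dB on the STED arm of the same
phantom under shared imaging conditions — the ~2 dB gap between the two
modalities emerges from the photon budget rather than being imposed.

What the phantoms do **not** model: detector read-out noise, depth-variant
blur, filament branching or biophysical dynamics, out-of-focus haze.
Passing benchmarks therefore demonstrate solver behaviour under ideal
Poisson statistics with a known PSF (an inverse-crime setup, intentionally:
the comparison isolates optimizer speed, not PSF mismatch robustness).

## Boundary-effect correction

For cropped structures, reconstruction runs on an extended domain `R`
(image domain `S` plus a pad of at least the kernel half-width).  The
weights `w = H^T(indicator of S)` replace `H^T 1` in the gradient and in
the multiplicative/scaling denominators; object pixels with `w` below 1e-4
are frozen at zero and excluded from the BB inner products (their scaling
entries would otherwise pin to the clip bounds meaninglessly).  Interior
pixels have `w = 1` to machine precision, so the correction is exactly
orthogonal to the uncorrected solver away from the frame edge.

## Benchmark conditions

256x256 images at 20 nm pixels (scaled down from the 512x512 reference
layout; the filament concentration per area is held fixed, which makes the
optimal iteration counts insensitive to image size), background 0, kernels
spanning +-4 sigma_r.  Confocal: Gaussian `sigma_r = 93 nm`, `tau`
calibrated to 13 dB.  STED: `sigma_r = 93 nm`, `psi = 3.22e-3 nm^-1`,
`saturation = 7`, exponent calibrated to a 100 nm FWHM, `tau` to 11 dB.
Per modality, 10 phantom seeds x 2 noise seeds (20 realizations; the test
suite uses 8 x 2 to keep its runtime modest).  The replicate budget is
spread across phantoms because a variance decomposition shows the
reduction statistic varies far more between phantom realizations
(std ~11 percentage points for STED) than between noise realizations of
the same phantom (std ~5 points), so phantom-heavy allocation minimizes
the variance of the reported mean.  RL runs to at most 3000 iterations and
SGP to 600, both with KL-stop patience 50 — the RL optima sit near 450
(confocal) and 45 (STED) iterations, far from the caps.  The reported
statistic is the mean of per-replicate percentage reductions.

## Known limitations

* The Lorentzian-exponent calibration is an effective-resolution fudge: it
  matches the width, not the exact line shape, of a real depletion profile.
* The KL-to-truth floor (1e-8 of peak) is a convention; the optimal
  iteration of SGP can shift by a few iterations under a different floor,
  while RL (strictly positive iterates) is insensitive.
* The boundary correction assumes the PSF is spatially invariant across
  the pad; strongly depth-variant blur is out of scope.
* Only the quadratic (Tikhonov) penalty is implemented; edge-preserving
  and sparsity penalties are deliberately excluded.
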