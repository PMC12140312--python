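# Methods

## Model

All three modalities share one image-formation template: a complex
wavefront `x` on a sampled grid passes through a chain of linear operators
`A_n = A_K ··· A_1` and the camera records `I_n = |A_n x|²`. The chains
are:

* **FPM** — spectrum shift by the LED tilt `k_n = (y, x)/(λ√(x²+y²+h²))`
  (1/µm, no 2π factor), central crop of the high-resolution spectrum to the
  low-resolution grid, complex pupil mask, inverse Fourier transform.
  High- and low-resolution grids share the frequency step
  `1/(N·Δx_hi)`, so the crop window is the shifted sub-aperture.
* **Coded ptychography** — integer-pixel object shift, angular-spectrum
  propagation to the mask, pointwise coded-pattern mask, angular-spectrum
  propagation to the sensor.
* **Inline holography** — a single angular-spectrum propagation.

Angular-spectrum propagation uses the exact transfer phase
`exp(i2πz√(1/λ² − f²))` with a hard band limit at the evanescent cutoff and
no Fresnel approximation; it is unitary on the propagating band, so its
adjoint equals back-propagation. All grids are even-sized and DC-centered,
and every Fourier stage is orthonormal; consequently each operator's
adjoint is available in closed form and every chain passes the dot-product
test `⟨Au, v⟩ = ⟨u, Aᴴv⟩` to ~1e-15.

## Loss and gradients

The solver minimizes a feature-domain misfit plus constraint penalties

```
L = Σ_n D(Θ(S(I_n^obs)), Θ(S(|A_n x|²))) + α‖x − C(x)‖² + Σ_k β_k‖A_k − C(A_k)‖²
```

* `S` — pointwise intensity scaling. Default `sqrt(I + ε)`, ε = 1e-9:
  amplitude-like and variance-stabilizing for shot-noise-dominated frames.
  `identity` and `log1p` are selectable.
* `Θ` — a linear feature extractor. `gradient`: forward differences with
  replicate boundary (adjoint = negative divergence); central differences
  selectable. `wavelet`: multilevel 2-D DWT, default `bior2.2` with 5
  levels (clamped to what the frame size supports), symmetric extension
  for standalone analysis. Because a biorthogonal inverse is not the
  adjoint, the solver evaluates wavelet features in periodization mode,
  where the time-reversed filter bank is the exact analysis adjoint
  (verified by dot-product tests).
* `D` — `l2`, or Charbonnier `√(r² + ε²) − ε` with ε = 1e-3 as the smooth
  surrogate of ℓ1 (the default; exact ℓ1 is rejected for gradient use).

Gradients are Wirtinger gradients computed by hand-rolled backprop: pull
`D'` back through `Θᵀ` and `S'`, convert to a field gradient via
`∂L/∂ū = (∂L/∂I)·u`, and push through the adjoint chain. The returned
direction is `g = 2·∂L/∂x̄`, so a real step `t` along `−g` changes the loss
by `−t‖g‖²` to first order; finite-difference checks agree to better than
1e-4 relative on random coordinates. The pupil (and coded pattern, when
learned) get their gradients from the same pass: the pupil gradient is the
conjugate spectrum patch times the back-transformed field residual, summed
over frames.

## Optimizers and iteration loop

Adam and YOGI (additive second-moment update,
`v ← v − (1−β₂)·sign(v−g²)·g²`) with bias correction, plus plain SGD and
heavy-ball SGD. Complex parameters track second moments on the squared
modulus of the complex gradient, making the step phase-invariant. Defaults:
β₁ = 0.9, β₂ = 0.999, ε = 1e-8, learning rates 0.01 for the object and
0.001 for the pupil (raised to 0.05/0.05 in the aberration benchmarks,
where the pupil must travel several radians), 500 iterations, optional
relative-loss stopping tolerance. Frames are summed each step by default;
a seeded mini-batch mode over frames exists for large LED counts.

The eHIO constraint block has two realizations, chosen per run:

* **penalty** (default) — each constraint contributes
  `2·weight·(x − C(x))` to its target's gradient, with no gradient flowing
  through `C`; the penalty value joins the loss trace. The run returns the
  best-total-loss iterate, which guards against the oscillation adaptive
  optimizers show near convergence.
* **hard** — after each optimizer step the target is replaced by `C(x)` at
  a per-constraint cadence (`every`). Because replacement deliberately
  trades data consistency for feasibility, the run returns the final
  iterate: comparing losses across infeasible iterates would always prefer
  the unrefined initialization, which is exactly the twin-image trap in
  holography.

The penalty exponent is stored in `ConstraintSpec.norm_order` (default 2,
the squared-L2 reading); other readings remain expressible.

Physical projections run after every step regardless of mode: the pupil is
confined to its NA disk and its amplitude clamped at 1.5 — without a clamp
the joint fit is degenerate with the object's amplitude.

Initializations: FPM object = spectrum of the upsampled root-mean
brightfield frame with zero phase, pupil = ideal disk; holography object =
back-propagated root hologram; coded pattern = ones.

## Synthetic data

The generators emulate the conditions the solvers are evaluated under; no
external data is needed.

* **Phantoms** — USAF-1951 three-bar elements (bar width
  `500/2^(g+(e−1)/6)` µm), smooth phase disks, seeded cell-like blobs,
  spoke-wheel pure-phase objects.
* **Pupil aberrations** — the first 15 OSA/ANSI Zernike modes (piston
  excluded), seeded uniform [−1, 1] coefficients rescaled so the
  peak-to-valley over the NA disk is exact.
* **Degradations**, applied in fixed order vignette → polynomial background
  → Poisson → Gaussian: the vignette is a soft half-plane (or a circular
  window displaced linearly with the illumination angle), reproducing the
  half-bright/half-dark frames seen under oblique LEDs; noise defaults are
  10⁴ photons per full-scale pixel and 1% full-scale read noise. Every
  simulator's truth record regenerates its frames bit-exactly from the
  same seed.

The generators do not model partial coherence, sensor MTF, multi-slice
(thick) samples, or the rotational scan geometry of real coded-ptychography
instruments (integer-pixel raster shifts are used instead, and the
mask-to-sensor distances are repository defaults, not instrument values).
Passing tests therefore demonstrate correctness of the algorithms under
these stated conditions, not performance on arbitrary experimental data.

## Benchmarks and their conditions

* **Blind aberration recovery** (`blind_aberration_trial`): 128-px object,
  15×15 LED grid (4 mm pitch, 120 mm height), objective NA 0.1,
  λ = 0.532 µm, camera pitch 1.25 µm, downsampling 4× — chosen so the
  intensity passband is Nyquist-sampled and the most oblique crop window
  stays inside the spectrum. Clean frames; 450 Adam iterations. Success =
  pupil-phase RMS error < 0.5 rad after removing piston/tip/tilt and the
  conjugate-twin ambiguity (the tilt is estimated wrap-safely from
  neighbor phase differences, since a multi-cycle tilt defeats a linear
  fit on wrapped angles). Recovery succeeds through 8π peak-to-valley at
  ~0.002 rad RMS.
* **Robustness orderings**: a 64-px, 9×9-LED, NA 0.25 system with
  half-plane vignetting + noise (feature-domain vs pixel-domain vs EPRY)
  or a 4π aberration + noise (vs EPRY and mPIE). PSNRs are compared after
  removing the non-identifiable global intensity scale.
* **Holography**: a wheel-like pure-phase phantom at 1500 µm with shot and
  read noise; FD-PR with amplitude clip (weight 0.3) plus guided-filter
  phase denoising (radius 8 px, eps 0.04, weight 1.0) against
  unconstrained FD-PR and GS+TV. The weak-phase disk benchmark uses hard
  constraint mode (unit amplitude every step, one guided-filter pass at
  the end) at 1500 µm, where the phase-contrast transfer `sin(πλzf²)` of
  the disk-scale frequencies is order one — at a few hundred µm the bulk
  phase of large structures is nearly invisible in a single hologram.

## Constraints library

* amplitude threshold (phase-preserving clip) — idempotent;
* ROF total-variation denoiser via Chambolle dual projections (step 1/8,
  20 iterations by default), validated against an independent reference
  implementation;
* guided filter (box windows of side 2r+1, classic two-coefficient local
  linear model), validated against a literal sliding-window oracle;
  defaults radius 8 px, eps 0.04 for twin-image removal — smaller eps
  preserves more fine structure;
* discrete Hessian (curvature) penalty `Σ f_xx² + 2f_xy² + f_yy²` with its
  biharmonic-form gradient, applied to real and imaginary parts
  independently for complex targets;
* support projection, and a `complex_constraint` router that applies any
  real-image denoiser to the amplitude, the phase, or both channels
  (holography presets denoise the phase and constrain the amplitude).

## Baselines

GS (detector-amplitude replacement with object-plane constraints), ePIE
(sequential conjugate-weighted updates of object and coded pattern, frame
order seeded-shuffled once), EPRY (embedded pupil update confined to the
NA disk dilated 10%), and mPIE (EPRY plus per-sweep heavy-ball momentum on
the object spectrum only — momentum on the pupil destabilizes the embedded
update; zero momentum reduces bitwise to EPRY).

## Metrics

PSNR and SSIM follow the standard definitions (SSIM: 11×11 Gaussian
window, σ = 1.5, k₁ = 0.01, k₂ = 0.03). The no-reference noise level is
the Laplacian-mask residual estimator
`√(π/2)/(6(W−2)(H−2))·Σ|f∗M|`, and contrast is RMS contrast (std/mean);
both are scale-equivariant, flip/transpose-invariant within-repository
measures — their absolute values are not comparable to other instruments'
conventions. Resolution formulas: USAF frequency `2^(g+(e−1)/6)` lp/mm and
coherent Abbe limit `λ/2NA`.

## Known limitations

Iterative optimization is not real-time; the per-frame vectorized NumPy
path is the only backend. Wavelet-feature solving uses periodization
boundaries internally, which can differ from symmetric-extension analysis
near tile borders. Identity-scaling plus gradient features can stall on
very weak-contrast data (the Charbonnier distance saturates); sqrt scaling
is the robust default. Global phase, object/pupil tilt exchange, intensity
scale and the conjugate twin are structurally non-identifiable and are
removed before any comparison to ground truth.
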