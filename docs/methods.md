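# Methods

## The problem

The population receptive field (pRF) method estimates, for every fMRI
voxel or surface vertex in visual cortex, the region of visual space that
drives its BOLD response, modeled as an isotropic 2-D Gaussian with
center (μx, μy) and size σ (degrees of visual angle). The standard
mapping stimulus — a bar of fixed width sweeping at constant speed —
interacts badly with cortical magnification: near the fovea pRFs are
tiny, so the bar crosses them in a few seconds and the slow hemodynamics
erase the size information, producing inflated and unreliable foveal σ
estimates. This package implements the alternative *log-bar* stimulus and
everything needed to quantify its benefit in simulation.

## The log-eccentricity warp

Every frame of the fixed-bar movie is warped along the eccentricity axis:

    r' = c · log(1 + k·r),      c = r_max / log(1 + k·r_max)

with distortion factor k = 5 (approximately matching human V1 cortical
magnification) and r_max = 8° (the aperture radius), so the aperture edge
maps to itself. As k → 0 the warp tends to the identity. The warp is
implemented as a *pull* map: the log-bar frame at output eccentricity r
samples the fixed-bar frame at c·log(1 + k·r), with polar angle
untouched, bilinear interpolation at the source location, and
re-binarization at 0.5. Only the pull direction yields the intended
phenomenology — a thin, slow bar near the fovea and a wide, fast bar in
the periphery (the radial width of the warped bar is non-decreasing in
the eccentricity of its center). `apparent_eccentricity` is the exact
inverse map, used for bookkeeping and testing.

## Stimulus protocol

Defaults reproduce the standard run: a 2°-wide bar moving at 0.4°/s,
eight 45-s sweeps preceded by a 2-s and followed by a 4-s blank — 366 s
per run, rendered at 1 frame/s (the post-preprocessing temporal
resolution). The bar center travels 18° (= 0.4 × 45), covering the 16°
aperture plus one bar width, centered on fixation; positions are
evaluated at each frame's temporal midpoint, so the bar is exactly at
fixation at the sweep midpoint. Sweep directions are drawn pseudorandomly
(seeded) from the 8 cardinal/diagonal directions; when the direction set
size equals the sweep count a seeded permutation is used so every
direction appears once. Movies render at 540 × 540 and are linearly
downsampled to 108 × 108 (and re-binarized at 0.5) for fitting;
temporal downsampling is available but a 1-frame/s render already matches
the fitting resolution.

## Forward model and HRF

The predicted response is R̂(t) = ⟨S(·,·,t), G⟩ ⊛ h(t): the per-frame dot
product of the binary movie with the unnormalized Gaussian, convolved at
stimulus resolution with the six-parameter double-gamma HRF

    h(t) = g(t−δ; α1, β1) − g(t−δ; α2, β2)/ratio,

(gamma densities in shape/rate form; h ≡ 0 for t ≤ δ), then linearly
interpolated to the TR grid (TR = 1.2 s; a 366-frame movie yields 305
volumes). The HRF is normalized to unit peak for conditioning — harmless
because the fit criterion is correlation, which is invariant to positive
affine transforms, and no amplitude or baseline parameters exist.
Canonical defaults: δ = 0, α1 = 6, α2 = 16, β1 = β2 = 1, ratio = 6
(response peak ≈ 5 s, undershoot near 16 s). Convolution zero-pads before
stimulus onset; the slice-time reference offset of real acquisitions is
ignored for synthetic work. The literal formula is implemented even
though the verbal labels "time to peak" for α are only approximate
(the gamma mode is (α−1)/β + δ).

## Two-stage fitting

Stage 1: coarse grid search over 8000 seeds — μx, μy each from −8° to 8°
in 20 evenly spaced values (inclusive endpoints, spacing 16/19) and σ
from 1° to 5° in 20 values. Seed predictions are computed once per movie
(one dense matrix product) and z-scored, so the search over all units is
a single correlation matmul; ties break toward the first seed in
μx-major enumeration order. σ seeds deliberately start large: size
converges more reliably downhill from above. Stage 2: Nelder–Mead
simplex over (μx, μy, σ) minimizing the negative Pearson correlation
(xatol 2·10⁻³, fatol 10⁻⁷, ≤400 evaluations); σ is clamped to a 10⁻³°
floor inside the objective; the refined estimate never reports a lower
correlation than its seed. The refinement objective only evaluates the
Gaussian within a ±4σ window and only sums over bar-active pixels
(pixel-major sparse index), which makes the ~10⁴ fits of the simulation
experiments tractable. Predictions with zero variance get correlation 0
so degenerate seeds never win; constant time series are flagged
(correlation NaN, unconverged estimate).

HRF co-estimation: after a grid search with the canonical HRF on all
runs (units aligned, predictions and data concatenated in time), a
seeded random ⌈15%⌉ of the units with VE > 20% is selected; per unit,
a simplex fit of the six HRF parameters (pRF fixed; box bounds δ ∈ [0,4],
α1 ∈ (1,12], α2 ∈ (1,24], β1, β2 ∈ (0.1,4], ratio ∈ (0.5,24] enforced by
logistic reparameterization) alternates with a pRF refit (HRF fixed) for
three iterations, and the elementwise median across units is returned.
Individual parameters trade off (δ against α1, notably), but the
resulting *curve* is well identified — tests assert peak-time recovery
within 0.5 s. If no unit passes the threshold the canonical HRF is
returned with a warning. The recovery simulation itself fits with the
known simulation HRF rather than re-running co-estimation: the simulated
data are generated with a known HRF, and co-estimation there would
multiply runtime several-fold without changing what the experiment
measures.

Retention filters (strict inequalities, as printed): estimated
eccentricity < 8°, σ > 0.05°, variance explained > 10%. A per-unit log
records which rule(s) each rejected unit violated; retained + rejected
always equals the input count.

## Recovery simulation

Ground truth: 4800 pRFs — polar angles 0°–345° in 15° steps × 200
log-spaced eccentricities from 0.01° to 8°, with σ = 0.15·ecc + 0.1.
Each pRF's noise-free prediction is computed for both stimulus types and
IID Gaussian noise (white at TR resolution) is added with a single
standard deviation shared by the whole population.

**Amplitude convention.** The raw overlap amplitude scales with pRF area
(σ²), spanning ~3.5 orders of magnitude in variance across this grid —
not how BOLD percent signal change behaves, and enough to wipe out every
foveal unit at any single noise level. Each clean prediction is therefore
normalized to unit peak before noise is added, emulating a roughly
uniform response amplitude across cortex. Response *duration* keeps its
physical dependence on geometry, so a foveal pRF still yields a brief,
low-variance blip under the fixed bar and an extended, higher-variance
response under the log bar — which is exactly what produces the
differential foveal retention and the fixed-bar σ overestimation.

**Noise calibration.** The sd is chosen so that the mean variance
explained over retained fits (fixed-bar condition, canonical HRF) matches
a target of 42%, the empirical V1 level. The retained-mean VE is not
monotone at small sd (weak units that still pass retention first drag the
mean down, then drop out), so the calibration walks a geometric sd ladder
until the target is bracketed on the declining branch and then bisects on
log sd. A single frozen unit-variance noise draw is rescaled by each
candidate sd, making the measured curve deterministic across iterations.
Calibration runs on an eccentricity-stratified subsample (default 500
pRFs); tolerance ±1–2 VE percentage points.

**Analysis.** For each stimulus type: simulate (replicates are
independent seeded draws), fit, filter, pair with truth. Summaries use 20
log-spaced true-eccentricity bins over [0.01, 8]; the headline statistic
is the *overestimation edge* — the largest bin boundary below which the
median recovered σ exceeds the median true σ by more than 25% in every
lower populated bin (bins with no retained records carry no evidence and
are skipped). At the calibrated noise level the fixed bar's edge falls
near 1.5° while the log bar's is 0 and its binned medians track the
truth across eccentricity. Default scaled-down problem sizes: a 1200-pRF
stratified subsample with 3–5 replicates (the full experiment is 4800
pRFs × 100 replicates and is available by configuration); binned medians
over a stratified subsample estimate the same quantities with ~60
records per bin per replicate.

## Reliability metrics

Intersession reliability pairs estimates unit-by-unit across two sessions
of the same stimulus type, restricted to units passing retention in both
sessions. Eccentricity and σ use Spearman rank correlation; polar angle,
being circular, uses the Fisher–Lee (1983) T-linear circular correlation,
computed in O(n) via trigonometric moment identities and tested against
the literal O(n²) pairwise formula. That choice is deliberate and
documented because inequivalent "circular correlations" circulate
(Jammalamadaka–SenGupta differs); Fisher–Lee is invariant to independent
rotations of either variable. Coefficients are mapped to Fisher z =
arctanh(r) before any averaging. A synthetic two-session generator (two
independent noise draws over the same ground truth) exercises these
metrics without real data; σ reliability decreases monotonically with
the noise level, as tested.

## What the synthetic data do and do not show

The generator reproduces the *geometry* of the measurement — aperture,
timing, hemodynamic blur, TR sampling, retention selection — and a noise
level anchored to an empirical mean VE. It does not model temporal
autocorrelation or physiological drift, surface sampling, partial-volume
effects, amplitude variation across voxels, or nonlinear spatial/temporal
summation. Passing tests therefore demonstrate the stimulus-design
effect (size bias and retention asymmetry and their dependence on
eccentricity) under idealized noise, not absolute reliability levels of
real recordings.

## Numerical choices and limitations

- Even-sized pixel grids have no pixel exactly at fixation; pixel centers
  carry coordinates and analytic checks use actual pixel centers.
- Warp interpolation is bilinear with re-binarization at 0.5; identity
  behavior under k → 0 holds except at interpolation boundary pixels.
- The degenerate center pixel (r = 0) maps to the origin; output pixels
  whose source eccentricity exceeds r_max are blank.
- Seed fan-out: every stage derives its RNG seed as
  SeedSequence([global_seed, stage_index]) reduced below 2³¹, so stages
  are independently reproducible.
- The optimizer is a local simplex; with noise-free data it recovers
  parameters to well under 1% (tests assert 5% over a broad range), but
  with heavy noise it inherits grid-search basin choices — which is the
  phenomenon under study, not a defect to be removed.
- σ below roughly one stimulus pixel (0.148° at 108 px) is only weakly
  constrained by any stimulus; the log bar mitigates but cannot abolish
  this.
- The simulated size-eccentricity rule implies σ = 0.2° at ecc ≈ 0.67°;
  descriptions tying σ < 0.2° to "below 1.5° eccentricity" in the
  literature are not internally consistent with that rule, so summaries
  here are reported on eccentricity bins only.
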