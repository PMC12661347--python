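# Methods

This note documents the models, parameter choices, and numerical
decisions behind `catrack`, and what the synthetic-data tests do and do
not establish about behavior on real recordings.

## The synthetic generator defines the test conditions

Every downstream stage is validated against data from
`catrack.synthetic`, which emulates the acquisition the pipeline is
built for:

- **Geometry.** Default field of view 862 × 583 μm imaged as
  796 × 512 px (≈1.08 × 1.14 μm/px), three planes spaced 30 μm, cycled
  at 10.4 volumes/s. Tests and the analysis scripts use a reduced
  128 × 128 μm single plane at 1 μm/px with 600–900 frames so the whole
  suite runs in well under a minute per stage; the code paths are
  identical, only array sizes differ.
- **Cells** are isotropic 2-D Gaussians truncated at 2.5σ, with
  σ = radius/2 and somatic radii drawn from 4–7 μm. Axial defocus dims a
  cell by exp(−(Δz/σz)²) and inflates its footprint by
  √(1 + (Δz/σz)²) with σz = 12 μm by default. This is a deliberately
  simple stand-in for the real point-spread function: it gives the
  structural-stack correlation a smooth, peaked Z profile (which is
  what the Gaussian Z-fit assumes) without claiming optical realism.
- **Dynamics.** Spike trains are Bernoulli events at 0.12–0.2 Hz with
  log-normal amplitudes around 1.0 (a unit spike is a 100% ΔF/F
  transient); calcium follows the exact AR(1) recursion
  c(t) = γ·c(t−1) + s(t) with γ = 0.85 by default. The γ and event
  rates are in the range typical of fast GCaMP variants at ~10 Hz
  volume rates.
- **Background and noise.** A rank-1 background — a smooth random
  spatial map times a slowly varying positive trace — models the
  global fluorescence fluctuation that source-extraction frameworks fit
  with an unconstrained background component. Noise is gamma-distributed
  positive "shot-like" noise (shape 2) plus Gaussian read noise, making
  the gamma-null SNR screening meaningful: a Gaussian null would be
  systematically optimistic in dim regions.
- **Structural channel.** A configurable fraction (default 0.3–0.6 in
  tests) of cells carry a second, nuclear channel at half the somatic
  radius, standing in for a GABAergic nuclear label used as a stable
  registration landmark. Functional-only cells are absent from the
  structural stack by construction.
- **Behavior.** The T-maze simulator produces trials with a 219 cm stem
  and 37 cm arms, trial initiation at ≥5.7 cm/s, memory-trial cue
  positions uniform in [8.5, 153.8] cm, a 120 s response timeout, an
  8 s penalty after errors, and 1–1.5 s random inter-trial delays. Cue
  sides are drawn with a bias-correcting rule over the trailing 40
  trials: P(right) = clip(0.5 + k·(acc_L − acc_R), 0.2, 0.8),
  k = 0.6. The clipping bounds and the linear form are this package's
  stand-in — the original training software's rule is not public — so
  the simulator's bias correction is a documented approximation, not a
  claim about any particular rig.
- **Histology** sections are disks of specified area on a noisy
  background, placed inside a polygonal ROI with enough separation that
  the ground-truth count is well defined.

All generators are pure functions of (parameters, seed); identical
seeds give bit-identical output.

What passing these tests shows: the algorithms are implemented
correctly and recover known ground truth under the stated statistical
structure. What they do not show: robustness to non-rigid tissue
deformation, strong neuropil contamination, overlapping somata,
photobleaching, or optical aberrations — none of which the generator
produces (overlap and demixing are explicitly out of scope).

## Registration

- **Brightness correction** divides an image by its median filter with
  a 25 × 25 px square footprint (reflect padding), with an ε = 1e−6
  floor against division by zero.
- **Correlation metric.** Zero-normalized cross-correlation computed by
  FFT with periodic wrap, with the peak search restricted to
  ±20 px per axis (configurable). Under periodic padding this equals
  the Pearson correlation of the rolled overlap, so an integer-roll
  translation is recovered exactly — the property the equivariance
  tests assert. Sub-pixel refinement is parabolic interpolation around
  the integer peak (an extension; disable with `subpixel=False` for
  exact integer behavior). Ties between equal peaks break toward the
  smallest-magnitude shift. A peak below 0.2 is flagged
  `low_correlation` and cannot satisfy convergence, which prevents the
  closed loop from "converging" onto a spurious residual when the true
  drift is outside the search window.
- **Shift conventions.** XY estimates are corrections: applying the
  returned shift to the moving image best matches the reference. The Z
  estimate is the apparent axial displacement of the tissue, i.e. the
  objective adjustment. The iterative loop therefore updates
  position ← position − (dx, dy, 0) + (0, 0, dz).
- **Z fit.** Least squares of c(z) = a·exp(−(z−μ)²/2σ²) + b with
  initialization b = min, a = max − min, μ = argmax, σ = 2 steps;
  bounds σ ∈ [step/2, z-range], μ within the sampled range ± one step;
  solver tolerance 1e−10. A vanishing amplitude, a failed fit, or a
  center at the grid boundary raises "no axial peak". With the 5 μm
  stack step, ~2.5 μm axial accuracy is the attainable resolution and
  is what the closed-loop tests require.
- **Convergence** uses the < 5 μm rule on all three axes, with
  max_iter = 10 by default.
- **Piecewise-rigid mapping** tiles the images into an r × c patch grid
  (default 4 × 4, minimum 16 px patches), registers each patch rigidly
  after an optional initial shift, and interpolates the per-patch
  shifts bilinearly over patch centers (clamped outside). A 1 × 1 grid
  reduces exactly to the rigid estimate. Masks are transferred by
  forward-mapping pixels and rounding (binary preserved); images by
  bilinear resampling.

## Detection and screening

- **Adaptive threshold**: local mean over a 51 px block plus an offset
  of 3 robust noise SDs (MAD-based), then hole filling (< 10 px²),
  small-object removal (< 20 px²), and 4-connected labeling. Block size
  and offset are configurable; the specific constants are conventional
  choices, not published values.
- **Component extraction** uses seeded mask means plus a rank-1
  nonnegative background rather than a full constrained matrix
  factorization: the factorization is a published external algorithm,
  and the seeded approximation keeps this package self-contained while
  preserving the interfaces (this is the one deliberate simplification
  of the processing chain). The background trace is fit by alternating
  nonnegative updates on non-cell pixels only; its spatial weights
  under cell masks are filled in by masked-Gaussian interpolation
  (σ = 4 px) from the surrounding free pixels — regressing cell pixels
  directly on the background trace would absorb their resting
  fluorescence into the background. The background model is subtracted
  from each mask's raw trace before deconvolution so the denoised trace
  and its baseline describe the cell alone.
- **γ estimation**: the ratio of successive autocovariances
  acov(2)/acov(1), which is exact for an AR(1) process observed in
  white noise (noise inflates only lag 0); clipped to [0.5, 0.99]. The
  median across components is shared by default (`pool_gamma`) because
  single sparse traces give noisy ratios.
- **Deconvolution** solves min ½‖c − y‖² + λ·Σs with s(t) = c(t) −
  γ·c(t−1) ≥ 0 by a pool-adjacency algorithm (merge pools while the
  isotonic-in-decaying-coordinates condition is violated). The ℓ1 term
  is folded into the data as a shift of λ(1−γ) per frame (λ on the
  last). With `debias=True` (default) the spike amplitudes on the
  recovered support are refit by nonnegative least squares, removing
  the λ shrinkage from amplitudes — important for ΔF/F fidelity. At
  λ = 0 the algorithm inverts a noiseless AR(1) trace exactly.
  λ defaults to one noise SD per unit (1−γ).
- **SNR** (the exact published formula behind the original gamma-noise
  evaluator is not available, so this is a documented interpretation
  with a config hook): re-deconvolve with a strong sparsity weight
  (2.5 noise SDs per unit 1−γ, no debias) so noise excursions are
  shrunk to zero while real transients survive; fit a gamma
  distribution by method of moments to the positive residuals; convert
  the survival probability of the sparse trace's peak — Šidák-corrected
  over the trace's effective number of independent samples
  n·(1−γ)/(1+γ) — to an equivalent standard-normal score, clipped to
  [0, 100]. Under this scoring, pure gamma noise scores ~0 and a
  transient 10× the residual scale scores ≥ 2, so the 0.5/1.2
  thresholds separate cleanly.
- **r-value**: Pearson correlation between the binary footprint and the
  mean image over the most-active frames (top decile of the denoised
  trace, minimum 5), inside the mask's bounding box padded by 2 px.
- **Decision rule**: rejection (SNR < 0.5 or r < 0.1) is evaluated
  first and dominates; then acceptance (SNR > 1.2 or r > 0.85);
  otherwise undecided.

## ΔF/F

- **Moving percentile**: centered window truncated at the edges
  (a causal mode is available by flag); linear interpolation between
  order statistics; a trace shorter than the window gets its global
  percentile. Both the detrending and background windows use 500 frames
  and the 8th percentile, in phase with each other.
- **CNMF-style variant**: F0(t) = trend(t) + moving-percentile of the
  background component under the mask; ΔF/F = detrended/F0, unitless.
  The component's 8th-percentile raw offset is added back before
  detrending so the trend carries the cell's resting fluorescence. A
  non-positive F0 raises rather than returning infinities.
- **Simple variant** (percent): F = raw − blood-vessel background;
  F0 = mean of the contiguous ~2 s window minimizing variance (a
  reproducible stand-in for manually choosing an inactive stretch);
  ΔF/F0 = (F − F0)/F0 × 100.
- Both variants are invariant to a multiplicative gain on the movie.

## Matching

Cost = 1 − IoU, set to exactly 1 for pairs with centroid distance
> 10 px or in different planes. The phrase "intersection over union as
the cost" kept by a minimizing assignment with a 0.8 cutoff is read as
1 − IoU (so kept matches have IoU > 0.2); this interpretation is
configurable. Rectangular problems are solved natively; gated pairs may
enter the assignment but can never pass the threshold. Assignment is by
the standard Hungarian solver, checked in tests against an exhaustive
permutation oracle up to 7 × 7.

## Trial analysis

Choice-aligned windows default to 4 s before the choice in 0.5 s bins
(neither value is dictated by the procedure being reproduced; both are
configurable and must tile the window exactly). Timeout trials have no
choice time and are excluded, with the count reported. Normalization is
per-cell min-max; a zero-range cell becomes an all-zero row and sorts
last; peak-bin ties break by cell index. In the two-session comparison,
matched cells are sorted by the first session's peak bin and that order
is applied to both sessions; session-unique cells sort within their own
session.

## Histology

Manual thresholding is replaced by Otsu's method with a manual override
flag. Watershed runs on the distance transform with a 3 px minimum peak
separation. The 5 px²/10 px² minima are strict minimum areas (area ≥
minimum kept). Pixel-to-μm scale is not assumed; expression indices are
reported per px², exactly as count/area × 10,000. The co-expression
matrix z-scores each channel across cells before correlating and
refuses zero-variance channels.

## Problem sizes

The test suite and acceptance script use: 20-seed closed-loop
alignments on 128 × 128 px single-plane fields (13-position stacks,
2 frames/position); 200 noisy Z-fits; 100 assignment matrices ≤ 7 × 7;
20 matching runs with 40 cells each; 20 ΔF/F sessions of 8 cells ×
600 frames; 50 moving-percentile oracle traces; 20 histology sections.
These sizes make every stage's statistics stable while keeping the full
suite around a minute of compute; all are parameters, not limits.

## Known limitations

No demixing of overlapping somata; no non-rigid registration beyond the
patchwise map; no neuropil-ring subtraction; the SNR formula is an
interpretation (swappable via config); the behavior simulator's
bias-correction rule is a stand-in; particle counting assumes
bright-on-dark staining.
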