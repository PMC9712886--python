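# Methods

`mammofract` classifies 64×64 mammographic regions of interest (ROIs) as
*normal* or *abnormal* (containing a microcalcification, MC) from the
shape of their multifractal singularity spectrum plus four co-occurrence
texture statistics. This note records the models, the numerical choices,
and what the synthetic benchmark does and does not establish.

## Multifractal model

A gray image is treated as a mass measure: the probability of box *i* of
side *L* is its intensity sum over the total intensity,
`P_i(L) = N_i(L) / N_T`. For a multifractal measure the *q*-th moments
scale as `Σ_i P_i(L)^q ~ L^τ(q)`, defining the mass exponents `τ(q)` and
generalized dimensions `D_q = τ(q)/(q−1)`. The singularity spectrum
`f(α)` — the dimension of the set of points with Hölder exponent α — is
the Legendre transform `α = dτ/dq`, `f = qα − τ`.

Two independent estimators are implemented.

**Box counting (generalized fractal dimensions).** `τ(q)` is the
least-squares slope of `log Σ P_i^q` against `log L` over a ladder of
dyadic box sizes; `D_1` uses the entropy limit (slope of `Σ P_i log P_i`
vs `log L`). The spectrum is obtained either by numerical Legendre
transform (central differences) or, preferably, by the direct
Chhabra–Jensen route: with normalized measures
`μ_i(q,L) = P_i^q / Σ P_i^q`, the slopes of `Σ μ_i log P_i` and
`Σ μ_i log μ_i` against `log L` give `α(q)` and `f(q)` without
differentiating a fitted curve. All moment sums are evaluated in the log
domain (`logsumexp`), so `q = ±4` on near-singular measures does not
overflow; empty boxes are excluded (required for q < 0); non-square or
non-dyadic images are zero-padded to the next power of two.

*Defaults.* q from −4 to 4 in steps of 0.1 (81 values); box sizes
{2, 4, 8, 16, 32} for 64×64 ROIs. L = 1 and L = side are dropped: the
single-box and per-pixel extremes contribute no scaling information and
destabilize the fits. On the 256×256 deterministic multinomial cascade
with weights (0.4, 0.3, 0.2, 0.1) the estimator reproduces the
closed-form `τ(q) = −log₂ Σ p_j^q` to machine precision and the direct
spectrum gives `α(0) = 2.1757`, because a dyadic cascade is *exactly*
scale-invariant on dyadic boxes — this is the repository's central
oracle (`synthdata.cascade_analytic`).

**MF-DMA (multifractal detrended moving average).** At each scale *n*
the field is integrated by a sliding n×n window sum `Y`, detrended by
the moving-average surface `Ỹ` (the average of the in-window cumulative
sums, equivalent to a separable triangular-weighted window sum), and the
residual is cut into disjoint n×n segments. The q-th order overall
fluctuation `F_q(n)` is the power mean of the per-segment RMS residuals
(logarithmic mean at q = 0); `F_q(n) ~ n^H(q)` gives the generalized
Hurst exponents, `τ(q) = qH(q) − D_f` with `D_f = 2` for an image
support, and the spectrum follows by Legendre transform.

*Defaults.* Backward windows (θ₁ = θ₂ = 0, the standard DMA
recommendation; centered/forward available), square segments, scale
ladder {4, 6, 8, 12, 16} for 64×64 ROIs and a geometric ladder up to
side/4 otherwise. Segments with squared fluctuation below 1e−24 are
dropped (they are singular for q < 0); a scale loses more than 10% of
its segments, it is discarded; fewer than 3 surviving scales is an
error.

*Calibration.* The window integration means a *smooth surface* must be
handed over as its increment field: feeding an fBm surface directly
saturates H(2) near 2, while feeding its second mixed difference
(`mfdma.double_increments`) recovers H(2) ≈ 0.36 / 0.51 / 0.69 for
generator Hurst 0.3 / 0.5 / 0.7 across seeds. Measure-like fields
(cascades, intensity ROIs) are analyzed as-is. A constant surface
leaves a spatially constant residual — there is nothing to detrend — and
raises a degenerate-surface error; note the equal-weight cascade *is*
such a constant measure, the zero-width monofractal limit.

## Enhancement (pre-processing)

Dense breast tissue veils MCs the way haze veils a scene. The chain is:

1. **Breast-field crop** — delete empty border rows/columns (background
   threshold 0 by default; configurable for noisy exports).
2. **Low-light enhancement by dehazing** — invert the image, apply the
   dark-channel prior (patch 15, ω = 0.8, t₀ = 0.1, airlight from the
   brightest 0.1% of dark-channel pixels, no guided-filter refinement),
   re-invert. Deterministic; constant inputs map to constant outputs.
3. **α-image** — per pixel, the sum-measure over centered windows of
   size 1, 3, 5 (intensity shifted by 1/255 so logs are defined;
   replicate padding at borders) is regressed in log-log coordinates;
   the slope is the local Hölder exponent α(m,n). Smooth tissue has
   α ≈ 2; an MC, being a near-point mass at these window scales, has
   α well below 2.

The enhanced image is the **singularity magnitude** |α − 2| min-max
rescaled to [0, 1]. Rescaling α itself would render MCs *dark* (small α)
and, on ROI-sized inputs, the per-image normalization erases exactly the
contrast the α-image creates; the magnitude map puts smooth tissue near
0 and singularities near 1, matching what an enhanced mammogram looks
like, and empirically is what makes the abnormal/normal spectrum-width
gap widen under enhancement. A degenerate (constant) α-map returns a
zero image with a `constant_alpha` flag.

## Features

Five spectrum descriptors: `α₀` (α at the spectrum maximum; ties broken
toward q nearest 0), width `w = α_max − α_min` over the q grid, left and
right half-widths `R = α₀ − α_min` and `L = α_max − α₀`, and asymmetry
`A = R/L` (undefined and flagged when L = 0; `w = R + L` holds to
machine precision by construction). Four Haralick statistics — contrast,
correlation, energy, homogeneity — of the non-symmetric gray-level
co-occurrence matrix at offset (0, +1), with intensities quantized to 8
levels over the ROI's own range (8 keeps a 64×64 matrix well populated;
16/32/256 configurable). Correlation uses the standard-deviation
normalization so it stays in [−1, 1]. Undefined entries are emitted as
NaN with flags; the classifier imputes them with training-fold medians.

## Classification

Stratified 5-fold cross-validation; per fold, features are median-imputed
and z-scored with training-fold statistics only (zero-variance columns
pass through flagged), then an SVM with a degree-2 polynomial kernel
(C = 1, coef0 = 1, gamma = 'scale'), a 5-NN on the standardized features,
or a default-impurity decision tree is fit. No hyper-parameter search.
Confusion counts are pooled across folds (each sample predicted exactly
once); per-fold metrics are also reported, and sensitivity, specificity,
accuracy and precision are all emitted as percentages with *abnormal*
as the positive class. Zero-denominator metrics are NaN, never raised.

## Synthetic data: what it emulates

Real MC-annotated mammogram collections are access-restricted, so the
benchmark is synthetic with known ground truth.

* **Multiplicative cascades** — quadtree multinomial measures with
  closed-form `τ(q)`, `α(q)`, `f(q)`; deterministic or per-node shuffled
  weight placement (randomizes texture, preserves the spectrum).
* **fBm surfaces** — spectral synthesis with PSD `f^−(2H+2)`; the
  monofractal control.
* **ROIs** — a dense-tissue emulation: intensity = 0.7 (density base,
  the "haze") + 0.2-contrast texture, where the texture is the
  *logarithm* of a shuffled cascade with weights (0.3, 0.25, 0.25, 0.2)
  (an optical-density-like field whose heterogeneity still tracks the
  weights), smoothed by a 1.5 px Gaussian — the imaging point-spread
  scale, below which tissue has no structure. An abnormal ROI adds one
  isotropic Gaussian blob of σ = 1.5 px (a near-point object images as
  the PSF itself) with amplitude 5× the background fluctuation scale
  (99th percentile of |intensity − median|), clipped at saturation.
  Normal ROIs are background only. Every ROI has an independent
  background realization; all generators are pure functions of
  (specification, seed).

With these settings the raw classes are nearly indistinguishable in
spectrum width (w ≈ 0.004 vs 0.005, as subtle as real before-enhancement
ROIs) while enhancement opens a wide gap (≈ 0.25 vs 0.47 on average) —
the qualitative before/after structure the pipeline exists to produce.

**What the synthetic study does not show.** The blobs are clean
isotropic Gaussians on stationary texture; real MCs vary in shape and
sit on nonstationary anatomy with acquisition noise. Consequently both
spectrum estimators resolve the synthetic singularity about equally
well: pooled SVM accuracies of the box-counting and MF-DMA feature sets
differ by less than a percentage point either way across dataset seeds,
so the benchmark supports "both estimators separate the classes at
≥ 90% accuracy" but cannot resolve a robust ranking between them.
Passing tests establish internal consistency against analytic oracles
and the directional behavior of the pipeline, not clinical performance.

## Problem sizes and numerical conventions

Oracle fixtures are 256×256 (cascade depth 8); the end-to-end study uses
200 + 200 ROIs of 64×64, which keeps the full suite and the acceptance
script in the tens of seconds on one CPU. Coordinates are 0-based
(row, col), ROI windows half-open with the center at index size/2;
normal-ROI sampling uses Chebyshev distance (min 64 px from every
abnormal center), a 0.75 minimum tissue fraction, and a 10,000-attempt
rejection-sampling cap. Regression slopes are plain least squares with
per-fit R² reported. All randomness flows from explicit integer seeds;
repeated runs are bit-identical.
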