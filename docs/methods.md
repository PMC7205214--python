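# Methods

This note documents the models implemented in `retipulse`, the assumptions
behind the synthetic-data generator, and the numerical and design choices
made where the problem left them open.

## Signal model

A recording is an ordered stack of 8-bit RGB fundus frames covering three
cardiac cycles (typically ~70 frames at 25 fps). Cardiac timing is an input:
the per-cycle frame counts (derived externally, e.g. from pulse-oximeter
audio) define the phase time of frame *i* in cycle *c* as
*t = i/n_c + (c − 1)* with *i = 0..n_c−1*, so *t* spans [0, C) half-open and
no two frames share a phase time. Cycles need at least 4 frames.

The pulse signal of a vessel template or pixel cluster is the per-frame mean
of the green channel over its retained pixels. A pixel is excluded when its
mean RGB intensity lies within 1% of pure black or pure white on the 0–255
scale (≤ 2.55 or ≥ 252.45) — sensor noise and the central vessel light
reflex. The mean-of-RGB form follows the rule's usual statement; per-channel
bounds would differ only for strongly colored saturated pixels. Cluster
tilings anchor at the top-left pixel and drop partial edge tiles rather than
padding them, so every analyzed pixel belongs to exactly one tile and no
tile mean is computed over a short sample. Stored 8-bit values are used
as-is (no gamma linearization). Rigid integer-pixel frame alignment is
available but off by default; registration quality is deliberately outside
the analysis surface.

### Harmonic regression

Each series is modelled as a sum of a periodic cardiac trend, a non-periodic
drift, and AR(1) noise:

    y(t) = μ + Σ_{n=1..N} [a_n cos(ωnt) + b_n sin(ωnt)]
             + s₁t + s₂(t−1)₊ + s₃(t−2)₊ + e_t,
    e_t = ρ e_{t−1} + u_t,   u_t white noise.

* **Angular frequency.** ω = 2π per cycle by default, so harmonic *n*
  completes *n* periods per cardiac cycle; an `angular_factor` parameter
  accepts π for the half-frequency parameterization some sources print
  (which would give the first harmonic a two-cycle period — not physical
  for a cardiac signal).
* **Drift spline.** A truncated-power linear spline with knots at t = 1 and
  t = 2 (the cycle boundaries): movement artifacts last on the order of a
  cycle. The constant terms of the Fourier and spline parts are jointly
  unidentifiable, so a single intercept is fitted and reported.
* **AR(1)/REML.** ρ is estimated by profiling the restricted-likelihood
  criterion over ρ ∈ [−0.95, 0.95] with bounded scalar minimization
  (tolerance 1e-6), computing GLS coefficients by AR(1) whitening at each
  candidate. With ρ fixed at 0 the fit is exactly OLS. `sigma2_` is the
  REML innovation variance of u_t.
* **AIC.** Model order is selected by AIC = −2·logL + 2k with k = p + 2
  (fixed coefficients plus ρ and σ²) and logL the *restricted*
  log-likelihood at the fit — the criterion the model is estimated under,
  and what R's `AIC()` reports for a REML-fitted GLS model. The restricted
  likelihood charges additional design columns through its log|X′V⁻¹X|
  term; the ML variant at n ≈ 70 selects a spurious third harmonic in a
  quarter of replicates, which contradicts the observed dominance of the
  first two harmonics at 25 fps. Ties break toward the smaller order.
  Orders above 3 are out of scope (the frame rate cannot resolve them).
* **HRW_a.** The harmonic regression wave amplitude is the peak-to-trough
  excursion of the fitted periodic component over one cycle. Extrema are
  located on a 512-point cycle grid and polished by a bounded continuous
  search in the neighbouring grid cells, so a single harmonic's HRW_a
  equals 2√(a_n² + b_n²) to floating-point accuracy. HRW_a is invariant to
  the intercept and to any drift representable by the spline.

### Photometry

Green-channel intensity is treated as transmittance at the hemoglobin
isosbestic point: A = −ln T, and the nominal optical path
d = A / (ε·c_mmol), halved under the reflectance double-pass assumption,
reported in micrometers. Defaults: ε = 12 L/mmol/cm, hemoglobin
150 g/L, molar mass 64,500 g/mol. The `nominal_units` flag reminds users
these lengths are uncalibrated and meaningful only relatively.

### Geometry

V_Dist of an image point is the arc length from the optic-disc center to
the point's projection onto the digitized centerline, divided by the disc
diameter in pixels. When the centerline starts at the disc margin the
straight-line gap from the disc center is added. Coordinates are 0-based
(row, col); arc length is the Euclidean sum over polyline segments; points
farther than a configurable limit (default 10 px) from the centerline are
rejected. The point of maximum pulsation is the argmax of the
moving-median-3 smoothed log-amplitude profile (ties to the smallest
V_Dist); its shift across force levels is summarized by an OLS slope on ODF.

## Attenuation statistics

Per-series amplitudes become records (log₁₀ HRW_a, V_Dist, ODF, vessel
type, eye, subject). Zero amplitudes mean no detectable pulse and are
dropped (counted, not offset-adjusted — an offset would bias the
attenuation slope). Log base 10 is used throughout.

Mixed models are fitted with statsmodels `MixedLM` (REML), with random
intercept and V_Dist (or predictor) slope grouped by *eye within subject*,
implemented as one grouping factor keyed `subject/eye`: with random slopes
and ~28 eyes a second nesting level is not estimable. Demographic factors
(age, gender, laterality, hemiretina) can enter as fixed covariates; they
cannot form random-slope grouping factors at this sample size. If the
random-slope fit is singular or fails to converge the model falls back to a
random intercept with a logged warning. P-values use the Wald normal
approximation and 95% CIs are estimate ± 1.96 SE; small-sample df
corrections (Satterthwaite, Kenward–Roger) are deliberately out of scope.
The implementation is cross-checked against `lme4` in the test suite
(estimates agree to ~1e-9, SEs to ~1e-5).

Marginal and conditional R² follow the Nakagawa–Schielzeth decomposition:
var(fixed predictions) and the mean of z′Gz over observations for the
random part, against the total including residual variance. Standardized
coefficients β_σ multiply each estimate by the SD of its design column over
the SD of the response; the interaction is standardized by the SD of the
product column, making β_σ invariant to affine predictor rescaling.

Vessel-type comparisons: Kruskal–Wallis (tie-corrected, χ² p-value;
identical samples return H = 0, p = 1) for median amplitudes, and an
F-test of the vessel-type × V_Dist interaction in a combined fixed-effects
model for the attenuation slopes. Descriptive summaries report median,
range, linear-interpolation IQR, adjusted Fisher–Pearson skewness, Pearson
kurtosis (normal = 3, bias-corrected), and Pearson's second skewness
coefficient 3(mean − median)/sd as the normality criterion (flagged
undefined for constant samples).

## Synthetic-data generator

The generator defines the study conditions the analyses are validated
under. Defaults: 28 eyes (two per subject), 9 runs per eye with a 0-force
baseline and uniform ODF increments to 180 g, 20 V_Dist points on [0, 1]
DD, three cycles of 23 ± 2 frames at 25 fps, venous fixed effects
(0.90, −0.34, 0.0015, −0.00084) and arterial (0.66, −0.13, 0.0007,
−0.0005).

Each series is mean level + amplitude-scaled two-harmonic waveform +
piecewise-linear drift + AR(1) noise. The waveform shape (a₁, b₁, a₂, b₂) =
(0.93, −0.81, −0.24, 0.09) reproduces the observed sign pattern (dominant
positive first-harmonic cosine, opposed sine, smaller second harmonic) and
is rescaled to unit peak-to-trough before amplitude scaling, so the
noiseless HRW_a equals 10^(true log₁₀ amplitude) exactly under the
package's amplitude convention. Drift knots sit exactly at t = 1, 2 so
drift is exactly representable by the estimator's spline — estimator
correctness is tested without model mismatch. Cycle lengths are drawn once
per recording and shared by all positions of that recording (all clusters
of a video share one cardiac timing). `noise_sd` is the marginal SD of the
AR(1) noise (default 1.0 intensity units, ρ = 0.3). Identical config and
seed give bit-identical output.

Noise scales for the record-level generator were derived once from the
study's variance decomposition: with marginal R² ≈ 0.21 and conditional
R² ≈ 0.66 for veins, and the fixed-effect variance implied by the design
(≈ 0.019 log₁₀² units), the between-eye variance must be ≈ 0.040 and the
residual ≈ 0.030 — hence per-eye random intercept/slope SDs of 0.17 and a
record-level residual SD of 0.17 log₁₀ units. A fitted interaction model on
generated studies indeed returns R² ≈ 0.2/0.65.

Two generator routes exist by design: `generate_series` produces the full
time-domain series (feeding extraction and harmonic-fit validation), and
`generate_attenuation_records` draws log₁₀ amplitudes directly from the
amplitude law plus residual noise — the study-scale route for mixed-model
recovery, where re-fitting hundreds of thousands of harmonic regressions
per replicate would be pointless for what is being tested.

`render_frames` rasterizes one recording: a gently curved vessel whose
centerline starts at the disc center and whose total arc length equals one
disc diameter, darker than the background, with anti-aliased edges; the
green level at arc position *s* interpolates the generated series of the
neighbouring V_Dist points. The returned binary template covers only the
fully-shaded vessel core, so template means are not diluted by edge
anti-aliasing; 8-bit quantization limits round-trip amplitude recovery to
~2%, well inside the 5% validation tolerance. The generator does **not**
emulate eye movement or inter-frame misalignment, optical blur, uneven
illumination, vessel caliber change (the paper's signal is intensity, not
diameter), or pulse-oximeter audio. Passing round-trip tests therefore
demonstrate estimator and plumbing correctness under the assumed signal
model, not robustness to acquisition artifacts of real recordings.

In simulation examples quoted as "SNR 5", the noise SD is defined as
RMS(de-meaned periodic signal)/5.

## Mapping and units

Amplitude maps hold one value (HRW_a, a coefficient, or the intercept) per
cluster; grid dimensions are floor(image/cluster) and missing clusters are
NaN. Heat maps are exported as PNGs with the `viridis` colormap (named in
the export metadata); the value→color normalization can be fixed across all
force levels of one eye so cross-panel amplitude growth is visible, and
exports are byte-reproducible for fixed inputs. Force conversions:
1 Meditron unit = 3.33 g; induced IOP = 0.89·ODF(g) + baseline (mmHg), with
baseline accepted in a configurable physiologic band (default 5–60 mmHg).

## Problem sizes and known limitations

The validation suite uses the study-scale design (28 × 9 × 20 records, 50
replicates) for mixed-model recovery, 200 series of length 70 for AR(1)
recovery, 100 replicates for order selection, and a 96×96-pixel rendered
recording for the imaging round trip — sizes at which every check is a
few-minute computation.

Known limitations: Wald-z intervals for group-level fixed effects are
mildly anti-conservative with ~28 eyes (measured 2-SE coverage ≈ 0.93–0.95
against a nominal 0.954); amplitude maps inherit 8-bit quantization noise;
the rendered scene is a single idealized vessel, not a vascular tree; and
harmonics above the second are unresolvable at 25 fps and not modelled.
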