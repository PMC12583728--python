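# Methods

## Signal model and synthesis

A synthetic recording is silence plus additive white Gaussian sensor
noise, with each buzz an amplitude-shaped sum of harmonics:

    x(t) = Σ_h d^(h-1) sin(h φ(t)),   φ(t) = 2π ∫ f(τ) dτ,

with 3 harmonics and geometric decay d = 0.5 by default — enough
harmonic structure to make "fundamental frequency" distinct from
"spectral peak", which is what the estimator must resolve. The
instantaneous frequency f(t) is the nominal f0 plus an optional slow
wander (white noise smoothed over 50 ms, rescaled to `f0_jitter_sd`).
The envelope is attack–sustain–release (10% / 80% / 10% of the buzz by
default); a rectangular option exists but puts a broadband onset click
into every buzz. Before noise, each buzz is rescaled so its maximum
absolute value equals the planned peak acceleration exactly, which makes
peak recovery exactly checkable. Defaults mirror the field protocol:
60 s recordings at 20,480 Hz, buzz durations from ~0.1 to a few seconds,
fundamentals within the observed 81–444 Hz range.

What the generator does **not** model: contact mechanics between thorax
and accelerometer (coupling variation appears only as per-buzz amplitude
differences), resonances of the mounting, non-Gaussian field noise, and
buzz-internal amplitude modulation beyond the envelope. Passing tests
therefore certify the pipeline's numerics, not robustness to every field
artifact — which is why the per-recording threshold override exists.

## Extraction

**High-pass (20 Hz, Hann, 512).** A windowed-sinc FIR of 512 taps at
20,480 Hz has a transition band ~an order of magnitude wider than a
20 Hz cutoff, so that textbook design cannot express this filter. The
kernel actually used is δ − w/Σw (w a 513-point Hann window): exact DC
rejection, <4% gain below 10 Hz, unity ±2.5% above its first null at
2·fs/513 ≈ 80 Hz — i.e. flat over the entire buzz band. It is symmetric
and applied once by centred convolution, hence zero-phase: detected
onsets are not shifted. For cutoffs that are realisable at the
configured length, the standard Hann-windowed sinc is used instead.

**Segmentation.** The 8% threshold is taken relative to the maximum of
the whole recording's moving-RMS envelope (10 ms window; robust to
single-sample spikes), because raw traces are uncalibrated relative to
full scale. Runs above threshold separated by gaps under 20 ms are
merged (one amplitude-modulated buzz should not split), and runs under
0.1 s are discarded. Geometry note: with a relative threshold, a buzz of
amplitude A in a recording whose loudest buzz has amplitude A_max crosses
threshold a fraction 0.08·A_max/A of the way up its attack ramp, so
onset error grows with amplitude disparity and attack length. The
±25 ms round-trip guarantee therefore applies to amplitude-matched
plans (ratio ≲ 3, durations ≲ 1 s at the default 10% attack); larger
disparities are exactly the situation where the field protocol adjusted
thresholds per recording by hand.

**Peak acceleration** is the maximum of the 2-sample moving average of
the absolute signal — "smoothed peak" in the sense of the vibration
literature; homogeneous of degree 1 in the signal by construction.

**Fundamental frequency.** Frames of 512 samples, 50% overlap. Per
frame the estimate is the lag-domain (quefrency-domain) periodicity:
the normalised autocorrelation, overlap-corrected (capped at 4×),
searched past its first zero crossing; among local maxima within 85% of
the strongest, the smallest lag wins (rejecting period multiples), with
parabolic interpolation. A frame contributes only if its peak
periodicity exceeds 0.3; an implied fundamental above the 1000 Hz cap is
flagged, not aliased onto a subharmonic (a pure 1500 Hz tone yields a
missing value, not 750). The buzz-level value is the median over valid
frames, robust to octave errors at buzz edges; buzzes with no valid
frame are flagged and excluded from per-bee f0 means only. A liftered
log-cepstrum variant (`f0_method="cepstrum"`) is retained as a
cross-check; it needs harmonic-rich frames and is biased for pure tones
and ≤3-harmonic signals at this window length, which is why it is not
the default. Resolution: lags are integers, so precision at f0 is
fs/⌊fs/f0⌋ − fs/(⌊fs/f0⌋+1) (≈2.3 Hz at 217 Hz); with fewer than two
periods per frame (f0 ≲ 80 Hz at the default window) the estimator is
unreliable, which bounds the usable range from below at about the
observed minimum buzz frequency.

## Mixed models

Per-bee means are modelled as y = Xβ + Σ_k Z_k b_k + ε with independent
Gaussian random intercepts for species and caste (crossed) and
categorical fixed effects in sum-to-zero contrasts (Type III tests are
contrast-dependent; this is fixed, not configurable). Fitting is REML:
the profiled criterion is minimised over log variance ratios
(Nelder–Mead, 1–2 free parameters), with all V⁻¹ quantities computed
through the Woodbury identity on a q×q core (q = total random levels,
≈18), making one fit a few milliseconds — the property that makes
1000-replicate bootstraps and 100-seed recovery studies cheap. With no
random terms the same path is exact OLS. Agreement with lme4/lmerTest
(coefficients, SEs, variance components, REML log-likelihood, F and
denominator df) is verified in the test suite to ~1e-3 relative.

Satterthwaite denominator df are computed from the observed information
of the REML criterion in the variance parameters (central-difference
Hessian) and a numeric gradient of the contrast variance; multi-df terms
pool eigencontrast dfs so the F statistic keeps its first moment.
Variance components estimated at the boundary contribute zero
uncertainty rows rather than invalidating the approximation — this
matches lmerTest's behaviour and, unlike a Wald-χ² fallback, does not
inflate the test level. If no variance parameter is free the df
degenerate and Wald χ² p-values are reported and labelled. Measured
levels: ~5% for OLS-path terms; ~6–8% for interaction terms in the
mixed design at 15 species × 3 castes (identical to lmerTest on the same
data) — an intrinsic small-levels property of the approximation, noted
here because the stepwise-elimination guarantees inherit it.

Stepwise reduction removes, one at a time, the least significant
interaction with Type III p > α (default 0.05), refitting after each
removal, then applies the same rule to explicitly listed optional terms
(quadratic temperature, location); main effects are never removed and a
removal log is returned. Conditional R² is Nakagawa–Schielzeth:
(var_fixed + Σ var_random) / (var_fixed + Σ var_random + var_residual),
var_fixed taken over the modelled data.

## Thermal performance

Prediction curves are population-level (random effects zero): numeric
covariates held at their sample means, categoricals averaged over levels
(equal to the contrast-zero point under sum coding), CI by the delta
method on the fixed-effect covariance. The peak is −β₁/(2β₂) when
β₂ < 0 (no interior maximum otherwise — an error, not a silent
boundary). Its CI is a nonparametric cluster bootstrap: bees (rows of
the per-bee table) are resampled with replacement — bees are the
independent unit after per-bee averaging; a stratified-by-species option
exists — the model refitted (warm-started at the full-data variance
ratios, relaxed tolerance), predictions evaluated on a 200-point grid
over the observed temperature range, and the argmax recorded; the CI is
the 2.5/97.5 percentile over replicates. Non-converging replicates are
dropped and counted; above 20% failures the estimate aborts. Note the
distinction, which the package reports rather than hides: the analytic
vertex of the printed acceleration/air coefficients (7.95, −0.17) is
23.38 °C, while full-model grid peaks on any particular dataset land
wherever that dataset's fit puts them.

Model comparison across temperature variables reports conditional R²
and AIC; AIC uses a maximum-likelihood refit (REML likelihoods are not
comparable across fixed-effect structures) with k = fixed effects +
variance parameters.

## Thermoregulation

The air→thorax curve is a 4-parameter logistic
T_th = L + (U − L)/(1 + exp((M − T_air)/s)): two asymptotes are the
biologically meaningful choice (minimum operating temperature in cold
air; a ceiling below CT_max in hot air). Fitting is unconstrained
Levenberg–Marquardt least squares; the (scale, L↔U) sign ambiguity is
canonicalised to s > 0. Initialisation from data quantiles (5th/95th
thorax percentiles, median air, quarter air range), with up to five
seeded perturbed restarts on failure. Both models' AICs use the same
Gaussian convention n·log(RSS/n) + n·log 2π + n + 2k with k counting
curve parameters plus error variance (5 vs 3), asserted by the identity
ΔAIC = 2Δk at equal RSS. Pseudo-R² is 1 − RSS/TSS about the mean; the
raw value is retained even when negative.

## Synthetic populations and study-scale defaults

Generating coefficient sets (`thermobuzz.reference`) are the published
field estimates treated as truth; populations default to 215 bees from
15 species (6 specialist, 9 generalist) across three castes, masses
uniform on 0.05–0.6 g, air temperatures either field-uniform
(13.0–21.1 °C), lab-discrete (5–35 °C every 5 °C), or a half/half
combination mirroring the pooled analysis; thorax temperatures either
uniform on 16–44 °C or tied to air through the logistic link with
4.3 °C scatter (the scatter scale implied by the field sigmoid's
residual sum of squares). Group spreads default to SD 15 (species),
5 (caste), and residual SD 30 (frequency, Hz) or 60 (acceleration,
m s⁻²), chosen to sit near the printed standard errors' implied noise
level. Buzz counts per bee are a parameter, not a distribution — the
field average was ~52 per bee, but nothing in the pipeline depends on
the count's law.

## Problem sizes

Recovery studies use 100 seeded replicates per quantity (200 for the
isometric slope, 500 for test-calibration rates); bootstrap coverage
runs use 200 inner replicates × 100 outer datasets. These sizes put
Monte-Carlo error comfortably inside each stated tolerance while keeping
the full suite in the minutes range on a single CPU.

## Known limitations

* Onset accuracy degrades with amplitude disparity (relative-threshold
  geometry above); per-recording threshold overrides are the remedy, as
  in the original protocol.
* f0 below ~80 Hz (two periods per 512-sample frame) is outside the
  validated range.
* Satterthwaite tests carry mild level inflation for interaction terms
  with few grouping levels (shared with the reference implementation).
* The bootstrap argmax is grid-quantised (200 points over the observed
  range); CIs narrower than one grid step are reported as such.
* Random effects are intercepts only; no random slopes, no
  species-level phylogenetic covariance.
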