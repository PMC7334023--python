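# Methods

This note documents the models, conventions and numerical choices behind
the package, what the synthetic-data generator does and does not emulate,
and the known limitations.

## Signal conditioning

**Force calibration.** Tendon-buckle voltage is mapped to Newtons by
ordinary least squares against known applied loads.  A calibration with
R² ≤ 0.97 is flagged (warning, or an error in strict mode); the threshold
is configurable.

**Dropout and level-shift repair.** Sonomicrometry traces occasionally
drop out (NaN runs) or jump by a constant offset when the transit-time
detector locks onto a different echo.  NaN runs up to `gap_limit` samples
(default 100) are filled by a local cubic spline through neighbouring
samples; longer gaps are left unfilled and the strides overlapping them
are excluded rather than silently interpolated.  A level shift is a
*single-sample discontinuity*: a first difference that departs from the
local running-median slope by more than 6 robust SDs **and** by more than
2% of the signal range.  The absolute floor matters — a detector based
only on the global spread of first differences fires on steep but smooth
physiological segments and corrupts the trace.  The shorter side of each
detected jump is offset to meet the longer side; this removes the
discontinuity but cannot know which level was "true", so a shift in the
majority segment leaves a constant offset (which the fractional-length
normalization largely absorbs).

**Smoothing spline.** Lengths are smoothed with a natural cubic smoothing
spline defined by a bound on the residual sum of squares: the smoothest
curve whose RSS does not exceed `tolerance` (mm² for a trace in mm;
default 0.1, configurable).  The penalty parameter is found by bisection —
RSS is monotone in the penalty — so a larger tolerance never yields a
rougher curve, and tolerance 0 returns the interpolant.  Note that under
this "smoothest within budget" semantic even a noise-free polynomial is
reproduced exactly only as the tolerance goes to zero, because the
minimizer is free to spend the whole residual budget on extra smoothness.
The config value `auto` sets the bound to n·σ̂² with σ̂ estimated from the
median absolute *second* difference (scaled by √6); second differences are
insensitive to the waveform's slope, so a noise-free trace yields a
near-interpolating spline.  A first-difference estimator was rejected: it
confounds slope with noise and oversmooths.

**Fractional length and velocity.** L₀ is the mean smoothed length over
the bird's level-terrain strides (first to last foot contact, an integer
number of strides); L = ℓ/L₀; V = dL/dt by central differences
(second-order one-sided at the ends), shortening negative.  No additional
filtering is applied after the spline.

**EMG.** Zero-phase 4th-order Butterworth band-pass (default 10–1000 Hz,
the upper edge clipped below Nyquist for lower sample rates; the hardware
chain is assumed to have applied its own 10 Hz–3 kHz filter), then
full-wave rectification.  The signed band-passed signal feeds the wavelet
filterbank; the rectified version is what stride cycles carry for display.

## Wavelet intensity

The filterbank uses 11 nonlinearly spaced center frequencies
cf_j = (j + 1.45)^1.959 / 0.3 ≈ 7–395 Hz with frequency windows
W(f) = exp{a[ln(f/cf) + 1 − f/cf]}, a = cf·scale — unit gain at cf,
bandwidth growing with cf.  Per band, intensity is ½|z|² of the analytic
(one-sided-spectrum) response, so for stationary signals summed intensity
equals in-band power.  The window gains are renormalized to a partition of
unity (ΣW² = 1) between the first and last center frequency; this makes
E_tot comparable to ∫emg² dt for in-band signals (the suite checks 20%
agreement).  A complex-Morlet CWT (PyWavelets) is available behind the
same contract for cross-checking.

E_tot integrates total intensity over the stride's time window at full
rate; E_freq is the intensity-weighted mean of band center frequencies.

## Burst timing

The onset criterion is the one genuinely open choice in this chain (the
underlying experimental literature rarely states one).  Detection runs on
the smoothed amplitude (√intensity, circular Gaussian kernel, default 1%
of the cycle), whose fades under a stochastic carrier are half as deep as
the intensity's.  The threshold is

    baseline_mean + max(k·baseline_SD, rel_floor·(plateau − baseline_mean))

with baseline statistics from a quiet mid-swing window (default the
quarter cycle centered on phase 0, wrapping) and k = 3.  The `rel_floor`
term is the degenerate-baseline guard: with a clean recording the baseline
SD is numerically zero and a pure k·SD rule would track filterbank
leakage.  The plateau level is estimated robustly (median of samples above
quarter-maximum) so the floor follows the typical burst amplitude rather
than a chance peak.  Sub-threshold gaps shorter than 8% of the cycle are
closed before the longest supra-threshold run is taken; onset and offset
are linearly interpolated crossings.

For a symmetric smoothed edge the half-level crossing (rel_floor = 0.5,
the function default) is unbiased.  For traces produced by the *analytic*
filterbank the step response passes a true amplitude edge at ≈0.6 of the
plateau — the quadrature component lifts the modulus at the edge — so the
pipeline configuration uses `burst_rel_floor: 0.6`; this constant was
measured on the filterbank's own step response.

E_phase = onset − swing-peak-length phase, wrapped to (−0.5, 0.5]
(negative = earlier activation); the peak-length instant is refined with a
3-point parabolic fit.  E_phase in milliseconds is E_phase·T_stride.

## Segmentation, categories, outliers

Cycles run from mid-swing to mid-swing: the midpoint of each
toe-off → next-contact interval, or, when toe-off events are absent, the
swing-phase peak-length instant between contacts (documented fallback).
Each cycle is resampled to 200 phase-uniform points (≥2 points per percent
of cycle, the resolution of the reported phase quantities).

Category codes follow the instrumented leg's obstacle contacts: S0 on the
contact, S−1/S+1 adjacent, S+2 elsewhere in obstacle terrain, L on level
terrain.  A stride that is simultaneously S+1 of one obstacle and S−1 of
the next takes S−1 (anticipation precedence; configurable).

Outlier exclusion computes Z-scores of every metric within
(cohort × category) groups and flags non-S0 strides with any |Z| > 4
(any-exceeds rule over all metrics, since the original rule's variable set
is unstated; configurable).  S0 strides are never excluded; groups with
fewer than three strides are skipped.

## Mechanical metrics

P = −F·v_m with v_m = dL/dt·L₀ in m/s reconciles the two conventions in
use — shortening strain negative, shortening work positive — and is
verified against the closed-form area πab of an elliptical force–length
loop (Green's theorem) and against the signed polygon area of the loop.
T_force uses a 5%-of-peak threshold (none is standard; configurable).
Landmarks at peak force use the discrete argmax by default (first index on
ties); the pipeline refines the peak instant with a 3-point parabolic fit
because the force peak is locally quadratic and flat enough that the
discrete argmax wanders several grid steps at ΔF ~ 10⁻⁴.

## Perturbation analysis

Per individual, category and channel: pointwise mean with a t-based 95%
CI.  The deviation trajectory is d_i(φ) = mean_S0,i − mean_L,i per
individual, then the grand mean and cross-individual t-based 95% CI
(t quantiles rather than normal because cohorts have ~6 individuals).  The
first significant phase is the start of the earliest run of at least 2% of
the cycle where the CI excludes zero; the persistence requirement
suppresses single-point crossings.  Channel coupling is the zero-lag
Pearson correlation of grand-mean deviations (the full normalized lag
profile is also returned).

## Mixed-model statistics

Five candidate models per metric, all with a random intercept per
individual, fitted by maximum likelihood so AIC and likelihood-ratio
comparisons across fixed-effect structures are valid: intercept-only,
+treatment, +stride category, both, and both with interaction.  The
interaction model is used for inference on every metric regardless of the
AIC winner (with the selection table and 4-vs-5 LRT logged), keeping one
consistent inference model across metrics.

Fixed effects use sum-to-zero coding, so block Wald F-tests are
type-III-style with numerator df 1 (treatment), 4 (category), 4
(interaction).  Denominator df follow the between–within rule: treatment
(a between-individual factor) is tested against n_individuals − 2; the
within-individual terms against the residual df (n − k, in the thousands
for realistic tables).  Pairwise contrasts are linear combinations of the
model's population-level cell means — the individual random intercepts
drop out by construction, which implements "comparisons with the
individual effect removed" with calibrated standard errors; a utility that
literally subtracts the estimated (BLUP) intercepts from the responses is
also provided.  The treatment contrast (reinnervated − intact, averaged
over categories) uses the small between-individual df; the
category-vs-level contrasts within a cohort use the residual df.

With six individuals per cohort, Wald CIs ignore variance-component
uncertainty and run ~5% narrow (simulated coverage ≈ 93–94% at nominal
95%); a Kenward–Roger-type correction is out of scope and the effect is
documented rather than patched.

Significance uses a single Benjamini–Hochberg threshold — the largest
sorted p with p_(i) ≤ (i/m)·q, q = 0.05 — over the pooled vector of all
F-test and contrast p-values across all metrics.

A (near-)constant response column (e.g. a perfectly periodic stride
period in noise-free synthetic data) admits no inference and is skipped
with a warning rather than fitted.

## The synthetic generator

One level and one obstacle trial per individual; each trial carries one
padding stride at both ends so mid-swing segmentation recovers exactly
`strides_per_trial` cycles matching the ground-truth rows one for one.
The stride template is built from raised-cosine segments: swing stretch to
a single length peak at 20% of the cycle, rapid shortening to foot contact
(35% on level terrain, 10% earlier on obstacle strides), near-isometric
early stance, stance shortening, and a swing return that meets the cycle
boundary at unit fractional length with zero slope.  Force is zero in
mid-swing and unimodal in stance, rising from just before contact to a
peak before midstance.  Toe-off events are placed so that each
toe-off/next-contact midpoint falls exactly on the nominal stride
boundary, making the ground-truth stride period exact.

The stance-shortening depth of every stride is solved from the work
target — the work integral is affine in the depth — so the noise-free
trapezoidal work equals the prescribed level (default 2 J kg⁻¹, plus
3.6 J kg⁻¹ on obstacle strides; obstacle force is scaled ×1.2).  Each
individual draws one additive work offset (SD 0.3 J kg⁻¹), one
multiplicative force factor (SD 5%) and one activation-onset offset
(SD 0.002 cycles); these defaults are free parameters of the generator,
not measured values — the emulated study does not report level-terrain
variances.

The EMG burst is a plateau envelope with 2%-of-cycle cosine ramps centered
on the nominal onset/offset (so the envelope crosses one half exactly at
the nominal edges), multiplied by a band-limited noise carrier
(default 80–250 Hz) whose Hilbert envelope has been equalized to constant
modulus.  The equalization is deliberate: with a raw Gaussian carrier the
per-stride burst-edge location is uncertain by the carrier's envelope
correlation time (~2–4% of the cycle) for *any* detector, which would make
per-stride ground-truth timing unrecoverable; a constant-modulus carrier
keeps the prescribed spectral band (E_freq) while making burst timing
identifiable from a single stride.  Real EMG has amplitude-modulated
carriers — per-stride timing jitter of a few percent of the cycle is an
honest property of real recordings, and passing timing tests here says
nothing about that jitter, only about the detector's bias.

Additive Gaussian sensor noise (relative SD, default 0.002) is applied per
channel after ground truth is extracted.  Ground-truth metrics are
computed from the noise-free full-rate traces by the same defining
formulas (trapezoidal work, discrete argmax landmarks), which is exactly
what makes them an oracle for the resampled, conditioned pipeline path.

What the generator does **not** emulate: stride-period variability,
force–length/velocity coupling through a muscle model, tendon compliance,
history-dependent force, electrode cross-talk, within-trial drift or
amplitude non-stationarity of the EMG, and contralateral-leg obstacle
coding.  Results on synthetic cohorts therefore validate the measurement
chain, not muscle physiology.

## Problem sizes

Synthetic cohorts in the test suite and the acceptance script use a 2 kHz
sample rate, 8–15 strides per trial and 3–6 individuals per cohort; the
statistics simulations use 500 null replicates and 200 effect replicates
at stride-table level.  These sizes were chosen so the full suite and the
acceptance run each complete in about a minute on one CPU while keeping
every tolerance stated above meaningful; the generator's default sample
rate (10 kHz) matches the emulated acquisition chain and is used where
rate itself is under test.

## Known limitations

- The burst detector's 0.6 edge-crossing constant is specific to the
  analytic filterbank's step response; other intensity estimators should
  use the 0.5 default.
- The level-shift repair leaves a constant offset when the artifact
  occupies the majority of a trace, and processes multiple jumps
  sequentially without re-estimation.
- Wald CIs are mildly anticonservative at cohort sizes of ~6 individuals
  (see above).
- E_freq depends on the filterbank's band weighting near the carrier band
  edges; absolute values should be compared only within one filterbank
  configuration.
- Ankle angle at contact is accepted as a pre-computed per-stride column
  and flows through the statistics layer; the package does not digitize
  video.
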