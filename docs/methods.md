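# Methods

## The problem

MoCA (0–30 points; < 26 indicates impairment) is the standard manual
screen for mild cognitive impairment.  The package regresses
MoCA-equivalent scores from single-channel auditory EEG in two ways: a
multi-trial branch that works on grand-average event-related potentials
(ERPs), and a single-trial branch that maps individual-trial
time–frequency images to scores with a small CNN.  Everything below is
the package's own account of what is computed and why.

## Synthetic cohort generator

No public dataset matches this design, so the generator is first-class,
tested code, and the study conditions it emulates are its defaults:
15 cognitively normal subjects (MoCA ~ N(27.6, 1.18²)) and 8 MCI
subjects (N(23.0, 1.85²)), scores rounded and clipped to [0, 30]; five
vowel stimuli; 200 trials per stimulus; 700 ms epochs with 100 ms
pre-stimulus.  The default sampling rate is 1 kHz to keep array sizes
practical; it is a plain configuration knob and acquisition-grade rates
(20 kHz) work identically (sample count = round((pre+post)·fs/1000)+1,
onset at t = 0, pre-stimulus negative).

**ERP morphology.** Each subject's noiseless template is a sum of four
Gaussian deflections — the simplest shape that preserves peak/latency
semantics: Pa (+0.8 µV at 30 ms, σ 4 ms), P1 (+2.0 µV at 70 ms, σ 8 ms),
N1 (−4.0 µV at 100 ms, σ 10 ms), P2 (+3.0 µV at 180 ms, σ 22 ms),
roughly the amplitudes and latencies of cortical auditory evoked
potentials in older adults.  Component amplitude and latency drift
linearly with MoCA relative to the reference score 26 (the
normal/impaired boundary).  No literature value ties MoCA quantitatively
to ERP morphology, so the slopes are free parameters chosen once at
moderate, plausible magnitudes — amplitude: Pa +0.02, P1 +0.10,
N1 −0.25, P2 +0.15 µV/point; latency: −0.5 ms/point for N1 and P2 —
and correctness is defined by parameter recovery (the pipeline must find
the planted effects), not by literature fidelity.

**Noise and artifacts.** Per-trial background noise is a mix of white
and 1/f-shaped ("pink") Gaussian noise (default SD 12 µV per sample,
pink fraction 0.5), reflecting the 1/f character of EEG background; both
are settable to zero for exact tests.  A configurable fraction of trials
(default 5 %) receives a 120 µV slow Gaussian deflection (an
eye-blink-like artifact) at a random latency, guaranteed to trip the
±50 µV rejection rule.  Response times are lognormal (meanlog −0.5 ≈
0.61 s median, sdlog 0.25), with 5 % of trials replaced by out-of-range
values (< 0.2 s or > 1.5 s) to exercise the RT filter.  All draws flow
from one seed through per-subject seed-sequence substreams; identical
spec + seed gives bit-identical cohorts.

What the generator does **not** emulate: vowel acoustics and
stimulus-specific response differences (all five stimuli share a
subject's template), multi-channel topography, realistic blink
waveshapes, non-stationary drift, or line noise.  Passing tests
therefore demonstrate that the pipeline recovers planted linear
MoCA–ERP structure under realistic noise — not that it would achieve any
particular error on clinical data.

## Multi-trial preprocessing

Baseline correction subtracts each trial's pre-stimulus mean
(subtraction method).  Artifact rejection drops trials with any sample
strictly exceeding ±50 µV; "surpassing" is read strictly, so a sample at
exactly ±50 µV survives — the common ERP convention; both threshold and
strictness are configurable.  The grand average is the arithmetic mean
of surviving trials.  The 0–30 Hz band-pass is a zero-phase
forward–backward Butterworth of order 4 (no filter family is canonical
here; Butterworth is the usual ERP choice); a 0 Hz low edge degenerates
to a pure low-pass, and the doubled (filtfilt) order-4 response gives
≈ 48 dB attenuation one octave above the cutoff (measured ≥ 40 dB at
60 Hz in the tests).

For the single-trial branch, trials are kept when the response time is
within [0.2, 1.5] s — these bounds are sometimes printed in
milliseconds in the clinical literature, which is physically impossible
for an auditory categorization task; seconds are implemented and the
unit is configurable — and the trial's peak-to-peak range is ≤ 100 µV.
Kept trials are truncated to [onset, onset + RT], carried as a
zero-padded rectangular array with per-trial valid lengths.

## Feature bank

**Prominent points.**  Pa, P1, P2 are window argmaxima and N1 the window
argmin (N1 is by definition a negative deflection; a toggle treats it as
a maximum if ever needed) in the 25–35, 60–80, 90–110, 150–250 ms
windows; ties break to the earliest latency.  Peak amplitude, peak
latency and window mean amplitude per component, plus four relative band
powers (periodogram power in δ 0.5–4, θ 4–8, α 8–13, β 13–30 Hz —
standard clinical edges, configurable — normalized over the band
union), give 16 features per stimulus, 80 over five stimuli.

**Windowed dynamics.**  A 25 ms window with 50 % overlap slides across
the whole 700 ms epoch (55 windows at these settings; the last
incomplete window is dropped).  In each window all 107 catalog
characteristics are computed; for each characteristic's trajectory, the
slope (Δvalue/Δt) and coefficient of variation (sd/|mean|) of every
adjacent window pair are features.  The pairing of *adjacent* windows
was chosen over hand-picked timeframe pairs because it is deterministic
and parameter-free; CV of a zero-mean unequal pair is flagged missing
and such columns are dropped before selection.

**The 107-entry catalog** is an original, versioned registry in the
spirit of highly comparative time-series analysis: distribution
statistics (moments, order statistics, quantiles, proportions within
k·SD of the mean), correlation properties (ACF at lags 1–12, partial
ACF, ACF summaries, AR(1) fits, trend and difference statistics) and
entropies/complexity (histogram, spectral, permutation, approximate,
sample, Lempel–Ziv, Hjorth, Petrosian).  The exact identity of the
entries is a declared approximation to the much larger feature libraries
used in that literature — what is contractual is the count (exactly
107), name stability, determinism, and finiteness: every entry has a
documented fallback for degenerate windows (ratio statistics → 0;
proportion-within-k·SD of a constant window → 1; capped sample
entropy), so no window ever produces NaN/inf.

**Screening.**  Feature screening for "similar within groups, different
between groups" is, in practice, done by eye; the automated surrogate
retains dynamics features by standardized separation
|mean₁ − mean₂| / pooled SD, either above a cutoff or the top-N
(N = 510 by default so the assembled candidate feature vector is
80 + 510 = 590).  Prominent-point and band-power features are always
retained.

## Lasso selection

Coordinate descent solves min (1/2N)Σ(yᵢ−β₀−xᵢᵀβ)² + λΣ|βⱼ| on
z-scored columns (standardization is mandatory for penalty
comparability; computed on training folds only during CV), iterating to
an objective-decrease tolerance of 1e−7.  The λ grid has 100 log-spaced
values from λ_max = max|Xᵀ(y−ȳ)|/N (the null threshold) down to
1e−4·λ_max, solved warm-started in descending order.  "Deviance" is the
5-fold cross-validated mean squared prediction error (the Gaussian
deviance); λ* is its minimizer with ties broken toward larger λ (the
sparser model).  If the null model wins CV outright, the driver falls
back to the sparsest non-empty support with the lowest deviance.  A
random-forest permutation-importance ranking (with top-25 truncation)
is available as an alternative ranker.

## Regression

All four methods are scored on identical seeded 5-fold assignments
(paired comparison), pooling held-out predictions:

* **MR_logit** — linear least squares on logit(y/30), back-transformed
  by 30·logistic(·); predictions are bounded in [0, 30] by
  construction.  Boundary scores are shrunk by half a point (30 → 29.5)
  before the logit, a choice that cannot be validated externally and is
  therefore a documented default.
* **ER** — least-squares boosting with 100 depth-3 trees (the common
  default of ensemble-regression implementations); bagging by config.
* **SVR** — ε-insensitive RBF SVR, C = 1, ε = 0.1, z-scored inputs.
* **RR** — ridge with penalty chosen by inner 5-fold CV over a 25-point
  log grid (a fixed `alpha` bypasses the search, which the exact-recovery
  tests use).

RMSE and MAE use the standard formulas; RMSE ≥ MAE is *not* asserted
anywhere (it is false in general).

## Residual diagnostics

QQ data pair the i-th order statistic of the standardized residuals with
Φ⁻¹((i−0.5)/n) (the (i−0.5)/n plotting positions; other conventions
exist and differ negligibly at these n).  Because the usual adjudication
between models is visual, the numeric surrogates are: Shapiro–Wilk for
normality; for homoscedasticity/pattern, the Pearson correlation of
|residual| with fitted value plus a Wald–Wolfowitz runs test on residual
signs ordered by fitted value.  Decisions are reported with their
statistics at a configurable α (default 0.05).  Constant residuals make
the normality test undefined and are flagged degenerate.  No automatic
"model X is superior" verdict is produced.

## Single-trial branch

Each kept trial (onset to response) becomes a spectrogram with a
length-adaptive window (an eighth of the trial, ≥ 8 samples, 75 %
overlap), cropped to ≤ 100 Hz, log₁₀-scaled, bilinearly resampled to a
fixed small image (default 32×32; tests and the acceptance run use
16×16) and z-scored per image.  Fixed shape makes trials of different
durations batchable; per-image normalization removes gross gain
differences while keeping relative spectral structure.

The CNN is implemented directly in NumPy: three blocks of same-padded
conv → relu → 2×2 maxpool (8 filters each), flatten, inverted dropout,
dense(16) → tanh → dense(1), MSE loss, adadelta (ρ = 0.95, ε = 1e−6,
no learning rate).  Backpropagation is exact (verified against numeric
gradients to ~1e−9 relative error).  Targets are z-scored internally
during training and predictions un-scaled, keeping adadelta's unit-free
updates well conditioned.  Every sample's label is its subject's MoCA,
so cross-validation folds are grouped by subject — without grouping,
trials of the same subject would appear on both sides of a fold and the
error would be optimistic.

**Bayesian optimization.**  The three tunable hyperparameters are
discretized (filter size ∈ {3,5,7,9}, dropout ∈ {0.10…0.60 step 0.05},
epochs ∈ {10…100 step 10}) so that sampling "without repetition" and the
argmax of EI over candidates are well defined.  Stages: 5 uniform
pre-samples without repetition, each scored by grouped CV-RMSE; a
5-kernel comparison (Matern, RBF, RationalQuadratic, ExpSineSquared,
DotProduct) ranked by SSE of the GP posterior mean at the training
inputs (failed fits score ∞; ties break by list order); 15 exploration
rounds of fit-GP → argmax-EI → evaluate.  GP regression delegates to
scikit-learn with hyperparameter inputs normalized to [0,1]³; the
acquisition and loop logic are implemented here.  On the EI sign: with
f⁺ defined as the *lowest* RMSE so far, the formulation
Z = (μ−f⁺)/σ combined with argmax-EI selection would chase high
predicted loss; the default therefore uses the minimization-consistent
Z = (f⁺−μ)/σ, with the sign-flipped variant available as
`mode="literal"` for comparison.  EI is exactly 0 at σ = 0.

## Problem sizes used in tests and the acceptance script

The multi-trial acceptance runs use the full design scale — 23 subjects
× 5 stimuli × 200 trials at 1 kHz, the complete 590-feature CFV — which
completes in about a minute per run on one CPU.  Lasso-recovery is
checked over 20 cohort seeds with the prominent-point block (where the
effects are planted), requiring a planted-component feature in the
selected set in ≥ 95 % of seeds and ER/SVR CV-RMSE below the score SD.
The single-trial acceptance run is scaled down as a deliberate design
point: 12 subjects × 2 stimuli × 25 trials at low background noise
(SD 2 µV — the per-trial signal must be visible for a single-trial
method to have any chance), 16×16 images, epochs ≤ 15, 5 pre-sample +
5 BO evaluations.  Success is relative, not absolute: the shuffled-label
null's grouped CV-RMSE must sit near the label SD (within 0.7–1.5×; the
small subject count inflates the grouped null somewhat), and the
informative-label CV-RMSE must be lower.  Published error figures from
comparable clinical studies are not reproduction targets here: they
depend on private cohorts.

## Known limitations

* The characteristic catalog approximates, not replicates, the large
  HCTSA-style libraries; findings tied to a specific exotic
  characteristic will not transfer.
* The screening criterion is a univariate surrogate for expert visual
  inspection and ignores feature correlations.
* The NumPy CNN is CPU-bound and intentionally small; it is suitable
  for the image sizes used here, not for large-scale training.
* MR_logit's boundary handling (half-point shrinkage) is one of several
  defensible conventions and materially affects subjects scoring 30.
* The generator's linear MoCA→morphology link is a modeling convenience;
  real effects are unlikely to be linear or purely amplitude/latency.
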