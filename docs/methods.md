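# Methods

This note documents the models, numerical conventions and design choices
behind `fwave`, and what the synthetic-data experiments do and do not show.

## Synthetic F-wave sessions

**Waveform model.** A post-stimulus trace is the sum of an M-wave atom, an
F-wave atom (present on a Bernoulli draw per stimulation) and iid Gaussian
noise. Atoms are built from raised-cosine (Hann) lobes
`a · sin²(π (t − t₀)/w)` on `[t₀, t₀ + w]`. We chose Hann lobes over
Gabor-style Gaussian-windowed lobes because their compact support makes two
contracts exact rather than approximate: ground-truth annotation marks
coincide with analytic lobe centres, and M-segment features are *exactly*
invariant to F-wave parameters once the trace is split at the nerve's cut
point (Gaussian tails would leak ~1e-7 mV across it). The M-wave is
biphasic: a negative lobe (clinical negative deflection, stored as signed
mV) followed by a positive lobe at 0.4× the negative amplitude. The F-wave
is polyphasic: `f_n_phases` alternating lobes spread over 12 ms, leading
lobe negative, geometrically tapered (ratio 0.75).

**Physiology defaults** (control condition): F-latency means 28/29/48/50 ms
for ulnar/median/fibular/tibial, M onsets 3.5–5.5 ms, M durations 9–10 ms —
consistent with the 20 ms (upper limb) / 35 ms (lower limb) M/F segment
boundaries. M amplitudes 4–10 mV with per-subject log-normal variability
(log-SD 0.25); F amplitude is 12 % of the subject's M amplitude, capped at
20 %. Noise SD defaults to 0.02 mV. Real recordings' absolute amplitudes and
noise floors vary by hardware and montage; these magnitudes are free
parameters exposed in the pipeline config, not clinical claims.

**Disease presets** encode the qualitative clinical signatures only, with
magnitudes as free parameters: ALS — persistence 0.5 (vs 0.9), chronodispersion
SD 3 ms (vs 1 ms), M amplitude ×0.6, F amplitude ×1.5; IBM — M amplitude
×0.5 only; peripheral neuropathy — +8 ms latency shift, M ×0.7; cervical /
lumbar radiculopathy — mild ALS-direction effects restricted to upper- /
lower-limb nerves.

**Cohorts.** Group sizes are exact. Ages and BMIs are drawn from a shifted
log-normal fitted to match a 5th/50th/95th percentile triple exactly
(mirrored for left-skewed triples, normal for symmetric ones); the default
triples are the matched ALS/control test-cohort values, so demographics
carry almost no label signal — by design, mirroring an age/sex-matched
case-control study. Per-session nerve subsets follow a fixed distribution
in which the fibular+tibial pair dominates and the median nerve is rarest.
F-wave onset latencies are clipped to stay 0.5 ms clear of the segment
boundary (negligible at control dispersion; <1 % of draws at ALS
dispersion).

**Survival.** Durations follow a Weibull proportional-hazards model
`S(t|z) = exp(−(t/λ)^k e^{β'z})` (defaults k = 1.2, λ = 36 months), sampled
by inversion. Numeric covariate betas act on the standardized (z) scale so
a downstream fit on standard-scaled covariates recovers them directly.
Censoring is independent Uniform(0, c) with c calibrated by bisection so
the expected censored fraction matches the target — the simplest
non-informative mechanism.

## Preprocessing

Resampling to 10 kHz uses polyphase rational resampling (Kaiser β = 14
anti-aliasing filter, passband ripple ~1e-7), exact for the 2:1 and 4:1
clinical ratios; non-standard rates are resampled with a warning rather
than rejected. The trim window [2.5 ms, 300 ms) is half-open with sample
index `round(t·fs)`, making counts deterministic (2975 samples) and the M/F
split an exact partition. Time zero is the stimulation instant.

## Wavelet features

A 4-level Daubechies-2 cascade yields the five labelled coefficient sets
cA4, cD4–cD1 (the "five-level" wording in clinical descriptions counts
coefficient sets, which is what the 10 × 5 + 2 = 52 feature arithmetic
requires). Boundary extension is half-sample symmetric. Band power is the
sum of squared coefficients (standard relative wavelet energy); relative
power and entropy are computed per stimulation, like the other band
statistics. Conventions, each fixed and tested against an independent
direct-formula oracle: population (biased) moments; excess kurtosis;
percentiles by linear interpolation; mean crossings count sign changes of
(x − mean) with exact zeros inheriting the previous sign; natural-log
entropy with `r = 0 → SE = 0`. RMS is the true root mean square; the
config switch `rms_literal` selects the mean-square variant for
compatibility with write-ups that omit the square root (immaterial to tree
models either way). Aggregation uses population SDs; a single-stimulation
nerve gets SD 0 with a warning instead of an error. Feature order is fixed:
band-major, statistic-minor, then stimulus duration and amplitude; session
columns are nerve-major with mean before SD.

## Table transform

KNN imputation (k = 10, nan-Euclidean distances over mutually observed
numeric features) is fitted on training rows only, followed by
standardization and one-hot encoding of sex and recording source. The
fitted transform is frozen inside the classifier bundle and reapplied
verbatim to any evaluation table.

## Classifier

One gradient-boosted tree family (LightGBM) with a small grid — learning
rate {0.05, 0.1} × leaves {15, 31} — selected by 5-fold cross-validated
PR-AUC, each fold early-stopped on validation average precision; the winner
is refit at the mean early-stopped size. A single GBM family with CV
replaces a multi-architecture AutoML search: the search adds model-management
machinery without analytic content, and a GBM is the architecture such
searches select on tabular data of this shape. Probabilities are clipped to
[1e-9, 1−1e-9] before the log-odds score so saturated trees stay finite; a
probability exactly at the threshold classifies positive. Bootstrap metric
distributions redraw (rather than skip) single-class resamples, keeping B
effective replicates, and report the redraw count; resampling is
independent over rows. Importance uses the ensemble's additive tree
attributions (mean |contribution|), with permutation importance available
behind the same interface.

## Survival analysis

Cox partial likelihood with Efron tie handling (accurate for
month-resolution ties). Numerics are standard scaled; categoricals one-hot
with fixed reference levels (sex = female, onset site = lower limb, family
history = none) so coefficients are reproducible across runs. Partial-effect
curves hold all covariates at their design means and move one covariate by
±2 SD; median survival is the earliest time with S(t) ≤ 0.5 and is reported
as "not reached" (None) when S never falls that far — never extrapolated.

## Group statistics

One-way ANOVA with Tukey HSD post hoc tests runs on log-odds scores (the
scale on which score distributions are compared), converting probability
thresholds via the log-odds map where needed. The bootstrap-distribution
comparison uses a Welch t-test and always carries a `dependent_replicates`
flag: bootstrap replicates re-use the same predictions, so nominal p-values
overstate evidence. Classification rates are count-exact (integer
numerators and denominators reported beside percentages).

## Pipeline

One global seed fans out to per-stage child seeds by SHA-256 hashing of
`"{seed}:{stage}"` (kept below 2³¹), so a stage re-run in isolation
reproduces its in-pipeline output. Every artifact is a plain CSV or JSON;
the manifest records the config hash (excluding the output path), seed,
version and SHA-256 of each artifact, and two runs with the same seed are
byte-identical.

## Problem sizes used in tests and the acceptance script

Chosen as the package's standard desk-scale experiment sizes: classification
uses 200 + 200 sessions with a 70/30 stratified split; the segment ablation
averages 5 replicate cohorts of 120 + 120; Cox recovery and null calibration
use 200 replicates of n = 2000 (censoring 0.3); the exponential-baseline
median check uses n = 20 000; ANOVA calibration uses 1000 null replicates of
200 + 200 scores.

## What passing tests do and do not show

The generator reproduces the *statistical structure* the analysis assumes —
persistence, chronodispersion, amplitude effects, matched demographics,
missing-nerve patterns, proportional hazards with independent censoring —
not the physiology of real motor-unit firing: no stimulation artefact, no
motor-unit decomposition, no longitudinal within-patient progression, no
inter-device differences beyond a source label, and effect magnitudes are
assumptions. Passing tests therefore validate the pipeline's correctness
and calibration, and show the method *can* separate groups under the
encoded signatures; they say nothing about sensitivity or specificity on
real recordings.

## Known limitations

Binary classification only (mimic groups are scored, not trained on);
probabilities are not calibrated; no time-varying covariates, competing
risks or frailty in the survival model; the annotation comparator uses
simulator ground-truth marks rather than an automatic F-wave detector.
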