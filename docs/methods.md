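# Methods

This note documents the models and numerical choices behind `wearfit`:
how the engineered features are defined, what the synthetic cohort
generator does and does not emulate, and where genuinely open design
decisions were resolved.

## Feature definitions

**HROS.** For each intraday heart-rate sample with timestamp falling in a
recorded step minute `[minute_start, minute_start + 60 s)`,
`hros = bpm / (steps_of_that_minute + 1)`. The `+1` prevents division by
zero in sedentary minutes; the minute's step count is treated as constant
across the minute while every available HR sample is used. HR samples in
minutes *without* a step record are excluded and counted rather than
assumed sedentary: a missing minute record indicates non-wear or
non-sync, not rest. An empty HR stream (on-clip wear) makes the feature
missing for that patient. The per-patient summary is the 1 % quantile of
all HROS samples, computed by linear interpolation between order
statistics (position `(n−1)·q`) — the default of mainstream numerics
stacks, stated here so results reproduce across languages. A robust
quantile is used instead of the minimum because the minimum is an
outlier magnet.

**HROS anomaly flags.** A minimum-covariance-determinant location/scatter
is fit to the univariate HROS values and samples whose robust distance
exceeds the empirical `(1 − contamination)` quantile of all distances are
flagged (contamination defaults to 0.1), so the flagged fraction tracks
the contamination. For streams longer than 5,000 samples the MCD is fit
on a random subsample while the distance threshold is still taken over
all samples; this keeps week-long 5 s streams tractable without changing
the flagged fraction. Streams with fewer than 20 samples or zero scatter
yield no flags with a warning rather than an error. Flags are computed
and stored with the series; the 1 %-quantile summary is taken over all
samples, flagged or not, since the quantile itself is the outlier guard.
No temporal smoothing is applied (an optional window parameter is
deliberately absent until a use case demands it).

**PAL.** Weekly moderate-to-vigorous activity sessions, where one session
is 30 minutes of "fairly active" (moderate) or 15 minutes of "very
active" (vigorous) time:
`sessions/week = (7 / wear_days) · (Σ fairly_min / 30 + Σ very_min / 15)`.
Sessions are *fractional* and normalized to a 7-day week: the level bands
use non-integer cutoffs (e.g. "< 1.5 sessions"), which is incompatible
with integer bout counting, and wear periods range 3–14 days. Bands:
level 1 at exactly 0 sessions; level 2 on (0, 1.5); level 3 on [1.5, 3);
level 4 on [3, 6]; level 5 above 6. The endpoints 3 and 6 are ambiguous
between adjacent levels in the printed bands and are both assigned to
level 4 ("3 to 6" read inclusively). The coefficient table
{0, 0.35, 0.29, 0.64, 1.21} is reproduced verbatim, including the
non-monotonic step from level 2 (0.35) to level 3 (0.29); whether that
step is a typo in the source index is not resolved here.

**NET-F.** `sex·2.87 − age·0.11 − BMI·0.17 − RHR·0.05 + PAL + 21.41`,
sex 1 = male / 0 = female, age in years, BMI in kg/m² (height in
meters — metric BMI values near 25 are only consistent with meters), RHR
in bpm, PAL the coefficient above. RHR is the mean of the device's daily
resting-heart-rate values over the whole wear period (days, not nights
only); when the device never produced one — no night wear, or on-clip
wear that disables the optical sensor — the clinic-measured pre-test HR
is substituted, and the substitution is reported per patient.

**Step aggregates.** Mean and maximum daily totals; a day exactly at
10,000 steps counts as *not below* the activity threshold (≥). Sampling
gaps are summarized as the multiset of successive HR-sample deltas with
the count strictly exceeding 15 s, the device's nominal worst-case
spacing.

## Stratification

The outcome is binarized at 6MWD ≥ 350 m ("fit", boundary included).
Pearson r is reported with the two-sided p from the t transform with
n − 2 df. For ROC analysis the fit class is positive throughout; features
where lower values indicate fitness (HROS, RHR) are negated before curve
construction and the reported cutpoint is mapped back to the original
scale. Candidate thresholds are midpoints between consecutive distinct
scores plus ±∞ sentinels, so cutpoints never coincide with observed
values. "Best trade-off between high TPR and low FPR" is formalized as
maximal Youden J = TPR − FPR — no specific criterion being canonical,
this is the standard choice — with deterministic tie-breaks: smaller FPR,
then fewer patients classified fit. AUC is the trapezoidal area and
equals the Mann-Whitney concordant-pair statistic (property-tested).
Constant scores yield AUC 0.5 and no meaningful threshold, with a
warning.

The rank-sum comparison of 6MWD between predicted groups uses exact
permutation enumeration of the midrank sum whenever
C(n₁+n₂, n₁) < 10⁶ (two-sided p = permutation probability of
|W − E[W]| at least as extreme), and otherwise the normal approximation
with tie correction. Patients with a missing feature are excluded
pairwise per analysis with the excluded count carried into the results;
p-values are reported without multiple-testing correction, matching the
analysis design this package implements.

## Synthetic cohort model

The generator produces cohorts with the statistical structure the
analysis assumes, for testing and demonstration; defaults encode the
study conditions of a 31-patient elderly pre-surgical cohort.

**Latent fitness.** Each patient has a scalar fitness factor
`F = 0.42·z_sex + (−0.35)·z_age + 0.842·ε` (standardized sex and age,
independent standard-normal residual), so F is standard normal and
fitter patients are somewhat more often male and younger.
`6MWD = 328.94 + 99.53·F`, truncated at 50 m. Per-patient resting HR is
`73.03 − 5·F + N(0, 11.8²)` bpm (total SD ≈ 13, matching the cohort
table) and mean daily steps `6500 + 2000·F + N(0, 3400²)`, floored at
1,000 steps/day. Weights and loadings were chosen analytically so the
population feature–6MWD correlations reproduce the reported association
structure: NET-F strongest (~0.6), steps ~0.5, RHR ≈ −0.39, PAL ≈ 0.5,
with the implied male–female 6MWD gap (~90 m) consistent with the
cohort table given its large female-subgroup SD. The steps correlation
sits slightly below its reported 0.59 — reproducing that value and
NET-F dominance simultaneously is not possible under the table's
dispersions, and the ordering was prioritized because it is what the
analysis asserts. BMI is drawn directly as N(24.83, 2.61²) and weight
derived as BMI·height², because independent height/weight draws inflate
BMI dispersion far beyond the demographic table and drown the fitness
index in BMI noise.

**Days and minutes.** Wear duration is a rounded normal (7.03, SD 2.3)
clipped to 3–14 days. Day totals are normal around the patient mean with
SD 1,500 capped at 30 % of the mean (a 6MWT-capable cohort has no
fully step-free days). Minute-level steps are realized as activity bouts
between 08:00 and 21:00: the number of active minutes targets
`total / cadence` with per-patient walking cadence
`45·(1 + 0.10·F + N(0, 0.05)) steps/min`, gamma-distributed per-slot
weights, and a multinomial draw so minute counts sum *exactly* to the
day total. Daily activity-minute categories are then derived from the
realized cadence (light ≥ 20, moderate ≥ 100, vigorous ≥ 130 steps/min —
the usual ambulatory-cadence criteria), which makes step volume and
active minutes co-vary the way device summaries do. The derivation of
active minutes from step cadence is a modeling choice; no empirical
steps-to-active-minutes relationship was available to fit.

**Heart rate.** 5 s cadence over the wear window; each sample is the
day's resting level plus a circadian sinusoid (amplitude 5 bpm, trough
near 04:00), an elevation of 0.3 bpm per step/min of concurrent cadence,
and N(0, 3) noise, rounded and clipped to [25, 250]. Sampling gaps
> 15 s are injected as a Poisson process (default 4/h) by deleting runs
of 3–24 samples, kept non-adjacent so each deletion yields exactly one
gap; injected gap positions are stored in the ground truth so recovery
is exactly testable. No-night-wear patients have streams only
07:00–22:00 (night defined as 22:00–07:00; no definition being given,
this is the package's) and missing daily resting HR; on-clip patients
have an empty HR stream, missing daily resting HR, and full step data.
Clinic HR is the patient's resting level plus N(0, 4), rounded.

**Determinism.** All randomness flows from a single seed through
`numpy.random.SeedSequence(seed).spawn`: child 0 drives cohort-level
draws, child i+1 drives patient i's intraday streams. Two calls with the
same config are byte-identical. Exact failure-mode counts
(`n_on_clip`, `n_no_night`) can override the Bernoulli probabilities to
reproduce observed cohort composition deterministically.

**What the generator does not emulate** — and hence what passing tests do
not show about real data: PPG motion artifacts and optical-sensor bias,
the device's proprietary step/activity classification, true circadian
and day-of-week activity structure, sleep, heart-rate variability,
1 s exercise-tracking cadence, and any nonlinearity or non-Gaussianity in
the fitness–feature relationships. Tests against it validate the
*pipeline arithmetic and the recoverability of a known structure*, not
device accuracy.

## Problem sizes and numerical notes

Generator-fidelity checks run at n = 500 patients (~60 M heart-rate
samples, generated vectorized in ~10 s); association-structure checks at
n = 200; end-to-end demonstrations at the study size n = 31. The
anomaly-detector calibration check averages 100 replicates of n = 500.
Quantile agreement is asserted to 1e-12, formula oracles to 1e-9,
ROC/rank-sum identities to 1e-12. Degenerate inputs (empty HR streams,
constant HROS, constant ROC scores, single-class outcomes, empty
condition sets) return documented missing/warning results rather than
raising, except where the contract is an error (empty groups, zero
variance in a correlation, non-positive wear days).

## Known limitations

- The generator's linear-Gaussian latent factor reproduces marginal
  means/SDs and pairwise correlations only; higher-order structure is
  not modeled.
- The HROS 1 % quantile in synthetic cohorts is a stronger step-volume
  proxy (population r ≈ −0.5) than typically observed in small real
  cohorts; see the note on calibration above.
- PAL session counting is fractional by design; an integer-bout variant
  would need explicit bout detection, which minute-level summaries do not
  support.
- Timestamps are naive local time; multi-site or DST-spanning recordings
  are out of scope.
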