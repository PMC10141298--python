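# wearfit

Preoperative functional capacity is usually assessed with supervised
exercise tests such as the 6-Minute Walk Test (6MWT), whose walked
distance (6MWD, meters) is the standard outcome: ≥ 350 m indicates
adequate exercise tolerance. `wearfit` implements a pipeline that derives
the same stratification from a week of consumer wrist-tracker data
(intraday heart rate at ~5 s cadence, minute-level step counts, daily
summaries), for biostatisticians and digital-health researchers working
with elderly pre-surgical cohorts.

## Features and analysis

From each patient's recording the pipeline engineers:

- **HROS** (heart rate over steps): for every heart-rate sample,
  `bpm / (steps_in_that_minute + 1)`; the per-minute step count is held
  constant within the minute and the `+1` guards the sedentary case.
  Summarized at its **1 % quantile** — a robust minimum; low values mean a
  restrained heartbeat under real load, i.e. high fitness. Anomalous HROS
  samples are flagged with a robust-covariance (elliptic-envelope)
  detector at contamination 0.1.
- **NET-F** (non-exercise-testing cardiorespiratory fitness):
  `sex·2.87 − age·0.11 − BMI·0.17 − RHR·0.05 + PAL + 21.41`
  (sex: 1 = male, 0 = female), with the physical-activity level **PAL**
  derived objectively from device activity minutes: weekly
  moderate-to-vigorous sessions (1 session = 30 min moderate or 15 min
  vigorous activity) mapped to 5 levels with additive coefficients
  {0, 0.35, 0.29, 0.64, 1.21}.
- **RHR**: the device's daily resting heart rate averaged over the wear
  period, substituting the clinic-measured HR when the device never
  produced one (no night wear, or "on-clip" wear with the optical sensor
  disabled).
- **Step aggregates**: mean and maximum daily totals against the
  conventional 10,000-step threshold, plus the distribution of
  heart-rate sampling gaps (> 15 s).

The cohort analysis computes Pearson correlations of each feature with
6MWD, ROC curves with Youden-optimal cutpoints for the composed indices
(NET-F and HROS), Wilcoxon rank-sum comparisons of 6MWD between the
predicted groups with exact small-sample p-values, 2×2 contingency
tables, and conditional probabilities such as
P(6MWD < 350 m | mean daily steps < 10,000).

Because no patient-level dataset is distributable, the package ships a
first-class synthetic cohort generator (`wearfit.synthetic`) that
reproduces the study conditions: the demographic distributions, a latent
fitness factor linking 6MWD to resting HR, step volume and activity
minutes, 7 ± 2-day wear, night non-wear, on-clip failure, and > 15 s
heart-rate gaps. See `docs/methods.md` for the model.

## Worked example

```bash
wearfit run --seed 0 --out demo
cat demo/report/report.txt
```

```
Wearable features vs 6-minute-walk distance
patients analyzed: 31

Correlation analysis (Pearson r vs 6MWD)
  netf               r=+0.617  p=0.0002  n=31
  mean_rhr           r=-0.476  p=0.0067  n=31
  hros_q01           r=-0.675  p=0.0001  n=28  excluded=3
  mean_daily_steps   r=+0.688  p=0.0000  n=31

ROC threshold analysis (fit = 6MWD >= 350 m)
  netf               AUC=0.900  threshold=8.351 (higher_is_fit)  TPR=0.91  FPR=0.10
  hros_q01           AUC=0.950  threshold=1.16 (lower_is_fit)  TPR=1.00  FPR=0.11  excluded=3

...
Conditional probabilities
  P(6MWD<350 | mean steps < 10k): 0.783
  P(6MWD<350 | max steps < 10k): 0.938
```

Reading it: on this simulated 31-patient cohort the fitness index NET-F
and daily steps correlate positively with walked distance, resting HR and
the HROS quantile negatively — the expected physiology. Patients whose
device produced no heart-rate data (on-clip wear) are excluded pairwise
from HROS analyses (`excluded=3`) and fall back to the clinic-measured
resting HR inside NET-F. The ROC section gives each index's
discrimination (AUC) for the 350 m outcome and the cutpoint maximizing
TPR − FPR; e.g. a patient with NET-F above ~8.4 would be predicted fit.
Cohorts are random, so exact values vary with `--seed`.

The same stages are available as `wearfit simulate`, `wearfit features`
(flags `--hros-quantile`, `--contamination`, `--no-fallback-rhr`) and
`wearfit analyze`, or from Python:

```python
from wearfit import SimConfig, generate_cohort, build_features, analyze_cohort

bundle, truth = generate_cohort(SimConfig(n_patients=31, seed=0))
features, log = build_features(bundle)
analysis = analyze_cohort(features, bundle.patients)
print(analysis.to_text())
```

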