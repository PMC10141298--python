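"""Engineered wearable features for functional-capacity assessment.

Implements the feature set used to stratify patients against the 6-minute
walk distance:

* **HROS** — heart rate over steps: for each intraday HR sample, the
  instantaneous ratio bpm / (steps-in-that-minute + 1).  The +1 avoids
  division by zero while sedentary; the per-minute step count is treated
  as constant across the minute.  Summarized at its 1% quantile (a robust
  stand-in for the minimum: low HROS = restrained heartbeat under load =
  high fitness).
* **NET-F** — non-exercise-testing cardiorespiratory fitness, a weighted
  linear index of sex, age, BMI, resting heart rate and a 5-level
  physical-activity level (PAL) derived from weekly counts of
  moderate/vigorous activity sessions.
* **RHR** — the device's daily resting heart rate averaged over the wear
  period, substituting the clinic-measured HR when the device never
  produced one (no night wear, on-clip).
* **Step aggregates** — mean and maximum daily totals against the
  conventional 10,000-step activity threshold.
* **Gap histogram** — distribution of successive HR sample spacings and
  the count exceeding the device's nominal worst-case 15 s.

Anomalous HROS samples are flagged with a robust-covariance (elliptic
envelope) detector at a configurable contamination.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field

import numpy as np

from .io_formats import (
    CohortBundle,
    DailySummary,
    HRSeries,
    PatientRecord,
    StepSeries,
)

logger = logging.getLogger(__name__)

#: PAL level -> additive NET-F coefficient, as printed in the source index
#: (note the non-monotonic step between levels 2 and 3).
PAL_COEFFICIENTS = {1: 0.0, 2: 0.35, 3: 0.29, 4: 0.64, 5: 1.21}

STEP_THRESHOLD = 10_000
GAP_THRESHOLD_S = 15.0
MIN_ANOMALY_SAMPLES = 20


@dataclass
class HROSSeries:
    """Per-sample heart-rate-over-steps values with anomaly flags."""

    patient_id: str
    t: np.ndarray  # datetime64[s]
    hros: np.ndarray  # bpm per (step+1)
    anomaly: np.ndarray | None = None  # bool per sample, None if not computed
    n_uncovered: int = 0  # HR samples with no covering step minute

    def __len__(self) -> int:
        return len(self.t)


@dataclass(frozen=True)
class PALResult:
    """Physical-activity level: weekly MVPA session count mapped to a band.

    One session = 30 min of moderate ("fairly active") or 15 min of
    vigorous ("very active") activity.  Bands: level 1 = no activity,
    2 = (0, 1.5), 3 = [1.5, 3), 4 = [3, 6], 5 = > 6 sessions/week.
    """

    sessions_per_week: float
    level: int
    coefficient: float


@dataclass
class FeatureVector:
    """One row per patient: everything the stratification stage consumes."""

    patient_id: str
    netf: float
    hros_q01: float | None
    mean_rhr: float
    rhr_source: str  # "device" | "clinic_fallback"
    mean_daily_steps: float
    max_daily_steps: int
    above_10k_mean: bool
    above_10k_max: bool
    pal: PALResult
    wear_days: int


@dataclass
class GapStats:
    """Successive-sample spacing distribution for one HR stream."""

    deltas_s: np.ndarray
    n_gaps: int  # deltas strictly greater than 15 s
    gap_fraction: float


# ---------------------------------------------------------------------------
# HROS
# ---------------------------------------------------------------------------


def compute_hros(hr: HRSeries, steps: StepSeries) -> HROSSeries:
    """Heart rate over steps for every HR sample with a covering step minute.

    HR samples whose timestamp falls in a minute without a step record are
    excluded and counted in ``n_uncovered`` (no record means non-wear or
    non-sync, not zero steps).  An empty HR stream (on-clip wear) yields an
    empty result — the feature is treated as missing downstream.
    """
    if len(hr) == 0:
        return HROSSeries(
            hr.patient_id,
            np.array([], dtype="datetime64[s]"),
            np.array([]),
        )
    hr_minute = hr.t.astype("datetime64[m]").astype("datetime64[s]").astype("int64")
    grid = steps.minute_start.astype("int64")
    pos = np.searchsorted(grid, hr_minute)
    covered = (pos < len(grid)) & (grid[np.minimum(pos, len(grid) - 1)] == hr_minute)
    n_uncovered = int((~covered).sum())
    if n_uncovered:
        logger.info(
            "%s: %d HR sample(s) outside any step minute excluded from HROS",
            hr.patient_id,
            n_uncovered,
        )
    step_of_sample = steps.steps[pos[covered]]
    hros = hr.bpm[covered] / (step_of_sample + 1.0)
    return HROSSeries(hr.patient_id, hr.t[covered], hros, n_uncovered=n_uncovered)


def hros_quantile(hros: HROSSeries | np.ndarray, q: float = 0.01) -> float | None:
    """Linear-interpolation quantile of the HROS values (None if empty)."""
    values = hros.hros if isinstance(hros, HROSSeries) else np.asarray(hros, float)
    if len(values) == 0:
        return None
    return float(np.quantile(values, q))


def detect_hros_anomalies(
    hros: HROSSeries | np.ndarray,
    contamination: float = 0.1,
    max_fit_samples: int = 5000,
    random_state: int = 0,
) -> np.ndarray:
    """Flag outlying HROS samples with a robust-covariance elliptic envelope.

    A minimum-covariance-determinant location/scatter is fit to the
    univariate values (on a random subsample when the stream is long) and
    samples whose robust distance exceeds the empirical (1 - contamination)
    quantile of all distances are flagged, so the flagged fraction tracks
    the contamination.  Fewer than 20 samples, or a degenerate
    (zero-scatter) stream, yields no flags with a warning.
    """
    values = hros.hros if isinstance(hros, HROSSeries) else np.asarray(hros, float)
    n = len(values)
    flags = np.zeros(n, dtype=bool)
    if n < MIN_ANOMALY_SAMPLES:
        warnings.warn(
            f"anomaly detection skipped: {n} < {MIN_ANOMALY_SAMPLES} samples",
            stacklevel=2,
        )
        return flags
    if np.ptp(values) == 0.0:
        warnings.warn("anomaly detection skipped: degenerate (constant) HROS", stacklevel=2)
        return flags
    from sklearn.covariance import MinCovDet

    rng = np.random.default_rng(random_state)
    if n > max_fit_samples:
        fit_idx = rng.choice(n, size=max_fit_samples, replace=False)
        fit_values = values[fit_idx]
    else:
        fit_values = values
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # MCD chatter on near-singular subsets
            mcd = MinCovDet(random_state=random_state).fit(fit_values.reshape(-1, 1))
        dist = mcd.mahalanobis(values.reshape(-1, 1))
    except (ValueError, np.linalg.LinAlgError) as exc:
        warnings.warn(f"anomaly detection skipped: {exc}", stacklevel=2)
        return flags
    cutoff = np.quantile(dist, 1.0 - contamination)
    flags = dist > cutoff
    if isinstance(hros, HROSSeries):
        hros.anomaly = flags
    return flags


# ---------------------------------------------------------------------------
# PAL / NET-F
# ---------------------------------------------------------------------------


def derive_pal(daily: list[DailySummary], wear_days: int | float) -> PALResult:
    """Weekly MVPA session count from device activity minutes, banded.

    Sessions are fractional (summed minutes divided by the session length)
    and normalized to a 7-day week by the wear duration, since wear periods
    range 3–14 days and the printed bands use non-integer cutoffs.
    """
    if wear_days <= 0:
        raise ValueError("wear_days must be >= 1")
    fairly = sum(d.fairly_active_min for d in daily)
    very = sum(d.very_active_min for d in daily)
    sessions = (7.0 / wear_days) * (fairly / 30.0 + very / 15.0)
    if sessions == 0:
        level = 1
    elif sessions < 1.5:
        level = 2
    elif sessions < 3.0:
        level = 3
    elif sessions <= 6.0:
        level = 4
    else:
        level = 5
    return PALResult(sessions_per_week=sessions, level=level, coefficient=PAL_COEFFICIENTS[level])


def compute_netf(
    sex: int, age: float, bmi: float, rhr: float, pal_coefficient: float
) -> float:
    """Non-exercise cardiorespiratory fitness index.

    netf = sex*2.87 - age*0.11 - bmi*0.17 - rhr*0.05 + PAL + 21.41
    with sex = 1 for men, 0 for women.
    """
    if sex not in (0, 1):
        raise ValueError(f"sex must be 0 or 1, got {sex!r}")
    if not all(math.isfinite(v) for v in (age, bmi, rhr, pal_coefficient)):
        raise ValueError("NET-F inputs must be finite")
    if not any(
        math.isclose(pal_coefficient, c, abs_tol=1e-12)
        for c in PAL_COEFFICIENTS.values()
    ):
        raise ValueError(
            f"pal_coefficient {pal_coefficient!r} not in {sorted(PAL_COEFFICIENTS.values())}"
        )
    return (
        sex * 2.87 - age * 0.11 - bmi * 0.17 - rhr * 0.05 + pal_coefficient + 21.41
    )


# ---------------------------------------------------------------------------
# RHR / step aggregates / gaps
# ---------------------------------------------------------------------------


def aggregate_rhr(
    daily: list[DailySummary], patient: PatientRecord
) -> tuple[float, str]:
    """Mean device resting HR over the wear period, else the clinic HR.

    Returns ``(mean_rhr, source)`` with source "device" or
    "clinic_fallback" (the substitution used for no-night-wear and on-clip
    patients, whose device never computes a resting HR).
    """
    values = [d.resting_hr for d in daily if d.resting_hr is not None]
    if values:
        return float(np.mean(values)), "device"
    if math.isfinite(patient.clinic_hr):
        logger.info(
            "%s: no device resting HR; substituting clinic HR %.1f",
            patient.patient_id,
            patient.clinic_hr,
        )
        return float(patient.clinic_hr), "clinic_fallback"
    raise ValueError(f"{patient.patient_id}: no device RHR and no clinic HR")


def aggregate_steps(daily: list[DailySummary]) -> tuple[float, int, bool, bool]:
    """Mean/max daily step totals and their 10,000-step threshold flags.

    A day exactly at 10,000 counts as *not below* the threshold (>=).
    """
    if not daily:
        raise ValueError("aggregate_steps requires at least one day")
    totals = np.array([d.total_steps for d in daily], dtype=float)
    mean_steps = float(totals.mean())
    max_steps = int(totals.max())
    return (
        mean_steps,
        max_steps,
        mean_steps >= STEP_THRESHOLD,
        max_steps >= STEP_THRESHOLD,
    )


def gap_histogram(hr: HRSeries, threshold_s: float = GAP_THRESHOLD_S) -> GapStats:
    """Successive-sample time deltas and the count exceeding ``threshold_s``."""
    if len(hr) < 2:
        return GapStats(np.array([]), 0, 0.0)
    deltas = np.diff(hr.t.astype("int64")).astype(float)
    n_gaps = int((deltas > threshold_s).sum())
    return GapStats(deltas, n_gaps, n_gaps / len(deltas))


# ---------------------------------------------------------------------------
# Cohort-level feature assembly
# ---------------------------------------------------------------------------


@dataclass
class FeatureBuildLog:
    """What was skipped or substituted while building the feature table."""

    missing_hros: list[str] = field(default_factory=list)
    clinic_fallback: list[str] = field(default_factory=list)
    uncovered_hr_samples: dict[str, int] = field(default_factory=dict)


def build_features(
    bundle: CohortBundle,
    hros_q: float = 0.01,
    contamination: float = 0.1,
    detect_anomalies: bool = True,
    fallback_rhr: bool = True,
) -> tuple[list[FeatureVector], FeatureBuildLog]:
    """Compute the full per-patient feature table for a cohort.

    On-clip patients (empty HR stream) get a missing HROS quantile and,
    like no-night-wear patients, the clinic-HR fallback for resting HR.
    Set ``fallback_rhr=False`` to raise instead of substituting.
    """
    out: list[FeatureVector] = []
    log = FeatureBuildLog()
    for p in bundle.patients:
        daily = bundle.daily.get(p.patient_id, [])
        if not daily:
            raise ValueError(f"{p.patient_id}: no daily summaries")
        wear_days = len(daily)
        hr = bundle.hr.get(p.patient_id, HRSeries.empty(p.patient_id))
        steps = bundle.steps.get(p.patient_id, StepSeries.empty(p.patient_id))

        hros_series = compute_hros(hr, steps)
        if hros_series.n_uncovered:
            log.uncovered_hr_samples[p.patient_id] = hros_series.n_uncovered
        if len(hros_series) == 0:
            q01 = None
            log.missing_hros.append(p.patient_id)
        else:
            if detect_anomalies:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    detect_hros_anomalies(hros_series, contamination=contamination)
            q01 = hros_quantile(hros_series, hros_q)

        values = [d.resting_hr for d in daily if d.resting_hr is not None]
        if values or fallback_rhr:
            mean_rhr, rhr_source = aggregate_rhr(daily, p)
        else:
            raise ValueError(f"{p.patient_id}: no device RHR and fallback disabled")
        if rhr_source == "clinic_fallback":
            log.clinic_fallback.append(p.patient_id)

        pal = derive_pal(daily, wear_days)
        mean_steps, max_steps, above_mean, above_max = aggregate_steps(daily)
        netf = compute_netf(p.sex, p.age, p.bmi, mean_rhr, pal.coefficient)
        out.append(
            FeatureVector(
                patient_id=p.patient_id,
                netf=netf,
                hros_q01=q01,
                mean_rhr=mean_rhr,
                rhr_source=rhr_source,
                mean_daily_steps=mean_steps,
                max_daily_steps=max_steps,
                above_10k_mean=above_mean,
                above_10k_max=above_max,
                pal=pal,
                wear_days=wear_days,
            )
        )
    return out, log
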