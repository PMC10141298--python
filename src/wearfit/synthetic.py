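"""Synthetic wrist-tracker cohort generator.

Emulates the statistical structure the stratification analysis assumes for
an elderly pre-surgical cohort: demographics drawn from sex-specific
normals, a single latent fitness factor linking the 6-minute-walk distance
(6MWD) to resting heart rate, daily step volume and activity minutes, a
roughly week-long wear period, and the device's observed failure modes
(no night wear, "on-clip" wear with the optical HR sensor disabled, and
heart-rate sampling gaps longer than 15 s).

The latent factor F is standard normal per patient and is built from
standardized sex and age plus an independent residual, so that fitter
patients are somewhat more often male and younger — the pattern a
non-exercise fitness index exploits.  6MWD is an affine function of F
(truncated at 50 m); per-patient resting-HR and step-volume means load on
F linearly with independent Gaussian between-patient noise.  Activity
minutes are not drawn directly: they are derived from the realized
minute-level step cadence, so step volume and active minutes co-vary the
way device summaries do.

All randomness flows from ``SimConfig.seed`` through
``numpy.random.SeedSequence(seed).spawn``: child 0 drives cohort-level
draws and child i+1 drives patient i's intraday streams, so the bundle is
byte-identical across calls with the same config.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict
from datetime import date as _date, timedelta

import numpy as np
import pandas as pd

from .io_formats import (
    CohortBundle,
    DailySummary,
    HRSeries,
    PatientRecord,
    StepSeries,
)

logger = logging.getLogger(__name__)

SECONDS_PER_DAY = 86400

# minute-cadence bands used to classify a minute's intensity (steps/min);
# ~100 steps/min is the usual moderate-walking criterion
CADENCE_LIGHT = 20
CADENCE_MODERATE = 100
CADENCE_VIGOROUS = 130


@dataclass
class SimConfig:
    """Cohort-simulation parameters; defaults reproduce the study conditions.

    Demographic means/SDs are those of the 31-patient cohort the pipeline
    was designed around (22 men / 9 women, mean age 76.06 y, mean 6MWD
    328.94 m); wear time averages 7.03 days (SD 2.3, clipped to 3–14);
    2/31 patients skip night wear and 1/31 wears the device on-clip.
    Loadings are expressed per SD of the latent fitness factor.
    """

    n_patients: int = 31
    p_male: float = 22 / 31
    age_mean: float = 76.06
    age_sd: float = 4.75
    height_mean_male: float = 172.41
    height_sd_male: float = 7.81
    height_mean_female: float = 156.78
    height_sd_female: float = 10.23
    # weight is derived as BMI x height^2 so the cohort's BMI dispersion
    # matches the demographic table instead of being inflated by
    # independent height/weight draws
    bmi_mean: float = 24.83
    bmi_sd: float = 2.61
    sixmwd_mean: float = 328.94
    sixmwd_sd: float = 99.53
    # latent-factor construction: F = w_sex*z_sex + w_age*z_age + w_res*eps
    fitness_weight_sex: float = 0.42
    fitness_weight_age: float = -0.35
    # physiological loadings (per SD of F) and noise scales
    fitness_loading_rhr: float = -5.0  # bpm per SD of F (<= 0)
    rhr_base: float = 73.03
    rhr_between_sd: float = 11.8
    rhr_day_sd: float = 2.0
    fitness_loading_steps: float = 2000.0  # steps/day per SD of F (>= 0)
    steps_base: float = 6500.0
    steps_between_sd: float = 3400.0
    steps_day_sd: float = 1500.0  # capped at 30% of the patient mean
    steps_floor: float = 1000.0  # minimum per-patient mean daily steps
    # walking-cadence model: active minutes per day ~ total / cadence,
    # with fitter patients walking slightly faster
    cadence_base: float = 45.0  # mean steps per active minute at F = 0
    cadence_per_fitness: float = 0.10  # relative cadence gain per SD of F
    cadence_noise_sd: float = 0.05  # relative between-patient gait variation
    # wear protocol
    wear_days_mean: float = 7.03
    wear_days_sd: float = 2.3
    wear_days_min: int = 3
    wear_days_max: int = 14
    p_no_night_wear: float = 2 / 31
    p_on_clip: float = 1 / 31
    n_no_night: int | None = None  # exact-count override of the probability
    n_on_clip: int | None = None
    night_start_hour: int = 22
    night_end_hour: int = 7
    # intraday heart rate
    hr_cadence_s: int = 5
    hr_gap_rate: float = 4.0  # expected injected gaps >15 s per wear hour
    hr_noise_sd: float = 3.0
    circadian_amplitude: float = 5.0  # bpm, trough near 04:00
    hr_per_step: float = 0.3  # bpm elevation per (step/min) of concurrent cadence
    start_date: str = "2021-06-14"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients < 1:
            raise ValueError("n_patients must be >= 1")
        for name in ("p_male", "p_no_night_wear", "p_on_clip"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {p}")
        for name in (
            "age_sd", "height_sd_male", "height_sd_female", "bmi_sd",
            "sixmwd_sd", "rhr_between_sd", "rhr_day_sd",
            "steps_between_sd", "steps_day_sd", "wear_days_sd", "hr_noise_sd",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.fitness_loading_rhr > 0:
            raise ValueError("fitness_loading_rhr must be <= 0 (fit -> lower RHR)")
        if self.fitness_loading_steps < 0:
            raise ValueError("fitness_loading_steps must be >= 0 (fit -> more steps)")
        w2 = self.fitness_weight_sex**2 + self.fitness_weight_age**2
        if w2 >= 1.0:
            raise ValueError("sex/age fitness weights leave no residual variance")

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class GapInfo:
    """Book-keeping for >15 s heart-rate gaps in one patient's stream."""

    injected_starts: np.ndarray  # datetime64[s] of the last sample before each gap
    n_injected: int
    n_boundary: int  # structural gaps (overnight non-wear between days)


@dataclass
class GroundTruth:
    """Latent state stored alongside a generated cohort for recovery tests."""

    table: pd.DataFrame = field(repr=False)
    # columns: patient_id, fitness, true_pal_level, n_injected_gaps,
    #          n_boundary_gaps, wear_days, on_clip, no_night_wear
    injected_gaps: dict[str, np.ndarray] = field(default_factory=dict, repr=False)

    def write(self, path) -> None:
        self.table.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Per-day step realization
# ---------------------------------------------------------------------------


def _day_minute_steps(
    total: int, n_minutes: int, day_offset_min: int, cadence: float, rng
) -> np.ndarray:
    """Distribute ``total`` steps over a day's minute grid as activity bouts.

    The number of active minutes targets ``total / cadence`` so the mean
    per-minute cadence reflects the patient's walking speed; bout start
    minutes fall between 08:00 and 21:00, and gamma per-slot weights let
    cadence vary within and between bouts (the upper tail produces the
    moderate/vigorous minutes).  A multinomial draw guarantees the minute
    counts sum exactly to the daily total.
    """
    out = np.zeros(n_minutes, dtype=np.int64)
    if total <= 0:
        return out
    # active window relative to this day's grid start
    lo = max(0, 8 * 60 - day_offset_min)
    hi = min(n_minutes, 21 * 60 - day_offset_min)
    if hi <= lo:
        lo, hi = 0, n_minutes
    target = min(hi - lo, max(1, int(np.ceil(total / cadence))))
    slots: set[int] = set()
    while len(slots) < target:
        start = int(rng.integers(lo, hi))
        length = int(rng.integers(5, 26))
        slots.update(range(start, min(start + length, n_minutes)))
        if len(slots) >= hi - lo:
            break
    idx = np.fromiter(slots, dtype=np.int64)
    w = rng.gamma(2.5, 1.0, size=len(idx))
    counts = rng.multinomial(total, w / w.sum())
    out[idx] = counts
    return out


def _classify_minutes(minute_steps: np.ndarray) -> tuple[int, int, int, int]:
    """Count (sedentary, light, fairly, very) active minutes from cadence."""
    very = int(np.count_nonzero(minute_steps >= CADENCE_VIGOROUS))
    fairly = int(
        np.count_nonzero(
            (minute_steps >= CADENCE_MODERATE) & (minute_steps < CADENCE_VIGOROUS)
        )
    )
    light = int(
        np.count_nonzero(
            (minute_steps >= CADENCE_LIGHT) & (minute_steps < CADENCE_MODERATE)
        )
    )
    sedentary = int(len(minute_steps)) - very - fairly - light
    return sedentary, light, fairly, very


# ---------------------------------------------------------------------------
# Intraday generation
# ---------------------------------------------------------------------------


def _inject_gaps(n_samples: int, cadence_s: int, rate_per_hour: float, rng):
    """Choose sample runs to delete so each deletion leaves one delta > 15 s.

    Returns (keep mask, gap start indices).  Runs are >= 3 samples at 5 s
    cadence (delta >= 20 s), separated by at least one kept sample and kept
    away from segment edges so gaps never merge.
    """
    keep = np.ones(n_samples, dtype=bool)
    if n_samples < 10 or rate_per_hour <= 0:
        return keep, np.array([], dtype=np.int64)
    hours = n_samples * cadence_s / 3600.0
    n_gaps = int(rng.poisson(rate_per_hour * hours))
    if n_gaps == 0:
        return keep, np.array([], dtype=np.int64)
    starts = np.sort(rng.integers(1, n_samples - 30, size=n_gaps))
    lengths = rng.integers(3, 25, size=n_gaps)  # 20 s .. 2 min at 5 s cadence
    gap_starts = []
    prev_end = -2
    for s, ln in zip(starts, lengths):
        if s <= prev_end + 1:
            continue  # would merge with the previous gap; drop it
        e = min(s + ln, n_samples - 1)
        keep[s:e] = False
        gap_starts.append(s - 1)  # index of the last sample before the gap
        prev_end = e
    return keep, np.asarray(gap_starts, dtype=np.int64)


def generate_intraday(
    patient: PatientRecord,
    daily_profile: list[dict],
    config: SimConfig,
    rng: np.random.Generator,
) -> tuple[HRSeries, StepSeries, list[DailySummary], GapInfo]:
    """Realize minute steps, daily summaries and the 5-s HR stream.

    ``daily_profile`` holds one dict per wear day with keys ``date``,
    ``total_steps`` and ``resting_hr`` (None when the device cannot compute
    it).  Heart rate is the day's resting level plus a circadian sinusoid
    (trough near 04:00), an elevation proportional to the concurrent minute
    cadence, and Gaussian noise, clipped to [25, 250] bpm.  On-clip
    patients get an empty HR stream but a full step stream.
    """
    if not daily_profile:
        return (
            HRSeries.empty(patient.patient_id),
            StepSeries.empty(patient.patient_id),
            [],
            GapInfo(np.array([], dtype="datetime64[s]"), 0, 0),
        )
    full_day = patient.wore_at_night
    start_min = 0 if full_day else config.night_end_hour * 60
    end_min = 1440 if full_day else config.night_start_hour * 60
    n_min = end_min - start_min
    cadence = config.hr_cadence_s
    per_min = 60 // cadence

    all_minutes, all_steps = [], []
    summaries: list[DailySummary] = []
    hr_t_segments, hr_v_segments = [], []

    for day in daily_profile:
        d0 = np.datetime64(day["date"], "s")
        minute_steps = _day_minute_steps(
            int(day["total_steps"]),
            n_min,
            start_min,
            float(day.get("cadence", config.cadence_base)),
            rng,
        )
        sed, light, fair, very = _classify_minutes(minute_steps)
        summaries.append(
            DailySummary(
                patient_id=patient.patient_id,
                date=day["date"],
                resting_hr=day["resting_hr"],
                sedentary_min=sed,
                lightly_active_min=light,
                fairly_active_min=fair,
                very_active_min=very,
                total_steps=int(minute_steps.sum()),
            )
        )
        minute_t = d0 + (start_min + np.arange(n_min)) * np.timedelta64(60, "s")
        all_minutes.append(minute_t)
        all_steps.append(minute_steps)

        if patient.hr_available:
            sec = (start_min * 60) + np.arange(n_min * per_min) * cadence
            hour = sec / 3600.0
            rhr_day = day["resting_hr"] if day["resting_hr"] is not None else day["rhr_latent"]
            circ = config.circadian_amplitude * np.cos(2 * np.pi * (hour - 16.0) / 24.0)
            elev = config.hr_per_step * np.repeat(minute_steps, per_min)
            bpm = rhr_day + circ + elev + rng.normal(0.0, config.hr_noise_sd, len(sec))
            bpm = np.clip(np.round(bpm), 25.0, 250.0)
            hr_t_segments.append(d0 + sec * np.timedelta64(1, "s"))
            hr_v_segments.append(bpm)

    steps = StepSeries(
        patient.patient_id, np.concatenate(all_minutes), np.concatenate(all_steps)
    )

    if not patient.hr_available:
        return (
            HRSeries.empty(patient.patient_id),
            steps,
            summaries,
            GapInfo(np.array([], dtype="datetime64[s]"), 0, 0),
        )

    if full_day:
        # one continuous segment across midnights: no structural gaps
        segments = [
            (np.concatenate(hr_t_segments), np.concatenate(hr_v_segments))
        ]
        n_boundary = 0
    else:
        segments = list(zip(hr_t_segments, hr_v_segments))
        n_boundary = len(segments) - 1

    out_t, out_v, gap_ts = [], [], []
    for t, v in segments:
        keep, gap_idx = _inject_gaps(len(t), cadence, config.hr_gap_rate, rng)
        gap_ts.append(t[gap_idx])
        out_t.append(t[keep])
        out_v.append(v[keep])
    injected = np.concatenate(gap_ts) if gap_ts else np.array([], dtype="datetime64[s]")
    hr = HRSeries(patient.patient_id, np.concatenate(out_t), np.concatenate(out_v))
    return hr, steps, summaries, GapInfo(injected, len(injected), n_boundary)


# ---------------------------------------------------------------------------
# Whole-cohort generation
# ---------------------------------------------------------------------------


def generate_cohort(config: SimConfig) -> tuple[CohortBundle, GroundTruth]:
    """Generate a full cohort plus its latent ground truth.

    Deterministic given ``config`` (including its seed): two calls with the
    same config produce identical bundles.
    """
    n = config.n_patients
    ss = np.random.SeedSequence(config.seed)
    children = ss.spawn(n + 1)
    crng = np.random.default_rng(children[0])

    sex = (crng.random(n) < config.p_male).astype(int)
    age = np.clip(crng.normal(config.age_mean, config.age_sd, n), 60.0, 95.0)
    height = np.where(
        sex == 1,
        crng.normal(config.height_mean_male, config.height_sd_male, n),
        crng.normal(config.height_mean_female, config.height_sd_female, n),
    )
    height = np.clip(height, 130.0, 210.0)
    bmi = np.clip(crng.normal(config.bmi_mean, config.bmi_sd, n), 17.0, 36.0)
    weight = bmi * (height / 100.0) ** 2

    # latent fitness: standardized sex and age carry part of the signal
    p = config.p_male
    sd_sex = np.sqrt(p * (1 - p)) if 0 < p < 1 else 1.0
    z_sex = (sex - p) / sd_sex
    z_age = (age - config.age_mean) / config.age_sd
    w_res = np.sqrt(
        1.0 - config.fitness_weight_sex**2 - config.fitness_weight_age**2
    )
    fitness = (
        config.fitness_weight_sex * z_sex
        + config.fitness_weight_age * z_age
        + w_res * crng.standard_normal(n)
    )

    six_mwd = np.maximum(50.0, config.sixmwd_mean + config.sixmwd_sd * fitness)
    rhr_patient = np.clip(
        config.rhr_base
        + config.fitness_loading_rhr * fitness
        + crng.normal(0.0, config.rhr_between_sd, n),
        40.0,
        130.0,
    )
    steps_patient = np.maximum(
        config.steps_floor,
        config.steps_base
        + config.fitness_loading_steps * fitness
        + crng.normal(0.0, config.steps_between_sd, n),
    )
    clinic_hr = np.clip(np.round(rhr_patient + crng.normal(0.0, 4.0, n)), 40.0, 150.0)

    wear_days = np.clip(
        np.round(crng.normal(config.wear_days_mean, config.wear_days_sd, n)),
        config.wear_days_min,
        config.wear_days_max,
    ).astype(int)

    if config.n_on_clip is not None or config.n_no_night is not None:
        n_clip = int(config.n_on_clip or 0)
        n_night = int(config.n_no_night or 0)
        if n_clip + n_night > n:
            raise ValueError("n_on_clip + n_no_night exceeds n_patients")
        perm = crng.permutation(n)
        on_clip = np.zeros(n, dtype=bool)
        no_night = np.zeros(n, dtype=bool)
        on_clip[perm[:n_clip]] = True
        no_night[perm[n_clip : n_clip + n_night]] = True
    else:
        on_clip = crng.random(n) < config.p_on_clip
        no_night = (~on_clip) & (crng.random(n) < config.p_no_night_wear)

    start = _date.fromisoformat(config.start_date)
    width = len(str(n))
    patients: list[PatientRecord] = []
    hr_map: dict[str, HRSeries] = {}
    steps_map: dict[str, StepSeries] = {}
    daily_map: dict[str, list[DailySummary]] = {}
    gt_rows = []
    gaps: dict[str, np.ndarray] = {}

    from .features import derive_pal  # late import: features builds on io only

    for i in range(n):
        pid = f"P{i + 1:0{width}d}"
        rec = PatientRecord(
            patient_id=pid,
            sex=int(sex[i]),
            age=float(np.round(age[i], 2)),
            height=float(np.round(height[i], 2)),
            weight=float(np.round(weight[i], 2)),
            six_mwd=float(np.round(six_mwd[i], 2)),
            clinic_hr=float(clinic_hr[i]),
            wore_at_night=bool(~no_night[i]),
            hr_available=bool(~on_clip[i]),
        )
        prng = np.random.default_rng(children[i + 1])
        rhr_known = rec.wore_at_night and rec.hr_available
        cadence = config.cadence_base * float(
            np.clip(
                1.0
                + config.cadence_per_fitness * fitness[i]
                + prng.normal(0.0, config.cadence_noise_sd),
                0.6,
                1.6,
            )
        )
        # day-to-day noise proportional for low-volume patients: the cohort
        # can perform a walk test, so fully step-free days do not occur
        day_sd = min(config.steps_day_sd, 0.3 * steps_patient[i])
        profile = []
        for d in range(int(wear_days[i])):
            total = max(0, int(np.round(prng.normal(steps_patient[i], day_sd))))
            rhr_day_latent = float(
                np.clip(rhr_patient[i] + prng.normal(0.0, config.rhr_day_sd), 40.0, 130.0)
            )
            profile.append(
                {
                    "date": start + timedelta(days=d),
                    "total_steps": total,
                    "resting_hr": float(np.round(rhr_day_latent)) if rhr_known else None,
                    "rhr_latent": rhr_day_latent,
                    "cadence": cadence,
                }
            )
        hr, st, summaries, gap_info = generate_intraday(rec, profile, config, prng)
        patients.append(rec)
        hr_map[pid] = hr
        steps_map[pid] = st
        daily_map[pid] = summaries
        gaps[pid] = gap_info.injected_starts
        pal = derive_pal(summaries, int(wear_days[i]))
        gt_rows.append(
            {
                "patient_id": pid,
                "fitness": float(fitness[i]),
                "true_pal_level": pal.level,
                "n_injected_gaps": gap_info.n_injected,
                "n_boundary_gaps": gap_info.n_boundary,
                "wear_days": int(wear_days[i]),
                "on_clip": bool(on_clip[i]),
                "no_night_wear": bool(no_night[i]),
            }
        )

    bundle = CohortBundle(
        patients=patients, hr=hr_map, steps=steps_map, daily=daily_map
    )
    truth = GroundTruth(table=pd.DataFrame(gt_rows), injected_gaps=gaps)
    return bundle, truth
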