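"""Canonical data model and file formats for wrist-tracker cohorts.

Every downstream stage (feature engineering, stratification, the CLI)
consumes the types defined here and nothing else.  Timestamps are naive
local time (single-site, week-long wear) serialized as ISO 8601; intraday
series are held as numpy arrays (``datetime64[s]`` + value vector) so that
multi-day 5-second heart-rate streams stay cheap to process.

Formats
-------
* clinical table  — CSV ``patient_id,sex,age,height_cm,weight_kg,six_mwd_m,
  clinic_hr_bpm,wore_at_night,hr_available``
* intraday HR     — CSV ``timestamp,bpm`` or a takeout-style JSON list of
  ``{"dateTime": ..., "value": {"bpm": ...}}``
* intraday steps  — CSV ``minute_start,steps`` or JSON list of
  ``{"dateTime": ..., "value": ...}``
* daily summary   — CSV ``patient_id,date,resting_hr,sedentary_min,
  lightly_active_min,fairly_active_min,very_active_min,total_steps``
  (empty resting_hr cell = missing, e.g. no night wear)
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from datetime import date as _date
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

BPM_MIN = 25.0
BPM_MAX = 250.0

CLINICAL_COLUMNS = [
    "patient_id",
    "sex",
    "age",
    "height_cm",
    "weight_kg",
    "six_mwd_m",
    "clinic_hr_bpm",
    "wore_at_night",
    "hr_available",
]

DAILY_COLUMNS = [
    "patient_id",
    "date",
    "resting_hr",
    "sedentary_min",
    "lightly_active_min",
    "fairly_active_min",
    "very_active_min",
    "total_steps",
]


class FormatError(ValueError):
    """A file does not conform to one of the documented dialects."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass
class PatientRecord:
    """Demographics, clinic vitals and the 6MWT outcome for one patient.

    ``sex`` is the binary indicator used by the fitness index (1 = male,
    0 = female); ``bmi`` is derived as weight / (height m)^2.
    ``hr_available`` is False for on-clip wear (PPG disabled: step data only).
    """

    patient_id: str
    sex: int
    age: float
    height: float  # cm
    weight: float  # kg
    six_mwd: float  # meters
    clinic_hr: float  # bpm, measured before the 6MWT
    wore_at_night: bool = True
    hr_available: bool = True
    bmi: float = field(init=False)

    def __post_init__(self) -> None:
        if self.sex not in (0, 1):
            raise ValueError(f"sex must be 0 or 1, got {self.sex!r}")
        for name in ("age", "height", "weight"):
            v = getattr(self, name)
            if not (math.isfinite(v) and v > 0):
                raise ValueError(f"{name} must be finite and > 0, got {v!r}")
        if not (math.isfinite(self.six_mwd) and self.six_mwd >= 0):
            raise ValueError(f"six_mwd must be >= 0, got {self.six_mwd!r}")
        if not (BPM_MIN <= self.clinic_hr <= BPM_MAX):
            raise ValueError(
                f"clinic_hr {self.clinic_hr!r} outside [{BPM_MIN}, {BPM_MAX}]"
            )
        self.bmi = self.weight / (self.height / 100.0) ** 2


def _as_datetime64(values) -> np.ndarray:
    arr = np.asarray(pd.to_datetime(list(values)).values).astype("datetime64[s]")
    return arr


@dataclass
class HRSeries:
    """Intraday heart-rate stream: strictly increasing timestamps, bpm values.

    May be empty (on-clip patient).  Nominal cadence is 5 s (1 s during
    tracked exercise); the reader accepts any cadence.
    """

    patient_id: str
    t: np.ndarray  # datetime64[s], strictly increasing
    bpm: np.ndarray  # float

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype="datetime64[s]")
        self.bpm = np.asarray(self.bpm, dtype=float)
        if self.t.shape != self.bpm.shape:
            raise ValueError("t and bpm must have equal length")
        if len(self.t) and not np.all(np.diff(self.t.astype("int64")) > 0):
            raise ValueError("HRSeries timestamps must be strictly increasing")
        if len(self.bpm) and (
            self.bpm.min() < BPM_MIN or self.bpm.max() > BPM_MAX
        ):
            raise ValueError("bpm outside physiological range [25, 250]")

    def __len__(self) -> int:
        return len(self.t)

    @classmethod
    def empty(cls, patient_id: str) -> "HRSeries":
        return cls(patient_id, np.array([], dtype="datetime64[s]"), np.array([]))

    @classmethod
    def from_pairs(cls, patient_id: str, pairs: Iterable[tuple]) -> "HRSeries":
        pairs = list(pairs)
        if not pairs:
            return cls.empty(patient_id)
        t, bpm = zip(*pairs)
        return cls(patient_id, _as_datetime64(t), np.asarray(bpm, dtype=float))


@dataclass
class StepSeries:
    """Minute-level step counts; each minute covers [minute_start, +60 s)."""

    patient_id: str
    minute_start: np.ndarray  # datetime64[s], minute aligned, increasing
    steps: np.ndarray  # non-negative int

    def __post_init__(self) -> None:
        self.minute_start = np.asarray(self.minute_start, dtype="datetime64[s]")
        self.steps = np.asarray(self.steps, dtype=np.int64)
        if self.minute_start.shape != self.steps.shape:
            raise ValueError("minute_start and steps must have equal length")
        secs = self.minute_start.astype("int64")
        if len(secs):
            if not np.all(np.diff(secs) > 0):
                raise ValueError("minute_starts must be strictly increasing")
            if np.any(secs % 60 != 0):
                raise ValueError("minute_starts must be aligned to whole minutes")
            if self.steps.min() < 0:
                raise ValueError("steps must be non-negative")

    def __len__(self) -> int:
        return len(self.minute_start)

    @classmethod
    def empty(cls, patient_id: str) -> "StepSeries":
        return cls(
            patient_id,
            np.array([], dtype="datetime64[s]"),
            np.array([], dtype=np.int64),
        )

    @classmethod
    def from_pairs(cls, patient_id: str, pairs: Iterable[tuple]) -> "StepSeries":
        pairs = list(pairs)
        if not pairs:
            return cls.empty(patient_id)
        t, s = zip(*pairs)
        return cls(patient_id, _as_datetime64(t), np.asarray(s, dtype=np.int64))


@dataclass
class DailySummary:
    """One device day: resting HR (may be missing) and activity totals."""

    patient_id: str
    date: _date
    resting_hr: float | None
    sedentary_min: float
    lightly_active_min: float
    fairly_active_min: float
    very_active_min: float
    total_steps: int

    def __post_init__(self) -> None:
        mins = (
            self.sedentary_min,
            self.lightly_active_min,
            self.fairly_active_min,
            self.very_active_min,
        )
        if any(m < 0 for m in mins):
            raise ValueError("activity minutes must be >= 0")
        if sum(mins) > 1440 + 1e-9:
            raise ValueError("activity minutes exceed one day (1440)")
        if self.resting_hr is not None and not (
            BPM_MIN <= self.resting_hr <= BPM_MAX
        ):
            raise ValueError(f"resting_hr {self.resting_hr!r} outside [25, 250]")
        if self.total_steps < 0:
            raise ValueError("total_steps must be >= 0")


@dataclass
class CohortBundle:
    """A whole cohort: clinical records plus per-patient wearable streams."""

    patients: list[PatientRecord]
    hr: dict[str, HRSeries]
    steps: dict[str, StepSeries]
    daily: dict[str, list[DailySummary]]

    def __post_init__(self) -> None:
        ids = {p.patient_id for p in self.patients}
        for name, mapping in (("hr", self.hr), ("steps", self.steps), ("daily", self.daily)):
            unknown = set(mapping) - ids
            if unknown:
                raise ValueError(f"{name} map contains unknown patient ids {sorted(unknown)}")

    def patient_ids(self) -> list[str]:
        return [p.patient_id for p in self.patients]


# ---------------------------------------------------------------------------
# Clinical table
# ---------------------------------------------------------------------------


def _parse_bool(v) -> bool:
    if isinstance(v, (bool, np.bool_)):
        return bool(v)
    s = str(v).strip().lower()
    if s in ("true", "1", "yes"):
        return True
    if s in ("false", "0", "no"):
        return False
    raise ValueError(f"cannot parse boolean {v!r}")


def read_clinical_table(path) -> list[PatientRecord]:
    """Read the clinical CSV into PatientRecords, computing BMI.

    Rows whose mandatory fields cannot be parsed are rejected with a
    row-indexed log message; remaining rows are retained.  A missing header
    column raises :class:`FormatError` naming the column.
    """
    df = pd.read_csv(path, dtype={"patient_id": str}, float_precision="round_trip")
    missing = [c for c in CLINICAL_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"clinical table missing column(s): {', '.join(missing)}")
    records: list[PatientRecord] = []
    for i, row in df.iterrows():
        try:
            records.append(
                PatientRecord(
                    patient_id=str(row["patient_id"]),
                    sex=int(row["sex"]),
                    age=float(row["age"]),
                    height=float(row["height_cm"]),
                    weight=float(row["weight_kg"]),
                    six_mwd=float(row["six_mwd_m"]),
                    clinic_hr=float(row["clinic_hr_bpm"]),
                    wore_at_night=_parse_bool(row["wore_at_night"]),
                    hr_available=_parse_bool(row["hr_available"]),
                )
            )
        except (ValueError, TypeError) as exc:
            logger.warning("clinical table row %d rejected: %s", i, exc)
    return records


def write_clinical_table(patients: Sequence[PatientRecord], path) -> None:
    df = pd.DataFrame(
        {
            "patient_id": [p.patient_id for p in patients],
            "sex": [p.sex for p in patients],
            "age": [p.age for p in patients],
            "height_cm": [p.height for p in patients],
            "weight_kg": [p.weight for p in patients],
            "six_mwd_m": [p.six_mwd for p in patients],
            "clinic_hr_bpm": [p.clinic_hr for p in patients],
            "wore_at_night": [p.wore_at_night for p in patients],
            "hr_available": [p.hr_available for p in patients],
        }
    )
    df.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Intraday streams
# ---------------------------------------------------------------------------


def _read_takeout_json(path, nested_key: str | None):
    with open(path) as fh:
        payload = json.load(fh)
    if not isinstance(payload, list):
        raise FormatError(f"{path}: expected a JSON list of records")
    ts, vals = [], []
    for rec in payload:
        ts.append(rec["dateTime"])
        v = rec["value"]
        vals.append(v[nested_key] if nested_key else v)
    return ts, vals


def _load_stream(path, time_col: str, value_col: str, nested_key: str | None):
    path = Path(path)
    if path.suffix.lower() == ".json":
        return _read_takeout_json(path, nested_key)
    df = pd.read_csv(path, float_precision="round_trip")
    for col in (time_col, value_col):
        if col not in df.columns:
            raise FormatError(f"{path}: missing column {col!r}")
    return list(df[time_col]), list(df[value_col])


def read_intraday(path_hr, path_steps, patient_id: str = "") -> tuple[HRSeries, StepSeries]:
    """Load one patient's intraday HR and step streams.

    Duplicate timestamps are collapsed keeping the last value (device
    re-sync overwrites); out-of-range bpm samples are dropped with a logged
    count; unordered files are sorted with a warning.  An empty HR file is
    valid (on-clip wear) and yields an empty series.
    """
    ts, bpm = _load_stream(path_hr, "timestamp", "bpm", "bpm")
    if not patient_id:
        patient_id = Path(path_hr).stem
    if ts:
        t = _as_datetime64(ts)
        v = np.asarray(bpm, dtype=float)
        order = np.argsort(t, kind="stable")
        if not np.array_equal(order, np.arange(len(t))):
            logger.warning("%s: HR records out of order; sorted", path_hr)
            t, v = t[order], v[order]
        # keep the LAST record for each duplicated timestamp
        keep = np.ones(len(t), dtype=bool)
        keep[:-1] = t[1:] != t[:-1]
        n_dup = int((~keep).sum())
        if n_dup:
            logger.warning("%s: collapsed %d duplicate timestamp(s)", path_hr, n_dup)
        t, v = t[keep], v[keep]
        in_range = (v >= BPM_MIN) & (v <= BPM_MAX)
        n_drop = int((~in_range).sum())
        if n_drop:
            logger.warning("%s: dropped %d out-of-range bpm sample(s)", path_hr, n_drop)
        hr = HRSeries(patient_id, t[in_range], v[in_range])
    else:
        hr = HRSeries.empty(patient_id)

    ts, sv = _load_stream(path_steps, "minute_start", "steps", None)
    if ts:
        t = _as_datetime64(ts)
        v = np.asarray(sv, dtype=np.int64)
        order = np.argsort(t, kind="stable")
        if not np.array_equal(order, np.arange(len(t))):
            logger.warning("%s: step records out of order; sorted", path_steps)
            t, v = t[order], v[order]
        keep = np.ones(len(t), dtype=bool)
        keep[:-1] = t[1:] != t[:-1]
        steps = StepSeries(patient_id, t[keep], v[keep])
    else:
        steps = StepSeries.empty(patient_id)
    return hr, steps


def _iso(arr: np.ndarray) -> list[str]:
    return np.datetime_as_string(arr, unit="s").tolist()


def write_intraday(hr: HRSeries, steps: StepSeries, path_hr, path_steps) -> None:
    pd.DataFrame({"timestamp": _iso(hr.t), "bpm": hr.bpm}).to_csv(path_hr, index=False)
    pd.DataFrame(
        {"minute_start": _iso(steps.minute_start), "steps": steps.steps}
    ).to_csv(path_steps, index=False)


# ---------------------------------------------------------------------------
# Daily summaries
# ---------------------------------------------------------------------------


def read_daily_summaries(path) -> dict[str, list[DailySummary]]:
    df = pd.read_csv(path, dtype={"patient_id": str}, float_precision="round_trip")
    missing = [c for c in DAILY_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"daily summary missing column(s): {', '.join(missing)}")
    out: dict[str, list[DailySummary]] = {}
    for _, row in df.iterrows():
        rhr = row["resting_hr"]
        out.setdefault(str(row["patient_id"]), []).append(
            DailySummary(
                patient_id=str(row["patient_id"]),
                date=pd.Timestamp(row["date"]).date(),
                resting_hr=None if pd.isna(rhr) else float(rhr),
                sedentary_min=float(row["sedentary_min"]),
                lightly_active_min=float(row["lightly_active_min"]),
                fairly_active_min=float(row["fairly_active_min"]),
                very_active_min=float(row["very_active_min"]),
                total_steps=int(row["total_steps"]),
            )
        )
    return out


def write_daily_summaries(daily: Mapping[str, Sequence[DailySummary]], path) -> None:
    rows = []
    for pid in daily:
        for d in daily[pid]:
            rows.append(
                {
                    "patient_id": pid,
                    "date": d.date.isoformat(),
                    "resting_hr": d.resting_hr,
                    "sedentary_min": d.sedentary_min,
                    "lightly_active_min": d.lightly_active_min,
                    "fairly_active_min": d.fairly_active_min,
                    "very_active_min": d.very_active_min,
                    "total_steps": d.total_steps,
                }
            )
    pd.DataFrame(rows, columns=DAILY_COLUMNS).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Whole-cohort directory layout
# ---------------------------------------------------------------------------


def write_cohort(bundle: CohortBundle, out_dir) -> None:
    """Write a cohort as clinical.csv, daily.csv and per-patient streams."""
    out = Path(out_dir)
    (out / "hr").mkdir(parents=True, exist_ok=True)
    (out / "steps").mkdir(parents=True, exist_ok=True)
    write_clinical_table(bundle.patients, out / "clinical.csv")
    write_daily_summaries(bundle.daily, out / "daily.csv")
    for pid in bundle.patient_ids():
        hr = bundle.hr.get(pid, HRSeries.empty(pid))
        st = bundle.steps.get(pid, StepSeries.empty(pid))
        write_intraday(hr, st, out / "hr" / f"{pid}.csv", out / "steps" / f"{pid}.csv")


def read_cohort(in_dir) -> CohortBundle:
    """Read a cohort directory written by :func:`write_cohort`.

    Patient order follows clinical.csv; per-patient series come back sorted.
    """
    src = Path(in_dir)
    patients = read_clinical_table(src / "clinical.csv")
    daily = read_daily_summaries(src / "daily.csv")
    hr: dict[str, HRSeries] = {}
    steps: dict[str, StepSeries] = {}
    for p in patients:
        hr_path = src / "hr" / f"{p.patient_id}.csv"
        st_path = src / "steps" / f"{p.patient_id}.csv"
        if hr_path.exists() and st_path.exists():
            hr[p.patient_id], steps[p.patient_id] = read_intraday(
                hr_path, st_path, p.patient_id
            )
    return CohortBundle(patients=patients, hr=hr, steps=steps, daily=daily)


# ---------------------------------------------------------------------------
# Feature table / analysis report (written by downstream modules)
# ---------------------------------------------------------------------------

FEATURE_COLUMNS = [
    "patient_id",
    "netf",
    "hros_q01",
    "mean_rhr",
    "rhr_source",
    "mean_daily_steps",
    "max_daily_steps",
    "above_10k_mean",
    "above_10k_max",
    "pal_sessions_per_week",
    "pal_level",
    "pal_coefficient",
    "wear_days",
]


def write_feature_table(features, path) -> None:
    """Write FeatureVector rows as CSV with a stable column order."""
    rows = []
    for f in features:
        rows.append(
            {
                "patient_id": f.patient_id,
                "netf": f.netf,
                "hros_q01": f.hros_q01,
                "mean_rhr": f.mean_rhr,
                "rhr_source": f.rhr_source,
                "mean_daily_steps": f.mean_daily_steps,
                "max_daily_steps": f.max_daily_steps,
                "above_10k_mean": f.above_10k_mean,
                "above_10k_max": f.above_10k_max,
                "pal_sessions_per_week": f.pal.sessions_per_week,
                "pal_level": f.pal.level,
                "pal_coefficient": f.pal.coefficient,
                "wear_days": f.wear_days,
            }
        )
    pd.DataFrame(rows, columns=FEATURE_COLUMNS).to_csv(path, index=False)


def read_feature_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"patient_id": str}, float_precision="round_trip")
    missing = [c for c in FEATURE_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"feature table missing column(s): {', '.join(missing)}")
    return df


def write_analysis_report(analysis, path) -> None:
    """Render a CohortAnalysis as a structured plain-text report."""
    with open(path, "w") as fh:
        fh.write(analysis.to_text())
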