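"""Feature engineering: HROS, quantiles, anomalies, PAL, NET-F, aggregates."""

import datetime
import warnings

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from wearfit import (
    HRSeries,
    StepSeries,
    aggregate_rhr,
    aggregate_steps,
    compute_hros,
    compute_netf,
    derive_pal,
    detect_hros_anomalies,
    gap_histogram,
    hros_quantile,
)
from wearfit.io_formats import DailySummary, PatientRecord


def day(pid="P1", rhr=70.0, fairly=0.0, very=0.0, total=5000, d=1):
    return DailySummary(
        patient_id=pid,
        date=datetime.date(2021, 6, d),
        resting_hr=rhr,
        sedentary_min=1000,
        lightly_active_min=100,
        fairly_active_min=fairly,
        very_active_min=very,
        total_steps=total,
    )


def hr_series(pairs, pid="P1"):
    return HRSeries.from_pairs(pid, pairs)


def step_series(pairs, pid="P1"):
    return StepSeries.from_pairs(pid, pairs)


class TestComputeHROS:
    def test_zero_step_identity(self):
        hr = hr_series([(f"2021-06-14T08:{m:02d}:00", 70.0) for m in range(5)])
        steps = step_series([(f"2021-06-14T08:{m:02d}:00", 0) for m in range(5)])
        out = compute_hros(hr, steps)
        assert np.allclose(out.hros, 70.0)

    def test_minute_constant_steps_divide_each_sample(self):
        hr = hr_series(
            [
                ("2021-06-14T08:00:05", 100.0),
                ("2021-06-14T08:00:25", 110.0),
                ("2021-06-14T08:00:45", 120.0),
            ]
        )
        steps = step_series([("2021-06-14T08:00:00", 59)])
        out = compute_hros(hr, steps)
        assert out.hros == pytest.approx([100 / 60, 110 / 60, 2.0])

    def test_value_below_one_when_cadence_exceeds_bpm(self):
        hr = hr_series([("2021-06-14T08:00:30", 100.0)])
        steps = step_series([("2021-06-14T08:00:00", 199)])
        out = compute_hros(hr, steps)
        assert out.hros[0] == pytest.approx(0.5)

    def test_uncovered_samples_excluded_and_counted(self):
        hr = hr_series(
            [("2021-06-14T08:00:30", 80.0), ("2021-06-14T09:00:00", 90.0)]
        )
        steps = step_series([("2021-06-14T08:00:00", 10)])
        out = compute_hros(hr, steps)
        assert len(out) == 1
        assert out.n_uncovered == 1

    def test_empty_hr_gives_missing_feature(self):
        out = compute_hros(HRSeries.empty("x"), step_series([("2021-06-14T08:00:00", 5)]))
        assert len(out) == 0
        assert hros_quantile(out) is None

    def test_matches_brute_force_on_random_series(self, rng):
        # brute-force per-sample loop as an independent oracle
        n_min = 240
        base = np.datetime64("2021-06-14T00:00:00")
        minute_idx = np.sort(rng.choice(1440, size=n_min, replace=False))
        minutes = base + minute_idx * np.timedelta64(60, "s")
        stepvals = rng.integers(0, 180, size=n_min)
        steps = StepSeries("P1", minutes, stepvals)
        t = base + np.sort(rng.choice(86400, size=10_000, replace=False)) * np.timedelta64(1, "s")
        bpm = rng.integers(40, 180, size=len(t)).astype(float)
        hr = HRSeries("P1", t, bpm)
        out = compute_hros(hr, steps)
        lookup = {int(m): int(s) for m, s in zip(minute_idx, stepvals)}
        expected = []
        for ts, b in zip(t, bpm):
            m = int((ts - base).astype("int64") // 60)
            if m in lookup:
                expected.append(b / (lookup[m] + 1))
        assert len(out) == len(expected)
        assert np.array_equal(out.hros, np.array(expected))


class TestHROSQuantile:
    def test_singleton(self):
        assert hros_quantile(np.array([5.0]), 0.01) == 5.0

    def test_interpolated_value_on_1_to_100(self):
        assert hros_quantile(np.arange(1.0, 101.0), 0.01) == pytest.approx(1.99)

    def test_q0_is_minimum(self):
        assert hros_quantile(np.array([3.0, 1.0, 5.0]), 0.0) == 1.0

    @settings(max_examples=100, derandomize=True, deadline=None)
    @given(
        values=st.lists(
            st.floats(min_value=0.01, max_value=100, allow_nan=False), min_size=1, max_size=1000
        ),
        q=st.floats(min_value=0.0, max_value=1.0),
    )
    def test_agrees_with_sort_and_interpolate_oracle(self, values, q):
        v = np.asarray(values)
        got = hros_quantile(v, q)
        s = np.sort(v)
        pos = (len(s) - 1) * q
        lo, hi = int(np.floor(pos)), int(np.ceil(pos))
        expected = s[lo] + (pos - lo) * (s[hi] - s[lo])
        assert got == pytest.approx(expected, abs=1e-12)


class TestAnomalyDetection:
    def test_constructed_outlier_is_flagged(self, rng):
        values = np.concatenate([rng.normal(1.0, 0.05, 100), [1.0 + 10 * 0.05 * 20]])
        flags = detect_hros_anomalies(values, contamination=0.1)
        assert flags[-1]

    def test_flagged_fraction_tracks_contamination(self, rng):
        values = rng.normal(0, 1, 500)
        flags = detect_hros_anomalies(values, contamination=0.1)
        assert 0.08 <= flags.mean() <= 0.12

    def test_too_few_samples_warns_no_flags(self):
        with pytest.warns(UserWarning, match="19 < 20"):
            flags = detect_hros_anomalies(np.arange(19.0))
        assert not flags.any()

    def test_constant_series_degenerate_no_flags(self):
        with pytest.warns(UserWarning, match="degenerate"):
            flags = detect_hros_anomalies(np.full(50, 2.5))
        assert not flags.any()

    def test_subsampled_fit_still_thresholds_all_samples(self, rng):
        values = rng.normal(0, 1, 20_000)
        flags = detect_hros_anomalies(values, contamination=0.1, max_fit_samples=2000)
        assert len(flags) == 20_000
        assert 0.08 <= flags.mean() <= 0.12


class TestDerivePAL:
    def test_no_activity_is_level_1(self):
        pal = derive_pal([day(fairly=0, very=0)] * 7, 7)
        assert (pal.sessions_per_week, pal.level, pal.coefficient) == (0.0, 1, 0.0)

    def test_weekly_session_arithmetic(self):
        # 140 fairly + 35 very over 7 days: 140/30 + 35/15 = 7 sessions/week
        daily = [day(fairly=20, very=5)] * 7
        pal = derive_pal(daily, 7)
        assert pal.sessions_per_week == pytest.approx(7.0)
        assert pal.level == 5 and pal.coefficient == 1.21

    def test_normalized_by_wear_days(self):
        # 3 wear days, 45 fairly total -> (7/3) * 1.5 = 3.5 sessions/week
        daily = [day(fairly=15)] * 3
        pal = derive_pal(daily, 3)
        assert pal.sessions_per_week == pytest.approx(3.5)
        assert pal.level == 4

    @pytest.mark.parametrize(
        "sessions,level,coeff",
        [
            (0.0, 1, 0.0),
            (1.4999, 2, 0.35),
            (1.5, 3, 0.29),
            (2.9999, 3, 0.29),
            (3.0, 4, 0.64),
            (6.0, 4, 0.64),
            (6.0001, 5, 1.21),
            (10.0, 5, 1.21),
        ],
    )
    def test_band_boundaries_exact(self, sessions, level, coeff):
        # one wear-week with fairly-active minutes chosen to hit the target
        daily = [day(fairly=sessions * 30, very=0)]
        pal = derive_pal(daily, 7)
        assert pal.sessions_per_week == pytest.approx(sessions, abs=1e-12)
        assert pal.level == level
        assert pal.coefficient == coeff

    def test_wear_days_must_be_positive(self):
        with pytest.raises(ValueError):
            derive_pal([day()], 0)


class TestNETF:
    def test_intercept(self):
        # degenerate all-zero inputs isolate the constant term
        assert compute_netf(0, 0.0, 0.0, 0.0, 0.0) == pytest.approx(21.41)

    def test_cohort_mean_worked_examples(self):
        male = compute_netf(1, 76.45, 24.87, 71.09, 0.29)
        female = compute_netf(0, 75.11, 24.73, 77.78, 1.21)
        assert male == pytest.approx(8.3781, abs=1e-10)
        assert female == pytest.approx(6.2648, abs=1e-10)

    def test_rejects_off_table_pal_coefficient(self):
        with pytest.raises(ValueError):
            compute_netf(1, 70, 25, 70, 0.5)

    @settings(max_examples=200, derandomize=True, deadline=None)
    @given(
        sex=st.integers(0, 1),
        age=st.floats(40, 100),
        bmi=st.floats(15, 45),
        rhr=st.floats(40, 120),
        pal=st.sampled_from([0.0, 0.35, 0.29, 0.64, 1.21]),
    )
    def test_monotonicity_and_sex_offset(self, sex, age, bmi, rhr, pal):
        base = compute_netf(sex, age, bmi, rhr, pal)
        assert compute_netf(sex, age + 1, bmi, rhr, pal) < base
        assert compute_netf(sex, age, bmi + 1, rhr, pal) < base
        assert compute_netf(sex, age, bmi, rhr + 1, pal) < base
        assert compute_netf(1, age, bmi, rhr, pal) - compute_netf(
            0, age, bmi, rhr, pal
        ) == pytest.approx(2.87)


class TestRHRAggregation:
    def _patient(self, clinic_hr=68.0):
        return PatientRecord("P1", 1, 76, 170, 70, 300, clinic_hr)

    def test_mean_of_device_days(self):
        daily = [day(rhr=70), day(rhr=72, d=2), day(rhr=74, d=3)]
        assert aggregate_rhr(daily, self._patient()) == (72.0, "device")

    def test_clinic_fallback_when_all_missing(self):
        daily = [day(rhr=None), day(rhr=None, d=2)]
        assert aggregate_rhr(daily, self._patient(68.0)) == (68.0, "clinic_fallback")

    def test_singleton_day(self):
        assert aggregate_rhr([day(rhr=65)], self._patient())[0] == 65.0


class TestStepAggregation:
    def test_mean_max_and_threshold_flags(self):
        daily = [day(total=5000), day(total=12000, d=2), day(total=7000, d=3)]
        mean_s, max_s, above_mean, above_max = aggregate_steps(daily)
        assert (mean_s, max_s) == (8000.0, 12000)
        assert (above_mean, above_max) == (False, True)

    def test_exactly_10000_counts_as_not_below(self):
        _, _, above_mean, above_max = aggregate_steps([day(total=10000)])
        assert above_mean and above_max

    def test_all_zero(self):
        mean_s, max_s, above_mean, above_max = aggregate_steps(
            [day(total=0), day(total=0, d=2)]
        )
        assert (mean_s, max_s, above_mean, above_max) == (0.0, 0, False, False)

    def test_empty_errors(self):
        with pytest.raises(ValueError):
            aggregate_steps([])


class TestGapHistogram:
    def test_counts_gaps_over_15s(self):
        hr = hr_series(
            [
                ("2021-06-14T00:00:00", 70),
                ("2021-06-14T00:00:05", 70),
                ("2021-06-14T00:00:10", 70),
                ("2021-06-14T00:00:30", 70),
            ]
        )
        out = gap_histogram(hr)
        assert sorted(out.deltas_s) == [5, 5, 20]
        assert out.n_gaps == 1

    def test_uniform_cadence_has_no_gaps(self):
        hr = hr_series([(f"2021-06-14T00:00:{5*i:02d}", 70) for i in range(10)])
        assert gap_histogram(hr).n_gaps == 0

    def test_single_sample_empty_histogram(self):
        hr = hr_series([("2021-06-14T00:00:00", 70)])
        out = gap_histogram(hr)
        assert len(out.deltas_s) == 0 and out.n_gaps == 0
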