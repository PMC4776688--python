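import numpy as np
import pytest

from actihr.preprocessing import (
    GateDecision,
    InputError,
    ParameterError,
    RecordRejected,
    RegularSeries,
    SampleSeries,
    SubjectRecord,
    downsample_linear,
    filter_hr_floor,
    flag_long_gaps,
    per_day_missing,
    preprocess_subject,
    quality_gate,
    resample_zoh,
    select_best_days,
)

from conftest import regular


class TestGapFlagging:
    def test_hr_gap_over_15_min_flagged(self):
        s = flag_long_gaps(SampleSeries("hr", [0.0, 20.0], [70.0, 75.0]))
        assert s.gap_after.tolist() == [True]

    def test_exact_nominal_spacing_unflagged(self):
        t = np.arange(0, 100, 10.0)
        s = flag_long_gaps(SampleSeries("hr", t, np.full(len(t), 70.0)))
        assert not s.gap_after.any()

    def test_activity_7_min_spacing_below_threshold(self):
        s = flag_long_gaps(SampleSeries("activity", [0.0, 7.0, 14.0], [0.1, 0.2, 0.3]))
        assert not s.gap_after.any()

    def test_unsorted_timestamps_rejected(self):
        with pytest.raises(InputError):
            SampleSeries("hr", [10.0, 0.0], [70.0, 75.0])


class TestHRFloor:
    def test_low_values_removed_and_counted(self):
        s = filter_hr_floor(SampleSeries("hr", [0.0, 10.0, 20.0], [72.0, 19.0, 80.0]))
        assert s.v.tolist() == [72.0, 80.0]
        assert s.n_artifacts == 1
        assert s.artifact_fraction == pytest.approx(1 / 3)

    def test_all_valid_unchanged(self):
        s = filter_hr_floor(SampleSeries("hr", [0.0, 10.0], [60.0, 61.0]))
        assert s.v.tolist() == [60.0, 61.0] and s.n_artifacts == 0

    def test_exactly_20_bpm_retained(self):
        s = filter_hr_floor(SampleSeries("hr", [0.0, 10.0], [20.0, 60.0]))
        assert 20.0 in s.v

    def test_rejects_activity_series(self):
        with pytest.raises(InputError):
            filter_hr_floor(SampleSeries("activity", [0.0], [0.5]))


class TestZeroOrderHold:
    def test_hold_semantics_hand_trace(self):
        s = flag_long_gaps(SampleSeries("hr", [0.0, 12.0], [70.0, 80.0]))
        rs = resample_zoh(s, 10.0)
        assert rs.times.tolist() == [0.0, 10.0, 20.0]
        assert rs.values.tolist() == [70.0, 70.0, 80.0]

    def test_on_grid_observations_identity(self):
        t = np.arange(0, 60, 10.0)
        v = np.arange(6, dtype=float)
        rs = resample_zoh(flag_long_gaps(SampleSeries("hr", t, v)), 10.0)
        np.testing.assert_array_equal(rs.values, v)

    def test_no_hold_across_flagged_gap(self):
        s = flag_long_gaps(SampleSeries("hr", [0.0, 40.0], [70.0, 80.0]))
        rs = resample_zoh(s, 10.0)
        # slots strictly inside the (0, 40] gap are missing
        assert np.isnan(rs.values[1:4]).all()
        assert rs.values[0] == 70.0 and rs.values[4] == 80.0

    def test_empty_series_error(self):
        with pytest.raises(InputError):
            resample_zoh(SampleSeries("hr", [], []), 10.0)

    def test_never_fabricates_beyond_hold(self):
        rng = np.random.default_rng(5)
        t = np.sort(rng.uniform(0, 1440, 60))
        t = t[np.r_[True, np.diff(t) > 0.5]]
        s = flag_long_gaps(SampleSeries("hr", t, rng.uniform(60, 90, len(t))))
        rs = resample_zoh(s, 10.0)
        for slot, val in zip(rs.times, rs.values):
            if np.isnan(val):
                continue
            prev = t[t <= slot]
            assert len(prev) and slot - prev[-1] <= 15.0


class TestLinearDownsample:
    def test_pairing_hand_trace(self):
        rs = regular([2, 4, 6, 8, 10], interval=5.0, kind="activity")
        out = downsample_linear(rs, 10.0)
        assert out.values.tolist() == [3.0, 7.0]

    def test_constant_preserved(self):
        out = downsample_linear(regular([1.0] * 6, interval=5.0), 10.0)
        assert out.values.tolist() == [1.0, 1.0, 1.0]

    def test_missing_propagates(self):
        out = downsample_linear(regular([2, np.nan, 6, 8], interval=5.0), 10.0)
        assert np.isnan(out.values[0]) and out.values[1] == 7.0

    def test_non_divisible_interval_error(self):
        with pytest.raises(ParameterError):
            downsample_linear(regular([1, 2, 3], interval=7.0), 10.0)


def _days_series(fractions, interval=10.0):
    """Regular series spanning len(fractions) days with given missing fractions."""
    spd = int(1440 / interval)
    rng = np.random.default_rng(0)
    blocks = []
    for f in fractions:
        block = np.full(spd, 70.0)
        n_miss = int(round(f * spd))
        block[rng.choice(spd, n_miss, replace=False)] = np.nan
        blocks.append(block)
    return regular(np.concatenate(blocks), interval=interval)


class TestDaySelection:
    def test_lowest_missing_days_selected(self):
        fr = [0, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0.2, 0.3, 0.4, 0.5]
        out, report = select_best_days(_days_series(fr))
        assert out.retained_days == list(range(10))
        assert len(report) == 14

    def test_fewer_than_ten_days_rejected(self):
        with pytest.raises(RecordRejected):
            select_best_days(_days_series([0.0] * 9))

    def test_tie_broken_by_earlier_day(self):
        # days 10 and 12 tie at 0.05 for the last slot; earlier one wins
        fr = [0.0] * 9 + [0.3, 0.05, 0.4, 0.05]
        out, _ = select_best_days(_days_series(fr))
        assert 10 in out.retained_days and 12 not in out.retained_days

    def test_reported_fractions_match_injected(self):
        fr = [0.0, 0.1, 0.2] + [0.0] * 11
        _, report = select_best_days(_days_series(fr))
        spd = 144
        for d, f in enumerate(fr):
            assert report[d] == pytest.approx(round(f * spd) / spd, abs=1e-9)


def _processed_record(hr_missing=0.0, act_missing=0.0, artifacts=0, n_raw=1000):
    spd = 144
    hr_vals = np.full(10 * spd, 70.0)
    hr_vals[: int(hr_missing * 10 * spd)] = np.nan
    act_vals = np.full(10 * 288, 0.1)
    act_vals[: int(act_missing * 10 * 288)] = np.nan
    rec = SubjectRecord(
        "s1", 0,
        hr_raw=SampleSeries("hr", [0.0], [70.0], n_artifacts=artifacts, n_raw=n_raw),
        act_raw=SampleSeries("activity", [0.0], [0.1]),
    )
    rec.hr = regular(hr_vals)
    rec.activity = regular(act_vals, interval=5.0, kind="activity")
    return rec


class TestQualityGate:
    def test_clean_record_accepted(self):
        assert quality_gate(_processed_record()).accepted

    def test_artifacts_over_ten_percent_rejected(self):
        d = quality_gate(_processed_record(artifacts=150, n_raw=1000))
        assert not d.accepted and "artifact" in d.reasons[0]

    def test_exactly_ten_percent_accepted(self):
        assert quality_gate(_processed_record(artifacts=100, n_raw=1000)).accepted

    def test_missing_over_threshold_rejected(self):
        assert not quality_gate(_processed_record(act_missing=0.15)).accepted


class TestFullChain:
    def test_idempotent_on_clean_regular_record(self, profiles, clean_acq):
        from actihr.synthetic import generate_subject

        rec = generate_subject(profiles["control"], clean_acq, seed=11)
        rec, decision = preprocess_subject(rec)
        assert decision.accepted
        # re-preprocessing the regular output reproduces it exactly
        hr2 = resample_zoh(
            flag_long_gaps(SampleSeries("hr", rec.hr.times, rec.hr.values)), 10.0,
            align_days=True,
        )
        np.testing.assert_array_equal(hr2.values[: len(rec.hr.values)], rec.hr.values)

    def test_detected_corruption_matches_injected(self, profiles):
        from actihr.synthetic import AcquisitionModel, generate_subject

        acq = AcquisitionModel(dropout_rate=0.0, artifact_rate=0.08, record_days=14)
        rec = generate_subject(profiles["control"], acq, seed=3)
        injected = rec.quality["injected_hr_artifact_fraction"]
        rec, decision = preprocess_subject(rec)
        assert decision.hr_artifact_fraction == pytest.approx(injected, abs=0.002)

    def test_injected_gaps_flagged_downstream(self, profiles):
        from actihr.synthetic import AcquisitionModel, generate_subject

        acq = AcquisitionModel(dropout_rate=0.05, artifact_rate=0.0, record_days=14)
        rec = generate_subject(profiles["control"], acq, seed=9)
        flagged = flag_long_gaps(rec.hr_raw)
        starts = flagged.t[:-1][flagged.gap_after]
        for lo, hi in rec.quality["injected_hr_gaps"]:
            if hi - lo > 15.0:  # every injected long gap must be flagged
                assert np.any(np.isclose(starts, lo, atol=1e-6)), (lo, hi)
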