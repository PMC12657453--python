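import numpy as np
import pytest

from kneegait import pipeline as pl
from kneegait.events import (
    GaitCycleRecord,
    GaitEventTable,
    QCCriteria,
    detect_heel_strikes,
    detect_toe_offs,
    qc_cycles,
    segment_cycles,
    stance_intervals,
)
from kneegait.io_formats import JointAngleSeries
from kneegait.preprocess import NormalizedCurve

from conftest import match_errors_frames

FS = 60.0


class TestDetectors:
    def test_constant_trajectories_give_no_events(self):
        flat = np.zeros(300)
        with pytest.warns(UserWarning, match="flat"):
            assert len(detect_heel_strikes(flat, FS)) == 0
        with pytest.warns(UserWarning, match="flat"):
            assert len(detect_toe_offs(flat, FS)) == 0

    def test_refractory_interval_keeps_the_deeper_minimum(self):
        # two dips 0.2 s apart: with a 0.5 s refractory interval only the
        # deeper one may survive
        t = np.arange(0, 2.0, 1 / FS)
        z = 0.1 * np.ones_like(t)
        z -= 0.08 * np.exp(-0.5 * ((t - 0.9) / 0.03) ** 2)  # deeper
        z -= 0.05 * np.exp(-0.5 * ((t - 1.1) / 0.03) ** 2)
        times = detect_heel_strikes(z, FS, min_interval=0.5)
        assert len(times) == 1
        assert abs(times[0] - 0.9) < 1.5 / FS

    def test_monotone_ramp_yields_at_most_one_toe_off(self):
        z = np.linspace(0.0, 0.3, 300)
        assert len(detect_toe_offs(z, FS)) <= 1

    def test_offset_invariance(self, one_trial):
        _, mk, _, _ = one_trial
        z = mk.marker("L_heel")[:, 1] / 1000.0
        a = detect_heel_strikes(z, FS)
        b = detect_heel_strikes(z + 5.0, FS)
        np.testing.assert_allclose(a, b)

    def test_zero_noise_trials_match_truth_within_one_frame(self, small_koa_cohort):
        cohort = small_koa_cohort
        for d in cohort.participants:
            for mk, ang, truth in cohort.trials[d.pid]:
                res = pl.run_trial(mk, ang, pl.RunConfig())
                for foot in "LR":
                    for det, tru in (
                        (res.events.heel_strikes[foot], truth.heel_strikes[foot]),
                        (res.events.toe_offs[foot], truth.toe_offs[foot]),
                    ):
                        errs = match_errors_frames(det, tru, FS)
                        assert np.all(errs <= 1.0)


class TestStanceIntervals:
    def test_basic_pairing(self):
        table = GaitEventTable(
            heel_strikes={"L": np.array([0.0, 1.0])}, toe_offs={"L": np.array([0.62, 1.62])}
        )
        assert stance_intervals(table, "L") == [(0.0, 0.62), (1.0, 1.62)]

    def test_leading_toe_off_dropped(self):
        table = GaitEventTable(
            heel_strikes={"L": np.array([1.0])}, toe_offs={"L": np.array([0.5, 1.62])}
        )
        assert stance_intervals(table, "L") == [(1.0, 1.62)]

    def test_empty_table(self):
        assert stance_intervals(GaitEventTable(), "L") == []


def _angles_series(duration=3.0):
    t = np.arange(0.0, duration, 1 / FS)
    return JointAngleSeries(
        FS, t, ["knee_angle_l"], (30.0 + 20.0 * np.sin(2 * np.pi * t))[:, None]
    )


class TestSegmentCycles:
    def test_durations_from_consecutive_heel_strikes(self):
        table = GaitEventTable(heel_strikes={"L": np.array([0.0, 1.0, 2.1])})
        recs = segment_cycles(table, _angles_series(), "L")
        assert [round(r.duration, 3) for r in recs] == [1.0, 1.1]

    def test_single_heel_strike_gives_no_cycles(self):
        table = GaitEventTable(heel_strikes={"L": np.array([1.0])})
        assert segment_cycles(table, _angles_series(), "L") == []

    def test_cycle_count_equals_strikes_minus_one(self, one_trial_result):
        res = one_trial_result
        for foot in "LR":
            n_hs = len(res.events.heel_strikes[foot])
            n_rejected = (
                int((res.rejected["foot"] == foot).sum()) if len(res.rejected) else 0
            )
            assert len(res.records[foot]) + n_rejected == n_hs - 1

    def test_normalized_knee_peak_matches_generator_truth(self, one_trial, one_trial_result):
        _, _, _, truth = one_trial
        res = one_trial_result
        for foot in "LR":
            truth_map = {round(s, 2): peak for s, e, peak in truth.knee_peaks[foot]}
            for rec in res.records[foot]:
                key = round(rec.start, 2)
                matches = [p for s, p in truth_map.items() if abs(s - key) < 0.05]
                if matches:
                    measured = rec.normalized_curves[f"knee_angle_{foot.lower()}"].values.max()
                    assert abs(measured - matches[0]) < 0.5

    def test_contralateral_events_mapped_to_cycle_percent(self, one_trial_result):
        rec = one_trial_result.records["L"][1]
        ev = rec.events_in_cycle
        assert 40.0 < ev["contra_heel_strike_pct"] < 60.0
        assert 50.0 < ev["ipsi_toe_off_pct"] < 90.0


def _record(duration=1.0, knee_max=50.0, gap=0):
    vals = np.full(101, 10.0)
    vals[50] = knee_max
    return GaitCycleRecord(
        foot="L",
        start=0.0,
        end=duration,
        normalized_curves={"knee_angle_l": NormalizedCurve(vals)},
        max_marker_gap_frames=gap,
    )


class TestQC:
    def test_abnormal_timing(self):
        accepted, rejected = qc_cycles([_record(duration=5.0)], QCCriteria())
        assert accepted == [] and rejected[0][1] == "abnormal_timing"

    def test_implausible_amplitude(self):
        accepted, rejected = qc_cycles([_record(knee_max=170.0)], QCCriteria())
        assert rejected[0][1] == "implausible_trajectory"

    def test_marker_discontinuity(self):
        accepted, rejected = qc_cycles([_record(gap=25)], QCCriteria(max_gap_frames=10))
        assert rejected[0][1] == "marker_discontinuity"

    def test_clean_synthetic_cohort_fully_accepted(self, small_koa_cohort, small_control_cohort):
        for cohort in (small_koa_cohort, small_control_cohort):
            for d in cohort.participants:
                for mk, ang, _ in cohort.trials[d.pid]:
                    res = pl.run_trial(mk, ang, pl.RunConfig())
                    assert len(res.rejected) == 0
                    assert len(res.cycles) > 0
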