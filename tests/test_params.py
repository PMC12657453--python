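import numpy as np
import pandas as pd
import pytest

from kneegait import pipeline as pl
from kneegait.events import GaitCycleRecord, GaitEventTable
from kneegait.io_formats import MarkerTrajectorySet
from kneegait.params import (
    WalkingFrame,
    cadence,
    double_support_pct,
    gait_speed,
    participant_summary,
    peak_angles,
    step_length_asymmetry,
    step_width,
    stride_length,
    walking_direction,
)
from kneegait.preprocess import NormalizedCurve

FS = 60.0
XFRAME = WalkingFrame(forward=np.array([1.0, 0.0, 0.0]), lateral=np.array([0.0, 0.0, 1.0]))


def _markers(pelvis_xyz, heels=None):
    """Marker set from per-frame pelvis (and optional heel) coordinates, metres."""
    t = np.arange(len(pelvis_xyz)) / FS
    names = ["pelvis"]
    stacks = [np.asarray(pelvis_xyz, dtype=float)]
    if heels is not None:
        for name, arr in heels.items():
            names.append(name)
            stacks.append(np.asarray(arr, dtype=float))
    return MarkerTrajectorySet(FS, "m", names, t, np.stack(stacks, axis=1))


def _cycle(foot="L", start=0.0, end=1.0, curves=None):
    return GaitCycleRecord(foot=foot, start=start, end=end, normalized_curves=curves or {})


class TestWalkingDirection:
    def test_pure_x_walk(self):
        n = 120
        pelvis = np.column_stack([np.linspace(0, 2, n), np.full(n, 0.9), np.zeros(n)])
        frame = walking_direction(_markers(pelvis))
        np.testing.assert_allclose(frame.forward, [1.0, 0.0, 0.0], atol=1e-6)

    def test_diagonal_walk_recovers_heading(self):
        n = 120
        d = np.linspace(0, 2, n) / np.sqrt(2)
        pelvis = np.column_stack([d, np.full(n, 0.9), d])
        frame = walking_direction(_markers(pelvis))
        np.testing.assert_allclose(np.abs(frame.forward), [1 / np.sqrt(2), 0, 1 / np.sqrt(2)],
                                   atol=1e-6)
        assert frame.forward[0] > 0 and frame.forward[2] > 0  # oriented along travel

    def test_short_trial_rejected(self):
        n = 60
        pelvis = np.column_stack([np.linspace(0, 0.2, n), np.full(n, 0.9), np.zeros(n)])
        with pytest.raises(ValueError, match="too short"):
            walking_direction(_markers(pelvis))


class TestSpatiotemporal:
    def test_gait_speed_from_pelvis_displacement(self):
        n = 61
        pelvis = np.column_stack([np.linspace(0, 1.2, n), np.full(n, 0.9), np.zeros(n)])
        speed = gait_speed(_markers(pelvis), _cycle(end=1.0), XFRAME)
        assert speed == pytest.approx(1.2, abs=1e-9)

    def test_stationary_pelvis_zero_speed(self):
        pelvis = np.tile([0.5, 0.9, 0.0], (61, 1))
        assert gait_speed(_markers(pelvis), _cycle(end=1.0), XFRAME) == pytest.approx(0.0)

    def test_stride_length_between_ipsilateral_strikes(self):
        n = 61
        heel = np.column_stack([np.linspace(0, 1.32, n), np.zeros(n), np.zeros(n)])
        ms = _markers(np.zeros((n, 3)), heels={"L_heel": heel})
        assert stride_length(ms, _cycle(end=1.0), XFRAME) == pytest.approx(1.32, abs=1e-9)

    def test_step_width_lateral_separation(self):
        n = 61
        left = np.column_stack([np.zeros(n), np.zeros(n), np.full(n, 0.05)])
        right = np.column_stack([np.zeros(n), np.zeros(n), np.full(n, -0.05)])
        ms = _markers(np.zeros((n, 3)), heels={"L_heel": left, "R_heel": right})
        assert step_width(ms, XFRAME, 0.2, 0.7) == pytest.approx(0.10, abs=1e-9)
        # both heels on the midline -> zero width
        ms0 = _markers(np.zeros((n, 3)), heels={"L_heel": right * 0, "R_heel": right * 0})
        assert step_width(ms0, XFRAME, 0.2, 0.7) == 0.0

    @pytest.mark.parametrize(
        "duration,expected", [(1.0, 120.0), (2.0, 60.0), (1.2207, 98.3)]
    )
    def test_cadence_two_steps_per_cycle(self, duration, expected):
        assert cadence(_cycle(end=duration)) == pytest.approx(expected, abs=0.05)


class TestDoubleSupport:
    def test_interval_overlap_oracle_value(self):
        # 62 % stance per foot, contralateral offset 50 %: overlaps at
        # [50, 62] % and [0, 12] % -> 24 %
        table = GaitEventTable(
            heel_strikes={"L": np.array([0.0, 1.0, 2.0]), "R": np.array([0.5, 1.5])},
            toe_offs={"L": np.array([0.62, 1.62]), "R": np.array([0.12, 1.12, 2.12])},
        )
        ds = double_support_pct(table, _cycle("L", 0.0, 1.0))
        assert ds == pytest.approx(24.0, abs=1e-6)

    def test_running_pattern_zero_overlap(self):
        table = GaitEventTable(
            heel_strikes={"L": np.array([0.0, 1.0]), "R": np.array([0.5])},
            toe_offs={"L": np.array([0.3, 1.3]), "R": np.array([0.8])},
        )
        assert double_support_pct(table, _cycle("L", 0.0, 1.0)) == 0.0

    def test_full_cycle_bilateral_stance(self):
        table = GaitEventTable(
            heel_strikes={"L": np.array([0.0, 1.0]), "R": np.array([0.5])},
            toe_offs={"L": np.array([0.99, 1.99]), "R": np.array([1.49])},
        )
        # left stance covers ~the whole cycle; right stance enters at 50 % and
        # its previous stance (open-ended, evidenced by a leading toe-off)
        table.toe_offs["R"] = np.array([0.49, 1.49])
        ds = double_support_pct(table, _cycle("L", 0.0, 1.0))
        assert ds == pytest.approx(98.0, abs=1.0)

    def test_missing_contralateral_events_give_nan(self):
        table = GaitEventTable(heel_strikes={"L": np.array([0.0, 1.0])}, toe_offs={})
        assert np.isnan(double_support_pct(table, _cycle("L", 0.0, 1.0)))


class TestAsymmetry:
    def test_symmetric_steps(self):
        assert step_length_asymmetry([0.5], [0.5]) == 0.0

    def test_stated_formula(self):
        assert step_length_asymmetry([0.55], [0.45]) == pytest.approx(20.0, abs=1e-9)

    def test_swap_invariance(self):
        a = step_length_asymmetry([0.61, 0.59], [0.45, 0.44])
        b = step_length_asymmetry([0.45, 0.44], [0.61, 0.59])
        assert a == b

    def test_zero_means_undefined(self):
        with pytest.raises(ValueError):
            step_length_asymmetry([0.0], [0.0])


class TestPeakAngles:
    def test_signed_extrema(self):
        vals = np.linspace(-3.0, 50.6, 101)
        rec = _cycle(curves={"knee_angle_l": NormalizedCurve(vals)})
        peaks = peak_angles(rec)
        assert peaks["knee_flexion"] == pytest.approx(50.6)
        assert peaks["knee_extension"] == pytest.approx(-3.0)

    def test_constant_curve_degenerate_peaks(self):
        rec = _cycle(curves={"knee_angle_l": NormalizedCurve(np.full(101, 5.0))})
        peaks = peak_angles(rec)
        assert peaks["knee_flexion"] == 5.0 and peaks["knee_extension"] == 5.0


class TestParticipantSummary:
    def test_single_cycle_summary_is_that_cycle(self):
        df = pd.DataFrame({"participant": ["p1"], "stride_length_m": [1.23]})
        out = participant_summary(df, value_cols=["stride_length_m"])
        assert out.loc[0, "stride_length_m"] == pytest.approx(1.23)
        assert out.loc[0, "n_cycles"] == 1

    def test_pooled_three_sd_rule_excludes_artefact(self):
        rng = np.random.default_rng(5)
        strides = np.concatenate([rng.normal(1.0, 0.05, 20), [5.0]])
        df = pd.DataFrame({"participant": ["p1"] * 21, "stride_length_m": strides})
        out = participant_summary(df, value_cols=["stride_length_m"])
        mu, sd = strides.mean(), strides.std(ddof=1)
        kept = strides[np.abs(strides - mu) <= 3 * sd]
        assert 5.0 not in kept
        assert out.loc[0, "stride_length_m"] == pytest.approx(kept.mean())


class TestGeometryInvariance:
    def test_parameters_invariant_under_lab_rotation_and_translation(self, one_trial):
        d, mk, ang, _ = one_trial
        res0 = pl.run_trial(mk, ang, pl.RunConfig())

        rot = mk.copy()
        theta = np.deg2rad(35.0)
        c, s = np.cos(theta), np.sin(theta)
        x = rot.positions[..., 0].copy()
        z = rot.positions[..., 2].copy()
        rot.positions[..., 0] = c * x - s * z + 3210.0  # mm offset
        rot.positions[..., 2] = s * x + c * z - 1234.0
        res1 = pl.run_trial(rot, ang, pl.RunConfig())

        cols = [
            "gait_speed_m_s", "stride_length_m", "step_width_cm",
            "cadence_steps_min", "double_support_pct", "step_length_asymmetry_pct",
        ]
        pd.testing.assert_frame_equal(
            res0.cycles[cols], res1.cycles[cols], atol=1e-6, check_exact=False
        )

    def test_stride_decomposes_into_steps_and_speed_matches(self, one_trial_result):
        df = one_trial_result.cycles
        both = df.dropna(subset=["step_length_ipsi_m", "step_length_contra_m"])
        np.testing.assert_allclose(
            both["stride_length_m"],
            both["step_length_ipsi_m"] + both["step_length_contra_m"],
            atol=0.002,
        )
        np.testing.assert_allclose(
            df["gait_speed_m_s"],
            df["stride_length_m"] / df["duration_s"],
            rtol=0.05,
        )
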