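import dataclasses

import numpy as np
import pytest

from kneegait import synthetic as syn


class TestTemplates:
    def test_calibration_hits_targets_exactly(self):
        tpl = syn.calibrate_template(syn.base_template("knee_angle"), 50.60, 2.50)
        tmax, tmin = tpl.extrema()
        assert tmax == pytest.approx(50.60, abs=1e-6)
        assert tmin == pytest.approx(2.50, abs=1e-6)

    def test_calibration_to_current_extrema_is_identity(self):
        base = syn.base_template("hip_flexion")
        omax, omin = base.extrema()
        tpl = syn.calibrate_template(base, omax, omin)
        phi = np.linspace(0, 1, 97, endpoint=False)
        np.testing.assert_allclose(tpl.evaluate(phi), base.evaluate(phi), atol=1e-9)

    def test_inverted_targets_rejected(self):
        with pytest.raises(ValueError):
            syn.calibrate_template(syn.base_template("knee_angle"), 2.0, 50.0)

    def test_templates_are_periodic(self):
        tpl = syn.base_template("ankle_angle")
        assert tpl.evaluate(0.0) == pytest.approx(tpl.evaluate(1.0), abs=1e-9)

    def test_protocol_calibration_targets_smoothed_extrema(self):
        from kneegait.preprocess import SmoothingConfig

        cfg = SmoothingConfig(31, 3)
        tpl = syn.calibrate_template_to_protocol(
            syn.base_template("knee_angle"), 50.60, 2.50, duration=1.07, frame_rate=60.0,
            smoothing=cfg,
        )
        smax, smin = syn.protocol_extrema(tpl, 1.07, 60.0, cfg)
        assert smax == pytest.approx(50.60, abs=1e-6)
        assert smin == pytest.approx(2.50, abs=1e-6)


class TestSpecValidation:
    def test_inconsistent_speed_stride_cadence_rejected(self):
        spec = syn.control_cohort_spec(n=2)
        bad_st = dict(spec.targets.spatiotemporal)
        bad_st["gait_speed_m_s"] = (2.0, 0.1)  # stride*cadence/120 stays ~1.24
        with pytest.raises(ValueError, match="stride x cadence"):
            dataclasses.replace(spec, targets=syn.GroupTargets(bad_st, spec.targets.peaks))

    def test_negative_sd_rejected(self):
        spec = syn.control_cohort_spec(n=2)
        bad_st = dict(spec.targets.spatiotemporal)
        bad_st["step_width_cm"] = (8.87, -1.0)
        with pytest.raises(ValueError, match="negative SD"):
            dataclasses.replace(spec, targets=syn.GroupTargets(bad_st, spec.targets.peaks))


class TestStratifiedNormal:
    def test_moments_and_bounds(self):
        rng = np.random.default_rng(0)
        x = syn.stratified_normal(200, 5.0, 2.0, rng, lo=0.0)
        assert x.mean() == pytest.approx(5.0, abs=0.1)
        assert x.std(ddof=1) == pytest.approx(2.0, rel=0.1)
        assert x.min() >= 0.0

    def test_zero_sd_returns_constant(self):
        rng = np.random.default_rng(1)
        np.testing.assert_array_equal(syn.stratified_normal(5, 3.0, 0.0, rng), np.full(5, 3.0))


class TestCohortGeneration:
    def test_bookkeeping_counts(self, tmp_path):
        spec = syn.koa_cohort_spec(n=2, seed=3, trials_per_participant=1, cycles_per_trial=2)
        cohort = syn.generate_cohort(spec)
        assert len(cohort.participants) == 2
        assert all(len(v) == 1 for v in cohort.trials.values())
        syn.write_cohort(cohort, tmp_path)
        assert len(list(tmp_path.glob("*.trc"))) == 2
        assert len(list(tmp_path.glob("*.mot"))) == 2
        truth = (tmp_path / "truth.csv").read_text()
        assert truth.count("KOA001") > 0 and truth.count("KOA002") > 0

    def test_internal_consistency_speed_stride_cadence(self):
        cohort = syn.generate_cohort(syn.koa_cohort_spec(n=6, seed=4))
        for d in cohort.participants:
            assert d.speed == pytest.approx(d.stride / d.duration, rel=1e-9)
            assert d.duration == pytest.approx(120.0 / d.cadence, rel=1e-9)
            assert 0.5 < d.stance_fraction < 0.88
            # step split reproduces the drawn asymmetry
            asym = 200.0 * abs(d.step_left - d.step_right) / (d.step_left + d.step_right)
            assert asym == pytest.approx(d.asymmetry_pct, abs=1e-9)

    def test_byte_identical_outputs_for_same_seed(self, tmp_path):
        spec = syn.control_cohort_spec(n=2, seed=9, trials_per_participant=2)
        for sub in ("a", "b"):
            syn.write_cohort(syn.generate_cohort(spec), tmp_path / sub)
        for fa in sorted((tmp_path / "a").iterdir()):
            fb = tmp_path / "b" / fa.name
            assert fa.read_bytes() == fb.read_bytes(), fa.name

    def test_different_seeds_same_marginals(self):
        n = 40
        a = syn.generate_cohort(syn.koa_cohort_spec(n=n, seed=1, trials_per_participant=1))
        b = syn.generate_cohort(syn.koa_cohort_spec(n=n, seed=2, trials_per_participant=1))
        for param, (mean, sd) in syn.KOA_SPATIOTEMPORAL.items():
            if param == "stride_length_m":
                continue  # derived from speed and cadence, not drawn
            for cohort in (a, b):
                got = np.mean([d.true_parameters()[param] for d in cohort.participants])
                assert abs(got - mean) < 3 * sd / np.sqrt(n) + 1e-9, param

    def test_event_truth_consistent_with_marker_construction(self, one_trial):
        d, mk, ang, truth = one_trial
        z = mk.marker("L_heel")[:, 1] / 1000.0
        t = mk.time
        for hs in truth.heel_strikes["L"]:
            # heel height at a true contact is the global minimum (~0)
            assert np.interp(hs, t, z) < 0.002

    def test_affected_side_assigned_for_patients_only(self, small_koa_cohort, small_control_cohort):
        assert all(d.affected_side in ("L", "R") for d in small_koa_cohort.participants)
        assert all(d.affected_side is None for d in small_control_cohort.participants)
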