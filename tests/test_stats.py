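import numpy as np
import pandas as pd
import pytest

from kneegait.stats import (
    build_table1,
    build_table2,
    chi_square,
    cohens_d,
    compare_groups,
    normality_p,
    variance_homogeneity_p,
    welch_t,
)


def exact_moments(n, mean, sd, rng):
    """Sample with the requested mean and (ddof=1) SD exactly."""
    x = rng.normal(size=n)
    x = (x - x.mean()) / x.std(ddof=1)
    return mean + sd * x


class TestScreens:
    def test_uniform_grid_fails_shapiro_normality(self):
        # an evenly spaced (uniform-law) sample is flagged as non-normal once
        # n is large enough for the test to have power
        assert normality_p(np.linspace(0.0, 1.0, 100)) < 0.05
        assert normality_p(np.linspace(0.0, 1.0, 200)) < 0.001

    def test_identical_groups_pass_levene(self):
        rng = np.random.default_rng(0)
        a = rng.normal(size=30)
        assert variance_homogeneity_p(a, a) == pytest.approx(1.0, abs=1e-9)

    def test_minimum_sample_size(self):
        with pytest.raises(ValueError):
            normality_p(np.array([1.0, 2.0]))
        with pytest.raises(ValueError):
            variance_homogeneity_p(np.array([1.0, 2.0]), np.array([3.0, 4.0]))


class TestWelch:
    def test_identical_groups(self):
        a = np.array([1.0, 2.0, 3.0])
        t, df, p = welch_t(a, a)
        assert t == 0.0 and p == pytest.approx(1.0)

    def test_known_two_group_case(self):
        # equal-variance groups mean 10 vs 12, sd 2, n 16 each:
        # t = -2/(2*sqrt(2/16)) = -2.828, Satterthwaite df = 30
        rng = np.random.default_rng(7)
        a = exact_moments(16, 10.0, 2.0, rng)
        b = exact_moments(16, 12.0, 2.0, rng)
        t, df, p = welch_t(a, b)
        assert t == pytest.approx(-2.828, abs=0.001)
        assert df == pytest.approx(30.0, abs=1e-6)
        assert p == pytest.approx(0.008, abs=0.001)

    def test_scale_invariance(self):
        rng = np.random.default_rng(8)
        a, b = rng.normal(0, 1, 20), rng.normal(0.5, 2, 15)
        np.testing.assert_allclose(welch_t(a, b), welch_t(10 * a, 10 * b), atol=1e-12)


class TestChiSquare:
    def test_sex_distribution_table(self):
        # hand-computed: margins give expected counts 28.81/49.19/12.19/20.81,
        # Pearson statistic 0.262
        stat, p = chi_square(np.array([[30, 48], [11, 22]]))
        assert stat == pytest.approx(0.262, abs=0.001)
        assert p > 0.05

    def test_proportional_table(self):
        stat, p = chi_square(np.array([[10, 20], [30, 60]]))
        assert stat == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_zero_row_is_an_error(self):
        with pytest.raises(ValueError):
            chi_square(np.array([[0, 0], [5, 5]]))


class TestCohensD:
    def test_equal_means(self):
        rng = np.random.default_rng(2)
        a = rng.normal(size=20)
        assert cohens_d(a, a + 0.0) == 0.0

    def test_pooled_sd_formula_on_reported_moments(self):
        # pooled SD of (0.55, n=78) and (0.62, n=33) is 0.5714, so a mean gap
        # of 0.35 gives d = 0.6125
        rng = np.random.default_rng(3)
        a = exact_moments(78, 1.32, 0.55, rng)
        b = exact_moments(33, 0.97, 0.62, rng)
        assert cohens_d(a, b) == pytest.approx(0.6125, abs=0.001)

    def test_antisymmetry(self):
        rng = np.random.default_rng(4)
        a, b = rng.normal(0, 1, 12), rng.normal(1, 2, 18)
        assert cohens_d(a, b) == pytest.approx(-cohens_d(b, a))


class TestTables:
    def _summary(self, rng, n, speed_mean):
        return pd.DataFrame(
            {
                "participant": [f"p{i}" for i in range(n)],
                "gait_speed_m_s": rng.normal(speed_mean, 0.1, n),
                "stride_length_m": rng.normal(1.3, 0.1, n),
                "step_width_cm": rng.normal(9.0, 1.0, n),
                "cadence_steps_min": rng.normal(110, 5, n),
                "double_support_pct": rng.normal(22, 2, n),
                "step_length_asymmetry_pct": rng.normal(3, 1, n),
            }
        )

    def test_identical_groups_give_p_one(self):
        rng = np.random.default_rng(5)
        a = self._summary(rng, 10, 1.2)
        table = build_table1(a, a.copy())
        assert np.allclose(table["p"], 1.0)
        assert list(table["parameter"])[:2] == ["Gait speed (m/s)", "Stride length (m)"]

    def test_configured_speed_deficit_is_detected(self):
        rng = np.random.default_rng(6)
        a = self._summary(rng, 20, 1.24)
        b = self._summary(rng, 20, 0.87)  # large configured effect (d ~ 3.7)
        table = build_table1(a, b)
        speed_row = table[table["parameter"] == "Gait speed (m/s)"].iloc[0]
        assert speed_row["p"] < 0.05

    def test_table2_shape_and_bilateral_reference(self):
        rng = np.random.default_rng(7)
        def peaks(n, knee):
            return pd.DataFrame({
                "participant": [f"p{i}" for i in range(n)],
                "knee_flexion": rng.normal(knee, 2.0, n),
                "knee_extension": rng.normal(2.0, 1.0, n),
            })
        t2 = build_table2(peaks(15, 50.0), peaks(15, 52.0), peaks(8, 37.0), peaks(8, 40.0))
        assert list(t2["peak"]) == ["Flexion", "Extension"]
        row = t2[t2["peak"] == "Flexion"].iloc[0]
        assert row["control_mean"] == pytest.approx(51.0, abs=1.0)
        assert row["p_affected_vs_control"] < 0.001
        assert {"p_affected_vs_control", "p_unaffected_vs_control"} <= set(t2.columns)


def test_compare_groups_drops_nonfinite():
    a = np.array([1.0, 2.0, np.nan, 3.0])
    b = np.array([1.5, 2.5, 3.5])
    cmp = compare_groups("x", a, b)
    assert cmp.n_a == 3 and np.isfinite(cmp.p_value)
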