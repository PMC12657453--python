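"""Group-level statistics for two-cohort gait comparisons.

Continuous parameters are compared with Welch's unequal-variance t-test
(Satterthwaite degrees of freedom) regardless of the Shapiro-Wilk and Levene
screens, which are computed for reporting only; categorical tables use the
Pearson chi-square without continuity correction.  Effect sizes are Cohen's d
in its pooled-SD form.  Table builders assemble the demographic/spatiotemporal
comparison and the 15-row peak-angle comparison (affected and unaffected sides
each against the control group's bilateral mean).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "GroupComparison",
    "normality_p",
    "variance_homogeneity_p",
    "welch_t",
    "chi_square",
    "cohens_d",
    "compare_groups",
    "build_table1",
    "build_table2",
    "TABLE1_ROW_ORDER",
    "TABLE2_ROW_ORDER",
]


@dataclass
class GroupComparison:
    parameter: str
    mean_a: float
    sd_a: float
    n_a: int
    mean_b: float
    sd_b: float
    n_b: int
    test: str  # "welch_t" | "chi_square"
    statistic: float
    df: float
    p_value: float
    effect_size_d: float | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_value <= 1.0:
            raise ValueError("p-value outside [0, 1]")


def normality_p(values: np.ndarray) -> float:
    """Shapiro-Wilk p-value (reporting only; does not switch the test used)."""
    x = np.asarray(values, dtype=float)
    if len(x) < 3:
        raise ValueError("Shapiro-Wilk needs at least 3 values")
    return float(sps.shapiro(x).pvalue)


def variance_homogeneity_p(a: np.ndarray, b: np.ndarray) -> float:
    """Levene (Brown-Forsythe, centre = median) p-value, reporting only."""
    a, b = np.asarray(a, dtype=float), np.asarray(b, dtype=float)
    if len(a) < 3 or len(b) < 3:
        raise ValueError("Levene test needs at least 3 values per group")
    return float(sps.levene(a, b, center="median").pvalue)


def welch_t(a: np.ndarray, b: np.ndarray) -> tuple[float, float, float]:
    """Welch's t statistic, Satterthwaite df, and two-sided p-value."""
    a, b = np.asarray(a, dtype=float), np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("Welch t-test needs at least 2 values per group")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    na, nb = len(a), len(b)
    se2 = va / na + vb / nb
    if se2 == 0.0:
        return 0.0, float(na + nb - 2), 1.0
    t = (a.mean() - b.mean()) / np.sqrt(se2)
    df = se2**2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
    p = 2.0 * sps.t.sf(abs(t), df)
    return float(t), float(df), float(p)


def chi_square(table: np.ndarray, correction: bool = False) -> tuple[float, float]:
    """Pearson chi-square on a contingency table (no Yates correction by default)."""
    obs = np.asarray(table, dtype=float)
    if obs.ndim != 2:
        raise ValueError("chi_square expects a 2-D contingency table")
    if np.any(obs.sum(axis=1) == 0) or np.any(obs.sum(axis=0) == 0):
        raise ValueError("contingency table has an empty row or column")
    res = sps.chi2_contingency(obs, correction=correction)
    return float(res.statistic), float(res.pvalue)


def cohens_d(a: np.ndarray, b: np.ndarray) -> float:
    """(mean A - mean B) / pooled SD; sign kept."""
    a, b = np.asarray(a, dtype=float), np.asarray(b, dtype=float)
    na, nb = len(a), len(b)
    if na < 2 or nb < 2:
        raise ValueError("Cohen's d needs at least 2 values per group")
    pooled = np.sqrt(((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / (na + nb - 2))
    if pooled == 0.0:
        return 0.0
    return float((a.mean() - b.mean()) / pooled)


def compare_groups(parameter: str, a: np.ndarray, b: np.ndarray) -> GroupComparison:
    """Welch comparison of one continuous parameter between two groups."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    a, b = a[np.isfinite(a)], b[np.isfinite(b)]
    t, df, p = welch_t(a, b)
    return GroupComparison(
        parameter=parameter,
        mean_a=float(a.mean()),
        sd_a=float(a.std(ddof=1)),
        n_a=len(a),
        mean_b=float(b.mean()),
        sd_b=float(b.std(ddof=1)),
        n_b=len(b),
        test="welch_t",
        statistic=t,
        df=df,
        p_value=p,
        effect_size_d=cohens_d(a, b),
    )


TABLE1_ROW_ORDER = [
    ("Gait speed (m/s)", "gait_speed_m_s"),
    ("Stride length (m)", "stride_length_m"),
    ("Step width (cm)", "step_width_cm"),
    ("Cadence (step/min)", "cadence_steps_min"),
    ("Double support (%cycle)", "double_support_pct"),
    ("Step length asymmetry (%)", "step_length_asymmetry_pct"),
]

TABLE2_ROW_ORDER = [
    ("Pelvis", "Tilt", "pelvis_tilt"),
    ("Pelvis", "List", "pelvis_list"),
    ("Pelvis", "Rotation", "pelvis_rotation"),
    ("Hip", "Flexion", "hip_flexion"),
    ("Hip", "Extension", "hip_extension"),
    ("Hip", "Adduction", "hip_adduction"),
    ("Hip", "Abduction", "hip_abduction"),
    ("Hip", "Internal Rotation", "hip_internal_rotation"),
    ("Hip", "External Rotation", "hip_external_rotation"),
    ("Knee", "Flexion", "knee_flexion"),
    ("Knee", "Extension", "knee_extension"),
    ("Ankle", "Dorsiflexion", "ankle_dorsiflexion"),
    ("Ankle", "Plantarflexion", "ankle_plantarflexion"),
    ("Subtalar", "Inversion", "subtalar_inversion"),
    ("Subtalar", "Eversion", "subtalar_eversion"),
]


def build_table1(
    summary_a: pd.DataFrame, summary_b: pd.DataFrame, label_a: str = "control", label_b: str = "koa"
) -> pd.DataFrame:
    """Spatiotemporal comparison table (one Welch row per parameter).

    Group A is conventionally the control group; rows follow the standard
    report order (speed, stride, width, cadence, double support, asymmetry).
    """
    rows = []
    for label, col in TABLE1_ROW_ORDER:
        if col not in summary_a.columns or col not in summary_b.columns:
            continue
        cmp = compare_groups(label, summary_a[col].to_numpy(), summary_b[col].to_numpy())
        rows.append(
            {
                "parameter": label,
                f"{label_a}_mean": cmp.mean_a,
                f"{label_a}_sd": cmp.sd_a,
                f"{label_b}_mean": cmp.mean_b,
                f"{label_b}_sd": cmp.sd_b,
                "t": cmp.statistic,
                "df": cmp.df,
                "p": cmp.p_value,
                "d": cmp.effect_size_d,
            }
        )
    return pd.DataFrame(rows)


def build_table2(
    control_left: pd.DataFrame,
    control_right: pd.DataFrame,
    affected: pd.DataFrame,
    unaffected: pd.DataFrame,
) -> pd.DataFrame:
    """Peak-angle comparison: affected and unaffected sides vs control bilateral mean.

    Inputs are per-participant peak summaries (one row per participant, one
    column per peak).  The control reference for each participant is the mean
    of their left and right per-side values, computed before any group
    statistic.  Produces two p-value columns, as in the standard report shape.
    """
    rows = []
    for joint, peak_label, col in TABLE2_ROW_ORDER:
        if col not in control_left.columns:
            continue
        ctrl = 0.5 * (control_left[col].to_numpy() + control_right[col].to_numpy())
        aff = affected[col].to_numpy(dtype=float)
        unaff = unaffected[col].to_numpy(dtype=float)
        cmp1 = compare_groups(col, aff, ctrl)
        cmp2 = compare_groups(col, unaff, ctrl)
        rows.append(
            {
                "joint": joint,
                "peak": peak_label,
                "control_mean": float(np.nanmean(ctrl)),
                "control_sd": float(np.nanstd(ctrl, ddof=1)),
                "affected_mean": cmp1.mean_a,
                "affected_sd": cmp1.sd_a,
                "unaffected_mean": cmp2.mean_a,
                "unaffected_sd": cmp2.sd_a,
                "p_affected_vs_control": cmp1.p_value,
                "p_unaffected_vs_control": cmp2.p_value,
                "d_affected_vs_control": cmp1.effect_size_d,
                "d_unaffected_vs_control": cmp2.effect_size_d,
            }
        )
    return pd.DataFrame(rows)
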