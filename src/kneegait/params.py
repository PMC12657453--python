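"""Spatiotemporal gait parameters and peak joint angles.

Six spatiotemporal quantities are computed per cycle — gait speed (m/s),
stride length (m), step width (m, reported in cm), cadence (steps/min),
double support (% of cycle) and step-length asymmetry (%) — together with
fifteen signed peak joint angles (pelvis tilt/list/rotation; hip
flexion/extension, adduction/abduction, internal/external rotation; knee
flexion/extension; ankle dorsiflexion/plantarflexion; subtalar
inversion/eversion).  Per-cycle values are pooled, screened with the +/-3 SD
rule, and averaged per participant to yield representative values.

All geometry is expressed in a per-trial walking frame: the forward axis is
the first principal direction of the pelvis marker's horizontal displacement
(oriented along net travel), the lateral axis its horizontal perpendicular.
Every parameter is therefore invariant to rotating or translating the lab.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .events import GaitCycleRecord, GaitEventTable, stance_intervals
from .io_formats import MarkerTrajectorySet
from .preprocess import outlier_mask

__all__ = [
    "WalkingFrame",
    "walking_direction",
    "marker_at",
    "gait_speed",
    "stride_length",
    "step_length",
    "step_width",
    "cadence",
    "double_support_pct",
    "step_length_asymmetry",
    "peak_angles",
    "cycle_spatiotemporal",
    "participant_summary",
    "SPATIOTEMPORAL_COLUMNS",
    "PEAK_COLUMNS",
    "PEAK_DEFS",
    "AXIS_INDEX",
]

log = logging.getLogger("kneegait")

AXIS_INDEX = {"x": 0, "y": 1, "z": 2}

SPATIOTEMPORAL_COLUMNS = [
    "gait_speed_m_s",
    "stride_length_m",
    "step_width_cm",
    "cadence_steps_min",
    "double_support_pct",
    "step_length_asymmetry_pct",
]

# peak name -> (dof family, side-specific, "max" | "min")
PEAK_DEFS: dict[str, tuple[str, bool, str]] = {
    "pelvis_tilt": ("pelvis_tilt", False, "max"),
    "pelvis_list": ("pelvis_list", False, "max"),
    "pelvis_rotation": ("pelvis_rotation", False, "max"),
    "hip_flexion": ("hip_flexion", True, "max"),
    "hip_extension": ("hip_flexion", True, "min"),
    "hip_adduction": ("hip_adduction", True, "max"),
    "hip_abduction": ("hip_adduction", True, "min"),
    "hip_internal_rotation": ("hip_rotation", True, "max"),
    "hip_external_rotation": ("hip_rotation", True, "min"),
    "knee_flexion": ("knee_angle", True, "max"),
    "knee_extension": ("knee_angle", True, "min"),
    "ankle_dorsiflexion": ("ankle_angle", True, "max"),
    "ankle_plantarflexion": ("ankle_angle", True, "min"),
    "subtalar_inversion": ("subtalar_angle", True, "max"),
    "subtalar_eversion": ("subtalar_angle", True, "min"),
}
PEAK_COLUMNS = list(PEAK_DEFS)


@dataclass(frozen=True)
class WalkingFrame:
    """Forward / lateral unit vectors of a trial, with the vertical axis index."""

    forward: np.ndarray  # (3,), zero vertical component
    lateral: np.ndarray  # (3,), horizontal perpendicular
    vertical_axis: int = 1


def _pelvis_marker_name(markers: MarkerTrajectorySet) -> str:
    for name in markers.marker_names:
        low = name.lower()
        if "pelvis" in low or "sacr" in low:
            return name
    raise KeyError(
        f"no pelvis-region marker (name containing 'pelvis' or 'sacr') in {markers.marker_names}"
    )


def walking_direction(
    markers: MarkerTrajectorySet, vertical_axis: int = 1
) -> WalkingFrame:
    """Walking frame from the pelvis marker's horizontal progression.

    Forward = first principal direction of the horizontal pelvis displacement,
    oriented along the net displacement; lateral = horizontal perpendicular.
    Trials with under 0.5 m of net pelvis travel are rejected.
    """
    if markers.units != "m":
        raise ValueError("walking_direction expects positions in metres (use to_metres)")
    pelvis = markers.marker(_pelvis_marker_name(markers))
    horiz_axes = [a for a in range(3) if a != vertical_axis]
    xy = pelvis[:, horiz_axes]
    xy = xy[np.all(np.isfinite(xy), axis=1)]
    if len(xy) < 2:
        raise ValueError("pelvis trajectory has fewer than 2 finite samples")
    net = xy[-1] - xy[0]
    if np.linalg.norm(net) < 0.5:
        raise ValueError(
            f"trial too short: net pelvis displacement {np.linalg.norm(net):.3f} m < 0.5 m"
        )
    centered = xy - xy.mean(axis=0)
    cov = centered.T @ centered
    eigvals, eigvecs = np.linalg.eigh(cov)
    principal = eigvecs[:, np.argmax(eigvals)]
    if principal @ net < 0:
        principal = -principal
    forward = np.zeros(3)
    forward[horiz_axes] = principal
    lateral = np.zeros(3)
    lateral[horiz_axes] = [-principal[1], principal[0]]
    return WalkingFrame(forward=forward, lateral=lateral, vertical_axis=vertical_axis)


def marker_at(markers: MarkerTrajectorySet, name: str, t: float) -> np.ndarray:
    """Linearly interpolated (3,) position of a marker at time *t*."""
    traj = markers.marker(name)
    return np.array([np.interp(t, markers.time, traj[:, a]) for a in range(3)])


def _heel_name(markers: MarkerTrajectorySet, foot: str) -> str:
    for name in markers.marker_names:
        low = name.lower()
        if "heel" in low and low.startswith(foot.lower()):
            return name
    raise KeyError(f"no {foot} heel marker in {markers.marker_names}")


def gait_speed(
    markers: MarkerTrajectorySet,
    cycle: GaitCycleRecord,
    frame: WalkingFrame,
    source: str = "pelvis",
) -> float:
    """Forward displacement over the cycle divided by its duration (m/s).

    ``source='pelvis'`` (default) tracks the pelvis marker, whose progression
    is steadier than a heel's; ``source='heels'`` uses the ipsilateral heel.
    """
    if source == "pelvis":
        name = _pelvis_marker_name(markers)
    elif source == "heels":
        name = _heel_name(markers, cycle.foot)
    else:
        raise ValueError(f"unknown speed source {source!r}")
    p0 = marker_at(markers, name, cycle.start)
    p1 = marker_at(markers, name, cycle.end)
    return float((p1 - p0) @ frame.forward) / cycle.duration


def stride_length(
    markers: MarkerTrajectorySet, cycle: GaitCycleRecord, frame: WalkingFrame
) -> float:
    """Forward distance between ipsilateral heel positions at the bounding strikes (m)."""
    name = _heel_name(markers, cycle.foot)
    p0 = marker_at(markers, name, cycle.start)
    p1 = marker_at(markers, name, cycle.end)
    return float((p1 - p0) @ frame.forward)


def step_length(
    markers: MarkerTrajectorySet,
    frame: WalkingFrame,
    foot_ipsi: str,
    t_ipsi: float,
    foot_contra: str,
    t_contra: float,
) -> float:
    """Forward distance from the contralateral heel (at its strike) to the
    ipsilateral heel (at its subsequent strike), in metres."""
    p_ipsi = marker_at(markers, _heel_name(markers, foot_ipsi), t_ipsi)
    p_contra = marker_at(markers, _heel_name(markers, foot_contra), t_contra)
    return float((p_ipsi - p_contra) @ frame.forward)


def step_width(
    markers: MarkerTrajectorySet,
    frame: WalkingFrame,
    t_hs_left: float,
    t_hs_right: float,
) -> float:
    """Absolute lateral distance between the heels at their bounding strikes (m)."""
    p_l = marker_at(markers, _heel_name(markers, "L"), t_hs_left)
    p_r = marker_at(markers, _heel_name(markers, "R"), t_hs_right)
    return float(abs((p_l - p_r) @ frame.lateral))


def cadence(cycle: GaitCycleRecord) -> float:
    """Steps per minute: two steps per gait cycle, 120 / duration."""
    return 120.0 / cycle.duration


def _stance_with_open_ends(table: GaitEventTable, foot: str) -> list[tuple[float, float]]:
    """Stance intervals including the half-known ones at the trial edges.

    A toe-off with no preceding heel strike still proves the foot was in
    stance until that instant (stance began before the recording window);
    symmetrically a trailing heel strike opens a stance with no observed end.
    Open ends are clipped by the caller's cycle bounds.
    """
    intervals = stance_intervals(table, foot)
    hs = np.asarray(table.heel_strikes.get(foot, ()), dtype=float)
    to = np.asarray(table.toe_offs.get(foot, ()), dtype=float)
    if len(to) and (len(hs) == 0 or to[0] <= hs[0]):
        intervals.insert(0, (-np.inf, float(to[0])))
    if len(hs) and (len(to) == 0 or hs[-1] >= to[-1]):
        intervals.append((float(hs[-1]), np.inf))
    return intervals


def double_support_pct(table: GaitEventTable, cycle: GaitCycleRecord) -> float:
    """Percentage of the cycle during which both feet are in stance.

    Stance intervals for each foot are intersected pairwise and clipped to the
    cycle; returns NaN (and logs) when the contralateral events needed to
    bound its stance are absent from the cycle.
    """
    contra = "R" if cycle.foot == "L" else "L"
    contra_hs = np.asarray(table.heel_strikes.get(contra, ()))
    contra_to = np.asarray(table.toe_offs.get(contra, ()))
    has_hs = np.any((contra_hs > cycle.start) & (contra_hs < cycle.end))
    has_to = np.any((contra_to > cycle.start) & (contra_to < cycle.end))
    if not (has_hs or has_to):
        log.info(
            "double_support: no contralateral events inside cycle [%0.3f, %0.3f]; value missing",
            cycle.start,
            cycle.end,
        )
        return float("nan")
    ipsi = _stance_with_open_ends(table, cycle.foot)
    other = _stance_with_open_ends(table, contra)
    total = 0.0
    for a0, a1 in ipsi:
        for b0, b1 in other:
            lo = max(a0, b0, cycle.start)
            hi = min(a1, b1, cycle.end)
            if hi > lo:
                total += hi - lo
    return 100.0 * total / cycle.duration


def step_length_asymmetry(left_steps: np.ndarray, right_steps: np.ndarray) -> float:
    """100 * |mean(L) - mean(R)| / (0.5 * (mean(L) + mean(R))), in percent."""
    l_mean = float(np.mean(left_steps))
    r_mean = float(np.mean(right_steps))
    denom = 0.5 * (l_mean + r_mean)
    if denom == 0.0:
        raise ValueError("step-length asymmetry undefined: both mean step lengths are zero")
    return 100.0 * abs(l_mean - r_mean) / denom


def peak_angles(record: GaitCycleRecord) -> dict[str, float]:
    """Signed peak angles (degrees) for one cycle.

    Flexion-type peaks are signed maxima of the normalized curve over the
    cycle; extension-type peaks are signed minima (negative values allowed).
    Peaks whose dof is absent from the record are omitted.
    """
    side = record.foot.lower()
    out: dict[str, float] = {}
    for peak_name, (dof_family, sided, kind) in PEAK_DEFS.items():
        dof = f"{dof_family}_{side}" if sided else dof_family
        curve = record.normalized_curves.get(dof)
        if curve is None:
            continue
        out[peak_name] = float(curve.values.max() if kind == "max" else curve.values.min())
    return out


def cycle_spatiotemporal(
    markers: MarkerTrajectorySet,
    table: GaitEventTable,
    cycle: GaitCycleRecord,
    frame: WalkingFrame,
    speed_source: str = "pelvis",
) -> dict[str, float]:
    """All six spatiotemporal parameters for one cycle (asymmetry from this
    cycle's left/right step pair; NaN where required events are missing)."""
    contra = "R" if cycle.foot == "L" else "L"
    contra_hs = np.asarray(table.heel_strikes.get(contra, ()))
    inside = contra_hs[(contra_hs > cycle.start) & (contra_hs < cycle.end)]
    t_contra = float(inside[0]) if len(inside) else None

    out = {
        "gait_speed_m_s": gait_speed(markers, cycle, frame, source=speed_source),
        "stride_length_m": stride_length(markers, cycle, frame),
        "cadence_steps_min": cadence(cycle),
        "double_support_pct": double_support_pct(table, cycle),
    }
    if t_contra is None:
        out["step_width_cm"] = float("nan")
        out["step_length_asymmetry_pct"] = float("nan")
        out["step_length_ipsi_m"] = float("nan")
        out["step_length_contra_m"] = float("nan")
    else:
        t_left, t_right = (
            (cycle.start, t_contra) if cycle.foot == "L" else (t_contra, cycle.start)
        )
        out["step_width_cm"] = 100.0 * step_width(markers, frame, t_left, t_right)
        # contralateral step: contra heel lands at t_contra after the ipsi
        # strike at cycle.start; ipsilateral step: ipsi heel lands at cycle.end
        step_contra = step_length(markers, frame, contra, t_contra, cycle.foot, cycle.start)
        step_ipsi = step_length(markers, frame, cycle.foot, cycle.end, contra, t_contra)
        left, right = (
            (step_ipsi, step_contra) if cycle.foot == "L" else (step_contra, step_ipsi)
        )
        out["step_length_ipsi_m"] = step_ipsi
        out["step_length_contra_m"] = step_contra
        out["step_length_left_m"] = left
        out["step_length_right_m"] = right
        out["step_length_asymmetry_pct"] = step_length_asymmetry([left], [right])
    return out


def participant_summary(
    cycle_table: pd.DataFrame,
    outlier_k: float = 3.0,
    participant_col: str = "participant",
    value_cols: list[str] | None = None,
) -> pd.DataFrame:
    """Per-participant means of per-cycle values after pooled outlier screening.

    For each value column the +/- ``outlier_k`` SD mask is computed once on
    the pooled (all participants, all cycles) values; surviving cycles are
    averaged per participant.  Returns one row per participant with the mean
    of each parameter and ``n_cycles`` (cycles contributing to at least one
    parameter).
    """
    if value_cols is None:
        value_cols = [
            c
            for c in cycle_table.columns
            if c != participant_col and pd.api.types.is_numeric_dtype(cycle_table[c])
        ]
    df = cycle_table.copy()
    for col in value_cols:
        vals = df[col].to_numpy(dtype=float)
        finite = np.isfinite(vals)
        keep = finite.copy()
        if finite.sum() >= 3:
            keep[finite] = outlier_mask(vals[finite], k=outlier_k)
        n_rejected = int(finite.sum() - keep[finite].sum())
        if n_rejected:
            log.info("participant_summary: %s: %d pooled outliers rejected", col, n_rejected)
        df.loc[~keep, col] = np.nan
    grouped = df.groupby(participant_col, sort=True)
    out = grouped[value_cols].mean()
    out["n_cycles"] = grouped.size()
    return out.reset_index()
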