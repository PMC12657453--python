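"""Gait-event detection, cycle segmentation and quality control.

Heel strike is taken as a local minimum of the vertical heel-marker
trajectory; toe off as the instant of peak upward toe-marker velocity (the
onset of rapid vertical rise at push-off).  Both definitions need nothing but
the displacement profiles a markerless system provides — no force plate.
Candidate events must clear an adaptive prominence threshold (0.2 x the
trajectory's 5th-to-95th percentile range) and respect a refractory interval
(default 0.5 s, a cadence ceiling of 240 steps/min); timing is refined to
sub-frame resolution by parabolic interpolation, which matters at 60 Hz where
one frame is 16.7 ms — a material fraction of double support.

A gait cycle runs from one heel strike to the next ipsilateral heel strike.
Quality control rejects cycles with abnormal timing, marker discontinuities,
or biomechanically implausible joint-angle excursions, mirroring the screening
applied to real markerless captures.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.signal import find_peaks

from .io_formats import JointAngleSeries
from .preprocess import NormalizedCurve, time_normalize  # noqa: F401 (re-export context)

__all__ = [
    "GaitEventTable",
    "GaitCycleRecord",
    "QCCriteria",
    "detect_heel_strikes",
    "detect_toe_offs",
    "stance_intervals",
    "segment_cycles",
    "qc_cycles",
    "PROMINENCE_FRACTION",
    "FLAT_RANGE_M",
]

log = logging.getLogger("kneegait")

PROMINENCE_FRACTION = 0.2  # of the 5th-95th percentile range
FLAT_RANGE_M = 0.001  # trajectories flatter than 1 mm carry no events


@dataclass
class GaitEventTable:
    """Heel-strike and toe-off times (seconds, ascending) per foot."""

    heel_strikes: dict[str, np.ndarray] = field(default_factory=dict)
    toe_offs: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for d in (self.heel_strikes, self.toe_offs):
            for foot, times in d.items():
                arr = np.asarray(times, dtype=float)
                if len(arr) >= 2 and not np.all(np.diff(arr) > 0):
                    raise ValueError(f"{foot} events must be strictly increasing")
                d[foot] = arr

    def feet(self) -> list[str]:
        return sorted(set(self.heel_strikes) | set(self.toe_offs))


@dataclass
class QCCriteria:
    """Acceptance rules for segmented cycles.

    Duration bounds bracket the cadences plausible for slow pathological
    through brisk healthy walking; plausibility bounds are generous anatomical
    ranges per joint family, matched against a dof name by substring.
    """

    duration_bounds: tuple[float, float] = (0.4, 2.5)
    max_gap_frames: int = 10
    angle_plausibility_bounds: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {
            "pelvis": (-40.0, 40.0),
            "hip": (-60.0, 70.0),
            "knee": (-20.0, 100.0),
            "ankle": (-60.0, 60.0),
            "subtalar": (-50.0, 50.0),
        }
    )

    def __post_init__(self) -> None:
        lo, hi = self.duration_bounds
        if not lo < hi:
            raise ValueError("duration bounds must be ordered")
        for fam, (a, b) in self.angle_plausibility_bounds.items():
            if not a < b:
                raise ValueError(f"plausibility bounds for {fam} must be ordered")


@dataclass
class GaitCycleRecord:
    """One segmented gait cycle with normalized curves and event phases."""

    foot: str
    start: float
    end: float
    normalized_curves: dict[str, NormalizedCurve]
    events_in_cycle: dict[str, float | None] = field(default_factory=dict)
    qc_status: str = "accepted"
    max_marker_gap_frames: int = 0
    participant: str | None = None
    trial: str | None = None

    @property
    def duration(self) -> float:
        return self.end - self.start

    def __post_init__(self) -> None:
        if not self.end > self.start:
            raise ValueError("cycle end must be after start")


def _refine_parabolic(y: np.ndarray, i: int) -> float:
    """Sub-frame offset of an extremum at index *i* (vertex of a 3-point parabola).

    The shift is capped at one frame: beyond that the local quadratic model is
    not trustworthy and the discrete extremum is the better estimate.
    """
    if i <= 0 or i >= len(y) - 1:
        return 0.0
    denom = y[i - 1] - 2.0 * y[i] + y[i + 1]
    if denom == 0.0:
        return 0.0
    delta = 0.5 * (y[i - 1] - y[i + 1]) / denom
    return float(np.clip(delta, -1.0, 1.0))


def detect_heel_strikes(
    heel_vertical: np.ndarray,
    frame_rate: float,
    min_interval: float = 0.5,
    start_time: float = 0.0,
) -> np.ndarray:
    """Times of heel-strike events from a (smoothed, gap-free) vertical profile.

    Heel strikes are prominent local minima of the heel height; the prominence
    floor adapts to the trajectory's amplitude so the same rule works in
    millimetres or metres.
    """
    z = np.asarray(heel_vertical, dtype=float)
    if len(z) < 3:
        return np.empty(0)
    p5, p95 = np.percentile(z, [5, 95])
    if p95 - p5 < FLAT_RANGE_M:
        warnings.warn("heel trajectory is flat (<1 mm range); no events detected", stacklevel=2)
        return np.empty(0)
    prominence = PROMINENCE_FRACTION * (p95 - p5)
    distance = max(1, int(round(min_interval * frame_rate)))
    idx, _ = find_peaks(-z, prominence=prominence, distance=distance)
    times = [start_time + (i + _refine_parabolic(z, i)) / frame_rate for i in idx]
    return np.asarray(times)


def detect_toe_offs(
    toe_vertical: np.ndarray,
    frame_rate: float,
    min_interval: float = 0.5,
    start_time: float = 0.0,
) -> np.ndarray:
    """Times of toe-off events: peaks of upward toe-marker velocity.

    The vertical velocity (central difference of the smoothed trajectory) has
    one dominant positive peak per cycle at the onset of swing; prominence
    gating on the velocity signal suppresses lesser fluctuations.
    """
    z = np.asarray(toe_vertical, dtype=float)
    if len(z) < 3:
        return np.empty(0)
    p5, p95 = np.percentile(z, [5, 95])
    if p95 - p5 < FLAT_RANGE_M:
        warnings.warn("toe trajectory is flat (<1 mm range); no events detected", stacklevel=2)
        return np.empty(0)
    v = np.gradient(z) * frame_rate
    vp5, vp95 = np.percentile(v, [5, 95])
    if vp95 - vp5 < 1e-6:  # constant velocity (e.g. monotone ramp): no push-off
        return np.empty(0)
    prominence = PROMINENCE_FRACTION * (vp95 - vp5)
    distance = max(1, int(round(min_interval * frame_rate)))
    idx, _ = find_peaks(v, prominence=prominence, distance=distance)
    times = [start_time + (i + _refine_parabolic(-v, i)) / frame_rate for i in idx]
    return np.asarray(times)


def stance_intervals(table: GaitEventTable, foot: str) -> list[tuple[float, float]]:
    """[heel_strike, next toe_off] intervals for one foot.

    Each heel strike is matched to the first subsequent toe-off; unmatched
    leading toe-offs and trailing heel strikes are dropped (logged).
    """
    hs = np.asarray(table.heel_strikes.get(foot, ()), dtype=float)
    to = np.asarray(table.toe_offs.get(foot, ()), dtype=float)
    intervals: list[tuple[float, float]] = []
    j = 0
    dropped = 0
    while j < len(to) and (len(hs) == 0 or to[j] <= hs[0]):
        j += 1  # leading toe-offs with no preceding heel strike
        dropped += 1
    for i, h in enumerate(hs):
        while j < len(to) and to[j] <= h:
            j += 1
        if j >= len(to):
            dropped += 1
            continue  # trailing heel strike without a toe-off
        nxt_hs = hs[i + 1] if i + 1 < len(hs) else np.inf
        if to[j] < nxt_hs:
            intervals.append((float(h), float(to[j])))
            j += 1
        else:
            dropped += 1  # no toe-off before the next strike of this foot
    if dropped:
        log.info("stance_intervals(%s): dropped %d unmatched events", foot, dropped)
    return intervals


def _pct_of_cycle(t: float | None, start: float, end: float) -> float | None:
    if t is None:
        return None
    return 100.0 * (t - start) / (end - start)


def segment_cycles(
    table: GaitEventTable,
    angles: JointAngleSeries,
    foot: str,
    n_points: int = 101,
) -> list[GaitCycleRecord]:
    """Cut and time-normalize joint-angle curves for each ipsilateral cycle.

    For every consecutive heel-strike pair of *foot*, every dof in *angles* is
    linearly interpolated onto ``n_points`` evenly spaced instants spanning the
    cycle.  Contralateral heel strike and both toe-offs falling inside the
    cycle are recorded as percentages of the cycle.
    """
    hs = np.asarray(table.heel_strikes.get(foot, ()), dtype=float)
    if len(hs) < 2:
        return []
    contra = "R" if foot == "L" else "L"
    contra_hs = np.asarray(table.heel_strikes.get(contra, ()), dtype=float)
    ipsi_to = np.asarray(table.toe_offs.get(foot, ()), dtype=float)
    contra_to = np.asarray(table.toe_offs.get(contra, ()), dtype=float)

    records = []
    for start, end in zip(hs[:-1], hs[1:]):
        grid_t = np.linspace(start, end, n_points)
        curves = {
            name: NormalizedCurve(np.interp(grid_t, angles.time, angles.dof(name)))
            for name in angles.dof_names
        }

        def _first_in(events: np.ndarray, lo: float, hi: float) -> float | None:
            inside = events[(events > lo) & (events < hi)]
            return float(inside[0]) if len(inside) else None

        rec = GaitCycleRecord(
            foot=foot,
            start=float(start),
            end=float(end),
            normalized_curves=curves,
            events_in_cycle={
                "contra_heel_strike_pct": _pct_of_cycle(_first_in(contra_hs, start, end), start, end),
                "ipsi_toe_off_pct": _pct_of_cycle(_first_in(ipsi_to, start, end), start, end),
                "contra_toe_off_pct": _pct_of_cycle(_first_in(contra_to, start, end), start, end),
            },
        )
        records.append(rec)
    return records


def qc_cycles(
    records: list[GaitCycleRecord],
    criteria: QCCriteria = QCCriteria(),
) -> tuple[list[GaitCycleRecord], list[tuple[GaitCycleRecord, str]]]:
    """Split cycles into accepted ones and (record, reason) rejections.

    Reason codes: ``abnormal_timing`` (duration outside bounds),
    ``marker_discontinuity`` (an unfilled marker gap longer than
    ``max_gap_frames`` inside the cycle), ``implausible_trajectory`` (a dof
    leaves its anatomical plausibility band).
    """
    accepted, rejected = [], []
    lo, hi = criteria.duration_bounds
    for rec in records:
        reason = None
        if not lo <= rec.duration <= hi:
            reason = "abnormal_timing"
        elif rec.max_marker_gap_frames > criteria.max_gap_frames:
            reason = "marker_discontinuity"
        else:
            for name, curve in rec.normalized_curves.items():
                fam = next(
                    (f for f in criteria.angle_plausibility_bounds if f in name), None
                )
                if fam is None:
                    continue
                blo, bhi = criteria.angle_plausibility_bounds[fam]
                if curve.values.min() < blo or curve.values.max() > bhi:
                    reason = "implausible_trajectory"
                    break
        if reason is None:
            rec.qc_status = "accepted"
            accepted.append(rec)
        else:
            rec.qc_status = f"rejected:{reason}"
            rejected.append((rec, reason))
            log.info(
                "qc: rejected %s cycle [%0.3f, %0.3f] s: %s", rec.foot, rec.start, rec.end, reason
            )
    return accepted, rejected
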