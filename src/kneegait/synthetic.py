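"""Synthetic two-group gait cohorts with exact ground truth.

The generator emulates the downstream products of a markerless capture
session — TRC marker files (pelvis, heels, toes) and MOT joint-angle files at
60 Hz — for cohorts whose group-level structure follows the published
spatiotemporal and peak-angle tables for knee-osteoarthritis (KOA) and
control walkers.  Every stage of the analysis pipeline can therefore be
scored against known truth: participant-level parameter draws, per-trial
heel-strike/toe-off times, and per-cycle peak angles.

Construction principles
-----------------------
* Kinematic waveforms are truncated Fourier series (K = 6), smooth and
  periodic, built from hand-authored normative control points and then
  affinely calibrated per participant so their extrema hit the drawn peak
  targets exactly.  The templates are synthetic stand-ins with the right
  qualitative shape, not measured curves.
* Event features are locally symmetric by design — heel contact is a
  symmetric dip in heel height, toe-off the centre of a symmetric-velocity
  rise — so that symmetric linear smoothing cannot bias detected timing.
* Participant-level parameters are drawn by stratified (balanced) inverse-CDF
  sampling of the configured normal distribution: marginals keep the target
  mean/SD while realized cohort moments match the targets closely, which is
  what a known-answer generator needs.
* Internal consistency is enforced by construction: cycle duration comes from
  drawn cadence, stride = speed x duration, stance fraction from drawn double
  support (contralateral offset fixed at 50 % of the cycle), left/right step
  lengths split to produce the drawn asymmetry.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import ndtri

from .io_formats import JointAngleSeries, MarkerTrajectorySet, write_mot, write_trc
from .preprocess import SmoothingConfig, savgol_smooth

__all__ = [
    "WaveformTemplate",
    "GroupTargets",
    "CohortSpec",
    "ParticipantDraw",
    "TrialTruth",
    "Cohort",
    "calibrate_template",
    "base_template",
    "synth_trial",
    "generate_cohort",
    "write_cohort",
    "stratified_normal",
    "CONTROL_SPATIOTEMPORAL",
    "KOA_SPATIOTEMPORAL",
    "CONTROL_PEAKS",
    "KOA_AFFECTED_PEAKS",
    "KOA_UNAFFECTED_PEAKS",
    "control_cohort_spec",
    "koa_cohort_spec",
    "PEAK_FAMILY_PAIRS",
    "PELVIS_SINGLE_PEAKS",
]

N_HARMONICS = 6

# ---------------------------------------------------------------------------
# published group structure used as default generator targets
# (mean, SD) per group; spatiotemporal units as reported, angles in degrees
# ---------------------------------------------------------------------------

CONTROL_SPATIOTEMPORAL = {
    "gait_speed_m_s": (1.24, 0.37),
    "stride_length_m": (1.32, 0.55),
    "step_width_cm": (8.87, 2.10),
    "cadence_steps_min": (112.50, 12.33),
    "double_support_pct": (22.68, 3.27),
    "step_length_asymmetry_pct": (2.75, 1.17),
}

KOA_SPATIOTEMPORAL = {
    "gait_speed_m_s": (0.87, 0.44),
    "stride_length_m": (0.97, 0.62),
    "step_width_cm": (13.23, 3.92),
    "cadence_steps_min": (98.30, 18.89),
    "double_support_pct": (38.54, 10.26),
    "step_length_asymmetry_pct": (7.67, 4.83),
}

CONTROL_PEAKS = {
    "pelvis_tilt": (-3.25, 5.74),
    "pelvis_list": (-3.90, 4.74),
    "pelvis_rotation": (5.39, 5.16),
    "hip_flexion": (23.07, 7.06),
    "hip_extension": (-14.81, 6.82),
    "hip_adduction": (5.32, 4.64),
    "hip_abduction": (-7.35, 5.13),
    "hip_internal_rotation": (-3.02, 5.85),
    "hip_external_rotation": (-11.41, 8.15),
    "knee_flexion": (50.60, 8.78),
    "knee_extension": (2.50, 4.90),
    "ankle_dorsiflexion": (6.88, 14.13),
    "ankle_plantarflexion": (-5.43, 19.55),
    "subtalar_inversion": (2.88, 12.84),
    "subtalar_eversion": (-10.37, 10.86),
}

KOA_AFFECTED_PEAKS = {
    "pelvis_tilt": (-5.10, 5.59),
    "pelvis_list": (-0.86, 3.18),
    "pelvis_rotation": (4.00, 6.26),
    "hip_flexion": (20.25, 7.72),
    "hip_extension": (-11.96, 6.49),
    "hip_adduction": (1.63, 4.52),
    "hip_abduction": (-5.17, 4.43),
    "hip_internal_rotation": (-7.65, 6.33),
    "hip_external_rotation": (-13.47, 6.77),
    "knee_flexion": (37.39, 13.69),
    "knee_extension": (0.30, 3.21),
    "ankle_dorsiflexion": (6.49, 12.35),
    "ankle_plantarflexion": (-8.94, 9.91),
    "subtalar_inversion": (5.37, 12.79),
    "subtalar_eversion": (-4.60, 11.44),
}

KOA_UNAFFECTED_PEAKS = {
    "pelvis_tilt": (-2.12, 5.56),
    "pelvis_list": (-3.01, 3.15),
    "pelvis_rotation": (0.40, 7.19),
    "hip_flexion": (17.75, 7.54),
    "hip_extension": (-10.92, 8.34),
    "hip_adduction": (3.01, 5.33),
    "hip_abduction": (-5.31, 11.36),
    "hip_internal_rotation": (-9.63, 7.69),
    "hip_external_rotation": (-20.46, 12.61),
    "knee_flexion": (36.13, 16.51),
    "knee_extension": (0.05, 2.75),
    "ankle_dorsiflexion": (8.68, 12.00),
    "ankle_plantarflexion": (-7.82, 10.45),
    "subtalar_inversion": (13.39, 11.06),
    "subtalar_eversion": (0.69, 18.75),
}

# peak families: (max peak name, min peak name) sharing one dof column
PEAK_FAMILY_PAIRS = {
    "hip_flexion": ("hip_flexion", "hip_extension"),
    "hip_adduction": ("hip_adduction", "hip_abduction"),
    "hip_rotation": ("hip_internal_rotation", "hip_external_rotation"),
    "knee_angle": ("knee_flexion", "knee_extension"),
    "ankle_angle": ("ankle_dorsiflexion", "ankle_plantarflexion"),
    "subtalar_angle": ("subtalar_inversion", "subtalar_eversion"),
}
# pelvis peaks are reported as a single signed extremum (the curve maximum);
# the template's native excursion is preserved below it
PELVIS_SINGLE_PEAKS = {
    "pelvis_tilt": "pelvis_tilt",
    "pelvis_list": "pelvis_list",
    "pelvis_rotation": "pelvis_rotation",
}

# hand-authored normative control points (percent of cycle, degrees);
# qualitative shapes only — extrema are recalibrated per participant
_TEMPLATE_POINTS: dict[str, list[tuple[float, float]]] = {
    "pelvis_tilt": [(0, -3.5), (12, -2.5), (25, -4.0), (37, -3.0), (50, -3.5),
                    (62, -2.5), (75, -4.0), (87, -3.0)],
    "pelvis_list": [(0, 0.0), (10, 3.0), (30, 1.0), (50, 0.0), (60, -3.0), (80, -1.0), (90, 0.0)],
    "pelvis_rotation": [(0, 4.0), (25, 0.0), (50, -4.0), (75, 0.0)],
    "hip_flexion": [(0, 28.0), (10, 22.0), (30, 2.0), (50, -8.0), (55, -5.0),
                    (65, 12.0), (85, 32.0), (95, 30.0)],
    "hip_adduction": [(0, 0.0), (15, 5.0), (40, 2.0), (55, -3.0), (70, -5.0), (85, -2.0)],
    "hip_rotation": [(0, -2.0), (20, 2.0), (50, -1.0), (70, -6.0), (90, -4.0)],
    "knee_angle": [(0, 5.0), (8, 12.0), (15, 17.0), (30, 8.0), (40, 4.0), (55, 12.0),
                   (65, 45.0), (72, 60.0), (80, 48.0), (90, 15.0), (97, 6.0)],
    "ankle_angle": [(0, 0.0), (7, -5.0), (20, 4.0), (45, 10.0), (55, 2.0), (62, -15.0),
                    (70, -8.0), (80, 2.0), (90, 3.0)],
    "subtalar_angle": [(0, 2.0), (10, -3.0), (30, -5.0), (50, -4.0), (62, 2.0),
                       (75, 5.0), (90, 4.0)],
}


# ---------------------------------------------------------------------------
# waveform templates
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class WaveformTemplate:
    """Periodic joint-angle waveform: truncated Fourier series on phase [0, 1)."""

    name: str
    a0: float
    a: np.ndarray  # cosine coefficients, k = 1..K
    b: np.ndarray  # sine coefficients, k = 1..K

    def evaluate(self, phase: np.ndarray) -> np.ndarray:
        phi = np.atleast_1d(np.asarray(phase, dtype=float))
        k = np.arange(1, len(self.a) + 1)
        arg = 2.0 * np.pi * np.outer(phi, k)
        out = self.a0 + np.cos(arg) @ self.a + np.sin(arg) @ self.b
        return out if np.ndim(phase) else float(out[0])

    def extrema(self, n_grid: int = 4096) -> tuple[float, float]:
        vals = self.evaluate(np.linspace(0.0, 1.0, n_grid, endpoint=False))
        return float(vals.max()), float(vals.min())


def base_template(family: str) -> WaveformTemplate:
    """Bundled normative template for one dof family (synthetic shape)."""
    pts = _TEMPLATE_POINTS[family]
    xp = [p for p, _ in pts] + [100.0 + pts[0][0]]
    fp = [v for _, v in pts] + [pts[0][1]]
    n = 256
    dense = np.interp(np.linspace(0.0, 100.0, n, endpoint=False), xp, fp)
    spec = np.fft.rfft(dense) / n
    a0 = float(spec[0].real)
    a = 2.0 * spec[1 : N_HARMONICS + 1].real
    b = -2.0 * spec[1 : N_HARMONICS + 1].imag
    return WaveformTemplate(name=family, a0=a0, a=np.asarray(a), b=np.asarray(b))


def _affine(template: WaveformTemplate, gain: float, offset: float) -> WaveformTemplate:
    return WaveformTemplate(
        name=template.name,
        a0=offset + gain * template.a0,
        a=gain * template.a,
        b=gain * template.b,
    )


def calibrate_template(
    template: WaveformTemplate, target_max: float, target_min: float
) -> WaveformTemplate:
    """Affine (gain + offset) rescale so the template's extrema hit the targets."""
    if target_max < target_min:
        raise ValueError(
            f"target_max ({target_max}) must be >= target_min ({target_min})"
        )
    omax, omin = template.extrema()
    if omax - omin < 1e-12:
        raise ValueError("cannot calibrate a constant template to a nonzero range")
    gain = (target_max - target_min) / (omax - omin)
    return _affine(template, gain, target_max - gain * omax)


def protocol_extrema(
    template: WaveformTemplate,
    duration: float,
    frame_rate: float,
    smoothing: SmoothingConfig,
) -> tuple[float, float]:
    """Extrema the template reaches after sampling at *frame_rate* and applying
    the analysis smoothing protocol (evaluated on interior cycles)."""
    n_cycles = max(4, int(np.ceil(smoothing.window_frames / frame_rate / duration)) + 3)
    t = np.arange(0.0, n_cycles * duration, 1.0 / frame_rate)
    y = template.evaluate((t / duration) % 1.0)
    if len(y) >= smoothing.window_frames:
        y = savgol_smooth(y, smoothing)
    mask = (t >= duration) & (t <= (n_cycles - 1) * duration)
    return float(y[mask].max()), float(y[mask].min())


def calibrate_template_to_protocol(
    template: WaveformTemplate,
    target_max: float,
    target_min: float,
    duration: float,
    frame_rate: float,
    smoothing: SmoothingConfig,
) -> WaveformTemplate:
    """Affine rescale so the protocol-smoothed curve's extrema hit the targets.

    Peak-angle targets describe measured (smoothed) values; since smoothing is
    linear, aiming the smoothed extrema is still a pure gain/offset on the
    emitted waveform.
    """
    if target_max < target_min:
        raise ValueError(
            f"target_max ({target_max}) must be >= target_min ({target_min})"
        )
    smax, smin = protocol_extrema(template, duration, frame_rate, smoothing)
    if smax - smin < 1e-12:
        raise ValueError("cannot calibrate a constant template to a nonzero range")
    gain = (target_max - target_min) / (smax - smin)
    return _affine(template, gain, target_max - gain * smax)


# ---------------------------------------------------------------------------
# cohort specification and participant draws
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GroupTargets:
    """Group-level mean/SD targets: spatiotemporal parameters and peak angles.

    ``peaks`` maps a side role (``bilateral`` for controls; ``affected`` /
    ``unaffected`` for a patient group) to per-peak (mean, SD) pairs.
    """

    spatiotemporal: dict[str, tuple[float, float]]
    peaks: dict[str, dict[str, tuple[float, float]]]


@dataclass(frozen=True)
class CohortSpec:
    """Everything needed to generate one group's cohort deterministically."""

    group: str
    n_participants: int
    targets: GroupTargets
    trials_per_participant: int = 3
    cycles_per_trial: int = 4
    frame_rate: float = 60.0
    marker_noise_mm: float = 2.0
    cycle_jitter_cv: float = 0.02
    angle_jitter_rel: float = 0.03
    heading_wobble_deg: float = 0.0
    seed: int = 0
    # the peak-angle targets describe measured values, i.e. curves that have
    # been through the standard Savitzky-Golay protocol; waveform calibration
    # therefore aims the protocol-smoothed extrema at the drawn targets
    analysis_smoothing_window: int = 31
    analysis_smoothing_order: int = 3

    # physical truncation bounds for participant draws
    speed_bounds: tuple[float, float] = (0.10, 3.0)
    cadence_bounds: tuple[float, float] = (50.0, 240.0)
    width_bounds_cm: tuple[float, float] = (0.5, 40.0)
    double_support_bounds: tuple[float, float] = (1.0, 70.0)
    asymmetry_bounds: tuple[float, float] = (0.0, 40.0)

    def __post_init__(self) -> None:
        st = self.targets.spatiotemporal
        for name, (_, sd) in st.items():
            if sd < 0:
                raise ValueError(f"negative SD for {name}")
        v, _ = st["gait_speed_m_s"]
        stride, _ = st["stride_length_m"]
        cad, _ = st["cadence_steps_min"]
        implied = stride * cad / 120.0
        if abs(v - implied) / v > 0.10:
            raise ValueError(
                "inconsistent spec: gait speed target "
                f"{v:.3f} m/s vs stride x cadence / 120 = {implied:.3f} m/s (>10% apart)"
            )
        ds_lo, ds_hi = self.double_support_bounds
        s_hi = 0.5 + ds_hi / 200.0
        if not 0.5 < s_hi <= 0.88:
            raise ValueError(
                f"inconsistent spec: double-support bound {ds_hi}% implies stance "
                f"fraction {s_hi:.2f} outside (0.5, 0.88]"
            )
        if self.n_participants < 1:
            raise ValueError("n_participants must be >= 1")


@dataclass
class ParticipantDraw:
    """Ground-truth parameter values drawn for one participant."""

    pid: str
    group: str
    affected_side: str | None  # 'L' | 'R' | None
    speed: float
    cadence: float
    duration: float
    stride: float
    step_width_m: float
    double_support_pct: float
    stance_fraction: float
    asymmetry_pct: float
    step_left: float
    step_right: float
    peak_targets: dict[str, dict[str, float]]  # side 'L'/'R' -> peak name -> value
    templates: dict[str, WaveformTemplate] = field(default_factory=dict)
    # per dof column, the (max, min) the protocol-smoothed curve reaches;
    # these are the measured-space truth values the pipeline should recover
    measured_extrema: dict[str, tuple[float, float]] = field(default_factory=dict)

    def true_parameters(self) -> dict[str, float]:
        return {
            "gait_speed_m_s": self.speed,
            "stride_length_m": self.stride,
            "step_width_cm": 100.0 * self.step_width_m,
            "cadence_steps_min": self.cadence,
            "double_support_pct": self.double_support_pct,
            "step_length_asymmetry_pct": self.asymmetry_pct,
        }


@dataclass
class TrialTruth:
    """Per-trial ground truth: event times and per-cycle knee peaks."""

    heel_strikes: dict[str, np.ndarray]
    toe_offs: dict[str, np.ndarray]
    knee_peaks: dict[str, list[tuple[float, float, float]]]  # side -> (start, end, peak)


@dataclass
class Cohort:
    spec: CohortSpec
    participants: list[ParticipantDraw]
    trials: dict[str, list[tuple[MarkerTrajectorySet, JointAngleSeries, TrialTruth]]]

    def truth_frame(self) -> pd.DataFrame:
        rows = []
        for draw in self.participants:
            for param, value in draw.true_parameters().items():
                rows.append(
                    {
                        "participant": draw.pid,
                        "group": draw.group,
                        "affected_side": draw.affected_side or "",
                        "parameter": param,
                        "true_value": value,
                    }
                )
            for side in ("L", "R"):
                for peak, value in draw.peak_targets[side].items():
                    rows.append(
                        {
                            "participant": draw.pid,
                            "group": draw.group,
                            "affected_side": draw.affected_side or "",
                            "parameter": f"{peak}_{side}",
                            "true_value": value,
                        }
                    )
        return pd.DataFrame(rows)


def stratified_normal(
    n: int,
    mean: float,
    sd: float,
    rng: np.random.Generator,
    lo: float = -np.inf,
    hi: float = np.inf,
) -> np.ndarray:
    """Balanced normal draws: one jittered quantile per stratum, shuffled.

    Marginally each value is N(mean, sd) truncated to [lo, hi]; jointly the
    realized cohort mean and SD track the configured targets far more tightly
    than i.i.d. sampling would.
    """
    if sd == 0.0 or n == 1:
        x = np.full(n, mean)
    else:
        u = (np.arange(n) + rng.uniform(size=n)) / n
        x = mean + sd * ndtri(u)
    x = np.clip(x, lo, hi)
    return x[rng.permutation(n)]


def _draw_participants(spec: CohortSpec, rng: np.random.Generator) -> list[ParticipantDraw]:
    n = spec.n_participants
    st = spec.targets.spatiotemporal
    speed = stratified_normal(n, *st["gait_speed_m_s"], rng, *spec.speed_bounds)
    cad = stratified_normal(n, *st["cadence_steps_min"], rng, *spec.cadence_bounds)
    width = stratified_normal(n, *st["step_width_cm"], rng, *spec.width_bounds_cm) / 100.0
    ds = stratified_normal(n, *st["double_support_pct"], rng, *spec.double_support_bounds)
    asym = stratified_normal(n, *st["step_length_asymmetry_pct"], rng, *spec.asymmetry_bounds)
    asym_sign = rng.choice([-1.0, 1.0], size=n)

    is_patient = set(spec.targets.peaks) != {"bilateral"}
    if is_patient:
        affected = rng.permutation(np.where(np.arange(n) % 2 == 0, "L", "R"))
        role_for = lambda i, side: (  # noqa: E731
            "affected" if side == affected[i] else "unaffected"
        )
    else:
        affected = [None] * n
        role_for = lambda i, side: "bilateral"  # noqa: E731

    # one balanced stream per (role, peak): marginals per side role hit the
    # configured column means/SDs
    peak_draws: dict[tuple[str, str], np.ndarray] = {}
    for role, peaks in spec.targets.peaks.items():
        for peak, (mean, sd) in peaks.items():
            peak_draws[(role, peak)] = stratified_normal(n, mean, sd, rng)
    if not is_patient:
        # independent draws for the second side of a control participant
        for (role, peak), _ in list(peak_draws.items()):
            mean, sd = spec.targets.peaks[role][peak]
            peak_draws[(role + "_2", peak)] = stratified_normal(n, mean, sd, rng)

    draws = []
    base_cache = {fam: base_template(fam) for fam in _TEMPLATE_POINTS}
    for i in range(n):
        duration = 120.0 / cad[i]
        stride = speed[i] * duration
        d = asym[i] / 100.0 * stride / 2.0
        step_l = stride / 2.0 + asym_sign[i] * d / 2.0
        step_r = stride / 2.0 - asym_sign[i] * d / 2.0

        smoothing = SmoothingConfig(spec.analysis_smoothing_window, spec.analysis_smoothing_order)
        peak_targets: dict[str, dict[str, float]] = {}
        templates: dict[str, WaveformTemplate] = {}
        measured_extrema: dict[str, tuple[float, float]] = {}
        for side_idx, side in enumerate(("L", "R")):
            role = role_for(i, side)
            key_role = role if (is_patient or side_idx == 0) else role + "_2"
            side_peaks = {
                peak: float(peak_draws[(key_role, peak)][i])
                for peak in spec.targets.peaks[role]
            }
            peak_targets[side] = side_peaks
            suffix = side.lower()
            for family, (max_name, min_name) in PEAK_FAMILY_PAIRS.items():
                tmax = side_peaks[max_name]
                tmin = min(side_peaks[min_name], tmax - 2.0)
                side_peaks[min_name] = tmin  # keep truth consistent with emission
                templates[f"{family}_{suffix}"] = calibrate_template_to_protocol(
                    base_cache[family], tmax, tmin, duration, spec.frame_rate, smoothing
                )
                measured_extrema[f"{family}_{suffix}"] = (tmax, tmin)
        # one pelvis segment: calibrated once per participant and shared by both
        # sides; for patients its peak targets come from the affected-side draws
        role0 = "affected" if is_patient else "bilateral"
        for family, peak_name in PELVIS_SINGLE_PEAKS.items():
            tmax = float(peak_draws[(role0, peak_name)][i])
            smax, smin = protocol_extrema(
                base_cache[family], duration, spec.frame_rate, smoothing
            )
            tmin = tmax - (smax - smin)  # native excursion preserved
            templates[family] = calibrate_template_to_protocol(
                base_cache[family], tmax, tmin, duration, spec.frame_rate, smoothing
            )
            measured_extrema[family] = (tmax, tmin)
            # pelvis is one physical segment: both sides see the same emitted
            # peak, so the stored truth reflects the emission
            for side in ("L", "R"):
                peak_targets[side][peak_name] = tmax

        draws.append(
            ParticipantDraw(
                pid=f"{spec.group}{i + 1:03d}",
                group=spec.group,
                affected_side=(affected[i] if is_patient else None),
                speed=float(speed[i]),
                cadence=float(cad[i]),
                duration=float(duration),
                stride=float(stride),
                step_width_m=float(width[i]),
                double_support_pct=float(ds[i]),
                stance_fraction=float(0.5 + ds[i] / 200.0),
                asymmetry_pct=float(asym[i]),
                step_left=float(step_l),
                step_right=float(step_r),
                peak_targets=peak_targets,
                templates=templates,
                measured_extrema=measured_extrema,
            )
        )
    return draws


# ---------------------------------------------------------------------------
# marker-profile primitives (phase in [0, 1), heights in metres)
# ---------------------------------------------------------------------------

HEEL_PLATEAU_M = 0.025  # heel-marker height in foot-flat
HEEL_BUMP_M = 0.18  # swing peak of the heel marker
HEEL_DIP_HALFWIDTH = 0.10  # phase half-width of the symmetric contact dip
TOE_BASE_M = 0.010
TOE_BUMP_M = 0.12
TOE_RISE_HALFWIDTH = 0.05  # phase half-width of the symmetric-velocity rise
TOE_FORWARD_OFFSET_M = 0.18
PELVIS_HEIGHT_M = 0.95


def _heel_height(phi: np.ndarray, stance_fraction: float) -> np.ndarray:
    """Heel-marker height: symmetric dip to 0 at contact, foot-flat plateau,
    swing bump after heel-off."""
    w = HEEL_DIP_HALFWIDTH
    s_h = max(0.15 + w, stance_fraction - 0.28)  # heel-off phase
    pk = 0.5 * (s_h + 1.0 - w)
    p, a = HEEL_PLATEAU_M, HEEL_BUMP_M
    phi = np.asarray(phi) % 1.0
    out = np.full_like(phi, p)
    m = phi < w
    out[m] = p * (1.0 - np.cos(np.pi * phi[m] / w)) / 2.0
    m = (phi >= s_h) & (phi < pk)
    u = (phi[m] - s_h) / (pk - s_h)
    out[m] = p + (a - p) * (1.0 - np.cos(np.pi * u)) / 2.0
    m = (phi >= pk) & (phi < 1.0 - w)
    u = (phi[m] - pk) / (1.0 - w - pk)
    out[m] = p + (a - p) * (1.0 + np.cos(np.pi * u)) / 2.0
    m = phi >= 1.0 - w
    out[m] = p * (1.0 - np.cos(np.pi * (phi[m] - 1.0) / w)) / 2.0
    return out


def _toe_height(phi: np.ndarray, stance_fraction: float) -> np.ndarray:
    """Toe-marker height: flat until toe-off, S-curve rise whose velocity peaks
    exactly at the toe-off phase, a short hold near peak clearance (keeping the
    velocity profile locally symmetric about toe-off), then a smooth descent."""
    w = TOE_RISE_HALFWIDTH
    s = stance_fraction
    b, a = TOE_BASE_M, TOE_BUMP_M
    hold = float(np.clip((1.0 - s - w) / 2.0 - 0.02, 0.0, 0.10))
    fall_start = s + w + hold
    phi = np.asarray(phi) % 1.0
    out = np.full_like(phi, b)
    m = (phi >= s - w) & (phi < s + w)
    u = (phi[m] - (s - w)) / (2.0 * w)
    out[m] = b + (a - b) * (1.0 - np.cos(np.pi * u)) / 2.0
    m = (phi >= s + w) & (phi < fall_start)
    out[m] = a
    m = phi >= fall_start
    u = (phi[m] - fall_start) / (1.0 - fall_start)
    out[m] = a + (b - a) * (1.0 - np.cos(np.pi * u)) / 2.0
    return out


def _advance(phi: np.ndarray, stance_fraction: float) -> np.ndarray:
    """Forward progression of a foot within its cycle: hold in stance, smooth
    unit step during swing (the foot lands exactly one stride ahead)."""
    phi = np.asarray(phi) % 1.0
    out = np.zeros_like(phi)
    m = phi >= stance_fraction
    u = (phi[m] - stance_fraction) / (1.0 - stance_fraction)
    out[m] = (1.0 - np.cos(np.pi * u)) / 2.0
    return out


def _phase_and_index(t: np.ndarray, knots: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    idx = np.clip(np.searchsorted(knots, t, side="right") - 1, 0, len(knots) - 2)
    phi = (t - knots[idx]) / (knots[idx + 1] - knots[idx])
    return phi, idx


def synth_trial(
    draw: ParticipantDraw, spec: CohortSpec, rng: np.random.Generator
) -> tuple[MarkerTrajectorySet, JointAngleSeries, TrialTruth]:
    """One walking trial: TRC markers, MOT joint angles, and its ground truth."""
    fs = spec.frame_rate
    n_c = spec.cycles_per_trial
    d_mean = draw.duration
    s = draw.stance_fraction

    jitter = np.clip(rng.normal(0.0, spec.cycle_jitter_cv, size=n_c), -3 * spec.cycle_jitter_cv, 3 * spec.cycle_jitter_cv)
    durations = d_mean * (1.0 + jitter)
    lead = tail = 0.8 * d_mean

    # left heel-strike knots with one virtual cycle on each end
    hs_left = lead + np.concatenate([[0.0], np.cumsum(durations)])
    l_knots = np.concatenate([[hs_left[0] - d_mean], hs_left, [hs_left[-1] + d_mean]])
    l_pos = (np.arange(len(l_knots)) - 1.0) * draw.stride
    # right strikes at mid-cycle, one stride apart, step_right ahead of the
    # preceding left strike position
    r_core = 0.5 * (l_knots[:-1] + l_knots[1:])
    r_knots = np.concatenate([[r_core[0] - d_mean], r_core, [r_core[-1] + d_mean]])
    r_pos = np.concatenate([[l_pos[0] - draw.stride], l_pos[:-1]]) + draw.step_right

    t_end = hs_left[-1] + tail
    t = np.arange(int(np.floor(t_end * fs)) + 1) / fs

    phi_l, idx_l = _phase_and_index(t, l_knots)
    phi_r, idx_r = _phase_and_index(t, r_knots)

    half_w = draw.step_width_m / 2.0
    heel_l = np.column_stack(
        [l_pos[idx_l] + draw.stride * _advance(phi_l, s), _heel_height(phi_l, s), np.full_like(t, half_w)]
    )
    heel_r = np.column_stack(
        [r_pos[idx_r] + draw.stride * _advance(phi_r, s), _heel_height(phi_r, s), np.full_like(t, -half_w)]
    )
    toe_l = np.column_stack(
        [
            l_pos[idx_l] + TOE_FORWARD_OFFSET_M + draw.stride * _advance(phi_l, s),
            _toe_height(phi_l, s),
            np.full_like(t, half_w),
        ]
    )
    toe_r = np.column_stack(
        [
            r_pos[idx_r] + TOE_FORWARD_OFFSET_M + draw.stride * _advance(phi_r, s),
            _toe_height(phi_r, s),
            np.full_like(t, -half_w),
        ]
    )
    pelvis = np.column_stack(
        [
            np.interp(t, l_knots, l_pos),
            PELVIS_HEIGHT_M + 0.025 * np.sin(4.0 * np.pi * phi_l),
            0.02 * np.sin(2.0 * np.pi * phi_l),
        ]
    )

    positions = np.stack([pelvis, heel_l, heel_r, toe_l, toe_r], axis=1)
    if spec.heading_wobble_deg:
        theta = np.deg2rad(rng.normal(0.0, spec.heading_wobble_deg))
        c, si = np.cos(theta), np.sin(theta)
        x, z = positions[..., 0].copy(), positions[..., 2].copy()
        positions[..., 0] = c * x - si * z
        positions[..., 2] = si * x + c * z
    if spec.marker_noise_mm > 0:
        positions = positions + rng.normal(0.0, spec.marker_noise_mm / 1000.0, positions.shape)

    markers = MarkerTrajectorySet(
        frame_rate=fs,
        units="mm",
        marker_names=["pelvis", "L_heel", "R_heel", "L_toe", "R_toe"],
        time=t,
        positions=positions * 1000.0,
    )

    # joint angles: calibrated templates on each side's phase, with per-cycle
    # amplitude jitter about the template midpoint
    eta_l = rng.normal(0.0, spec.angle_jitter_rel, size=len(l_knots) - 1)
    eta_r = rng.normal(0.0, spec.angle_jitter_rel, size=len(r_knots) - 1)
    dof_names: list[str] = list(PELVIS_SINGLE_PEAKS)
    angle_cols = []
    for family in PELVIS_SINGLE_PEAKS:
        tpl = draw.templates[family]
        tmax, tmin = draw.measured_extrema[family]
        mid = 0.5 * (tmax + tmin)
        angle_cols.append(mid + (1.0 + eta_l[idx_l]) * (tpl.evaluate(phi_l) - mid))
    for family in PEAK_FAMILY_PAIRS:
        for side, phi, idx, eta in (("l", phi_l, idx_l, eta_l), ("r", phi_r, idx_r, eta_r)):
            tpl = draw.templates[f"{family}_{side}"]
            tmax, tmin = draw.measured_extrema[f"{family}_{side}"]
            mid = 0.5 * (tmax + tmin)
            dof_names.append(f"{family}_{side}")
            angle_cols.append(mid + (1.0 + eta[idx]) * (tpl.evaluate(phi) - mid))
    angles = JointAngleSeries(
        frame_rate=fs, time=t, dof_names=dof_names, angles=np.column_stack(angle_cols)
    )

    # an event right at the recording edge is not fully observable: the signal
    # support that identifies it (the following swing excursion) is truncated;
    # the truth table lists only events whose evidence lies within the trial
    t_obs_lo = 0.15 * d_mean
    t_obs_hi = t[-1] - 0.45 * d_mean

    def _events(knots: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        hs = knots[(knots >= t_obs_lo) & (knots <= t_obs_hi)]
        to = knots[:-1] + s * np.diff(knots)
        to = to[(to >= t_obs_lo) & (to <= t_obs_hi)]
        return hs, to

    hs_l_truth, to_l_truth = _events(l_knots)
    hs_r_truth, to_r_truth = _events(r_knots)

    # per-cycle knee-peak truth: the measured (protocol-smoothed) peak depends
    # on the cycle's actual jittered duration, so recompute the smoothed
    # extrema of the emitted template at each cycle's duration
    smoothing = SmoothingConfig(spec.analysis_smoothing_window, spec.analysis_smoothing_order)
    knee_peaks: dict[str, list[tuple[float, float, float]]] = {"L": [], "R": []}
    for side, knots, eta in (("L", l_knots, eta_l), ("R", r_knots, eta_r)):
        tpl = draw.templates[f"knee_angle_{side.lower()}"]
        tmax, tmin = draw.measured_extrema[f"knee_angle_{side.lower()}"]
        mid = 0.5 * (tmax + tmin)
        for k in range(len(knots) - 1):
            start, end = knots[k], knots[k + 1]
            if start >= 0.0 and end <= t[-1]:
                smax_k, _ = protocol_extrema(tpl, float(end - start), fs, smoothing)
                knee_peaks[side].append(
                    (float(start), float(end), float(mid + (1.0 + eta[k]) * (smax_k - mid)))
                )

    truth = TrialTruth(
        heel_strikes={"L": hs_l_truth, "R": hs_r_truth},
        toe_offs={"L": to_l_truth, "R": to_r_truth},
        knee_peaks=knee_peaks,
    )
    return markers, angles, truth


def generate_cohort(spec: CohortSpec) -> Cohort:
    """Deterministically generate all participants and trials of one group."""
    rng = np.random.default_rng(spec.seed)
    draws = _draw_participants(spec, rng)
    trials = {
        draw.pid: [synth_trial(draw, spec, rng) for _ in range(spec.trials_per_participant)]
        for draw in draws
    }
    return Cohort(spec=spec, participants=draws, trials=trials)


def write_cohort(cohort: Cohort, outdir: str | Path) -> None:
    """Write a cohort as TRC/MOT pairs plus truth.csv, events_truth.csv, manifest.csv."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest_rows, event_rows = [], []
    for draw in cohort.participants:
        for k, (markers, angles, truth) in enumerate(cohort.trials[draw.pid], start=1):
            stem = f"{draw.pid}_T{k:02d}"
            write_trc(markers, outdir / f"{stem}.trc")
            write_mot(angles, outdir / f"{stem}.mot")
            manifest_rows.append(
                {
                    "participant": draw.pid,
                    "group": draw.group,
                    "affected_side": draw.affected_side or "",
                    "trial": stem,
                }
            )
            for foot in ("L", "R"):
                for ev_type, times in (
                    ("heel_strike", truth.heel_strikes[foot]),
                    ("toe_off", truth.toe_offs[foot]),
                ):
                    event_rows.extend(
                        {"trial": stem, "foot": foot, "event_type": ev_type, "time_s": float(tt)}
                        for tt in times
                    )
    pd.DataFrame(manifest_rows).to_csv(outdir / "manifest.csv", index=False)
    pd.DataFrame(event_rows).to_csv(outdir / "events_truth.csv", index=False)
    cohort.truth_frame().to_csv(outdir / "truth.csv", index=False)


def control_cohort_spec(n: int = 78, seed: int = 0, **kwargs) -> CohortSpec:
    """Control-group spec parameterized from the published control column."""
    return CohortSpec(
        group="CTRL",
        n_participants=n,
        targets=GroupTargets(
            spatiotemporal=dict(CONTROL_SPATIOTEMPORAL), peaks={"bilateral": dict(CONTROL_PEAKS)}
        ),
        seed=seed,
        **kwargs,
    )


def koa_cohort_spec(n: int = 33, seed: int = 1, **kwargs) -> CohortSpec:
    """KOA-group spec parameterized from the published experimental columns."""
    return CohortSpec(
        group="KOA",
        n_participants=n,
        targets=GroupTargets(
            spatiotemporal=dict(KOA_SPATIOTEMPORAL),
            peaks={
                "affected": dict(KOA_AFFECTED_PEAKS),
                "unaffected": dict(KOA_UNAFFECTED_PEAKS),
            },
        ),
        seed=seed,
        **kwargs,
    )
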