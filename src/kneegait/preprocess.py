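"""Signal conditioning shared by every pipeline stage.

Four primitives: Savitzky-Golay smoothing (the low-pass filter applied to
marker trajectories and kinematic curves), linear gap filling for short marker
drop-outs, time normalization of a single gait cycle onto a 0-100 % grid, and
the pooled +/-3 SD outlier rule used before participant averaging.

Defaults follow the processing protocol of the study this package reproduces:
a 31-frame window (nearest odd value to the protocol's 30 frames — the classic
Savitzky-Golay filter needs an odd window), cubic polynomial order, 101 grid
points so that cycle percentages are integral, and k = 3 for the outlier rule.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.signal import savgol_filter

__all__ = [
    "SmoothingConfig",
    "NormalizedCurve",
    "GapReport",
    "savgol_smooth",
    "fill_gaps",
    "time_normalize",
    "outlier_mask",
    "PERCENT_GRID",
    "N_GRID",
]

log = logging.getLogger("kneegait")

N_GRID = 101
PERCENT_GRID = np.linspace(0.0, 100.0, N_GRID)


@dataclass(frozen=True)
class SmoothingConfig:
    """Savitzky-Golay window (odd frame count) and polynomial order."""

    window_frames: int = 31
    poly_order: int = 3

    def __post_init__(self) -> None:
        if self.window_frames % 2 == 0:
            # even windows are accepted for convenience but rounded up; the
            # effective (odd) window is what the filter actually uses
            object.__setattr__(self, "window_frames", self.window_frames + 1)
            log.info(
                "smoothing: even window requested, using effective window %d",
                self.window_frames,
            )
        if self.window_frames <= self.poly_order:
            raise ValueError(
                f"window_frames ({self.window_frames}) must exceed poly_order "
                f"({self.poly_order})"
            )


@dataclass
class NormalizedCurve:
    """One kinematic quantity resampled onto the 0-100 % gait-cycle grid."""

    values: np.ndarray  # length 101

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (N_GRID,):
            raise ValueError(f"normalized curve must have {N_GRID} points, got {self.values.shape}")

    @property
    def grid(self) -> np.ndarray:
        return PERCENT_GRID


@dataclass
class GapReport:
    """Interior gaps found by :func:`fill_gaps`: (start_index, length, filled)."""

    gaps: list[tuple[int, int, bool]]

    @property
    def unfilled(self) -> list[tuple[int, int]]:
        return [(s, n) for s, n, filled in self.gaps if not filled]


def savgol_smooth(series: np.ndarray, cfg: SmoothingConfig = SmoothingConfig()) -> np.ndarray:
    """Savitzky-Golay smooth a 1-D series (edges by truncated-window poly fit).

    The series must be gap-free; interpolate with :func:`fill_gaps` first.
    """
    x = np.asarray(series, dtype=float)
    if x.ndim != 1:
        raise ValueError("savgol_smooth expects a 1-D series")
    if len(x) < cfg.window_frames:
        raise ValueError(
            f"series of length {len(x)} is shorter than the smoothing window "
            f"({cfg.window_frames}); use a smaller window"
        )
    if not np.all(np.isfinite(x)):
        raise ValueError("series contains missing values; run fill_gaps first")
    return savgol_filter(x, cfg.window_frames, cfg.poly_order, mode="interp")


def fill_gaps(series: np.ndarray, max_gap: int) -> tuple[np.ndarray, GapReport]:
    """Linearly interpolate interior NaN runs of length <= *max_gap* frames.

    Longer runs — and leading/trailing runs, which have no second anchor and
    are never extrapolated — are left missing and reported.
    """
    x = np.asarray(series, dtype=float).copy()
    isnan = ~np.isfinite(x)
    gaps: list[tuple[int, int, bool]] = []
    if not isnan.any():
        return x, GapReport(gaps)

    n = len(x)
    i = 0
    while i < n:
        if not isnan[i]:
            i += 1
            continue
        j = i
        while j < n and isnan[j]:
            j += 1
        length = j - i
        interior = i > 0 and j < n
        fill = interior and length <= max_gap
        if fill:
            x[i:j] = np.interp(np.arange(i, j), [i - 1, j], [x[i - 1], x[j]])
        else:
            log.info("fill_gaps: leaving gap at %d (length %d) unfilled", i, length)
        gaps.append((i, length, fill))
        i = j
    return x, GapReport(gaps)


def time_normalize(curve: np.ndarray, n_points: int = N_GRID) -> NormalizedCurve:
    """Resample one cycle's samples onto an even 0-100 % grid by linear interpolation."""
    y = np.asarray(curve, dtype=float)
    if y.ndim != 1 or len(y) < 2:
        raise ValueError("time_normalize needs at least 2 samples")
    src = np.linspace(0.0, 1.0, len(y))
    dst = np.linspace(0.0, 1.0, n_points)
    return NormalizedCurve(np.interp(dst, src, y))


def outlier_mask(values: np.ndarray, k: float = 3.0) -> np.ndarray:
    """Keep/reject flags for the pooled mean +/- k*SD rule (single pass).

    Returns a boolean array, True = keep.  Mean and SD are computed once on
    the full pooled input; the rule is not iterated.  All-equal inputs keep
    everything.
    """
    x = np.asarray(values, dtype=float)
    if x.ndim != 1 or len(x) < 3:
        raise ValueError("outlier_mask needs at least 3 pooled values")
    if not np.all(np.isfinite(x)):
        raise ValueError("outlier_mask expects finite values")
    mu = x.mean()
    sd = x.std(ddof=1)
    if sd == 0.0:
        return np.ones(len(x), dtype=bool)
    return np.abs(x - mu) <= k * sd
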