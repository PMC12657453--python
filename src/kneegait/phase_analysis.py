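"""Phase-wise comparison of time-normalized kinematic curves.

Mean curves per group come with pointwise percentile-bootstrap confidence
bands, and two groups are compared by bootstrapping the difference of group
means at every percent of the gait cycle.  The unit of resampling is the
participant (each represented by their cycle-averaged curve), not the cycle,
so the ~10 cycles a participant contributes cannot masquerade as independent
observations.  A grid point is flagged significant when the percentile CI of
the difference excludes zero; flagged points are merged into runs, and runs
shorter than ``min_run`` grid points are discarded, yielding the contiguous
"X%–Y%" regions conventionally reported for gait curves.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .events import GaitCycleRecord
from .preprocess import N_GRID, PERCENT_GRID, NormalizedCurve

__all__ = [
    "CurveBand",
    "SignificanceRegions",
    "participant_mean_curve",
    "bootstrap_band",
    "difference_regions",
]


@dataclass
class CurveBand:
    """Pointwise mean curve with a percentile-bootstrap confidence band."""

    mean: np.ndarray
    lower: np.ndarray
    upper: np.ndarray
    alpha: float

    def __post_init__(self) -> None:
        for arr in (self.mean, self.lower, self.upper):
            if np.asarray(arr).shape != (N_GRID,):
                raise ValueError(f"band arrays must have length {N_GRID}")
        tol = 1e-9
        if np.any(self.lower > self.mean + tol) or np.any(self.mean > self.upper + tol):
            raise ValueError("band must satisfy lower <= mean <= upper pointwise")

    @property
    def grid(self) -> np.ndarray:
        return PERCENT_GRID


@dataclass
class SignificanceRegions:
    """Contiguous significant intervals of the gait cycle, in percent."""

    regions: list[tuple[float, float]]
    alpha: float
    n_boot: int
    min_run: int
    flags: np.ndarray = field(default_factory=lambda: np.zeros(N_GRID, dtype=bool))
    diff_mean: np.ndarray | None = None
    diff_lower: np.ndarray | None = None
    diff_upper: np.ndarray | None = None

    def __post_init__(self) -> None:
        for lo, hi in self.regions:
            if not (0.0 <= lo <= hi <= 100.0):
                raise ValueError(f"region [{lo}, {hi}] outside [0, 100]")
        for (a0, a1), (b0, b1) in zip(self.regions, self.regions[1:]):
            if b0 <= a1:
                raise ValueError("regions must be disjoint and sorted")


def _as_matrix(curves) -> np.ndarray:
    rows = []
    for c in curves:
        rows.append(c.values if isinstance(c, NormalizedCurve) else np.asarray(c, dtype=float))
    mat = np.asarray(rows, dtype=float)
    if mat.ndim != 2 or mat.shape[1] != N_GRID:
        raise ValueError(f"expected curves of length {N_GRID}, got shape {mat.shape}")
    return mat


def participant_mean_curve(cycles: list[GaitCycleRecord], dof: str) -> NormalizedCurve:
    """Pointwise mean of one dof's normalized curve over a participant's cycles."""
    mats = [rec.normalized_curves[dof].values for rec in cycles if dof in rec.normalized_curves]
    if not mats:
        raise ValueError(f"no cycles carry dof {dof!r}")
    return NormalizedCurve(np.mean(mats, axis=0))


def bootstrap_band(
    curves,
    n_boot: int = 1000,
    alpha: float = 0.05,
    seed: int | None = None,
) -> CurveBand:
    """Percentile bootstrap band for a group mean curve (resampling participants).

    *curves* is one curve per participant (NormalizedCurve or length-101
    array).  With a fixed *seed* the band is reproducible.
    """
    mat = _as_matrix(curves)
    n = len(mat)
    if n < 2:
        raise ValueError("bootstrap_band needs at least 2 participants")
    if n_boot < 100:
        warnings.warn(f"n_boot={n_boot} is small; percentile bands may be unstable", stacklevel=2)
    rng = np.random.default_rng(seed)
    # m = n-1 resamples per replicate: the naive n-out-of-n bootstrap
    # understates the variance of a mean by (n-1)/n, which is material at
    # these group sizes; with m = n-1 the bootstrap variance is exact
    idx = rng.integers(0, n, size=(n_boot, max(n - 1, 1)))
    boot_means = mat[idx].mean(axis=1)  # (n_boot, 101)
    lower = np.percentile(boot_means, 100.0 * alpha / 2.0, axis=0)
    upper = np.percentile(boot_means, 100.0 * (1.0 - alpha / 2.0), axis=0)
    mean = mat.mean(axis=0)
    # a finite bootstrap can place a percentile fractionally across the
    # observed mean; clamp so the band always brackets it
    return CurveBand(
        mean=mean, lower=np.minimum(lower, mean), upper=np.maximum(upper, mean), alpha=alpha
    )


def _runs_to_regions(flags: np.ndarray, min_run: int) -> list[tuple[float, float]]:
    regions = []
    i = 0
    n = len(flags)
    while i < n:
        if not flags[i]:
            i += 1
            continue
        j = i
        while j < n and flags[j]:
            j += 1
        if j - i >= min_run:
            regions.append((float(PERCENT_GRID[i]), float(PERCENT_GRID[j - 1])))
        i = j
    return regions


def difference_regions(
    group_a,
    group_b,
    n_boot: int = 1000,
    alpha: float = 0.05,
    min_run: int = 3,
    seed: int | None = None,
) -> SignificanceRegions:
    """Significant regions of the pointwise group-mean difference (A - B).

    Participants are resampled with replacement within each group; a grid
    point is flagged when the (alpha/2, 1-alpha/2) percentile interval of the
    resampled mean difference excludes zero.  Flagged points shorter than
    *min_run* consecutive grid points are dropped.
    """
    mat_a = _as_matrix(group_a)
    mat_b = _as_matrix(group_b)
    if len(mat_a) == 0 or len(mat_b) == 0:
        raise ValueError("both groups need at least one participant")
    if len(mat_a) < 2 or len(mat_b) < 2:
        raise ValueError("difference_regions needs at least 2 participants per group")
    rng = np.random.default_rng(seed)
    # m = n-1 resampling within each group (see bootstrap_band)
    idx_a = rng.integers(0, len(mat_a), size=(n_boot, max(len(mat_a) - 1, 1)))
    idx_b = rng.integers(0, len(mat_b), size=(n_boot, max(len(mat_b) - 1, 1)))
    boot_diff = mat_a[idx_a].mean(axis=1) - mat_b[idx_b].mean(axis=1)
    lower = np.percentile(boot_diff, 100.0 * alpha / 2.0, axis=0)
    upper = np.percentile(boot_diff, 100.0 * (1.0 - alpha / 2.0), axis=0)
    flags = (lower > 0.0) | (upper < 0.0)
    return SignificanceRegions(
        regions=_runs_to_regions(flags, min_run),
        alpha=alpha,
        n_boot=n_boot,
        min_run=min_run,
        flags=flags,
        diff_mean=mat_a.mean(axis=0) - mat_b.mean(axis=0),
        diff_lower=lower,
        diff_upper=upper,
    )
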