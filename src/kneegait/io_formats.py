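"""Readers and writers for the OpenSim-style TRC and MOT text formats.

TRC carries time-stamped 3-D marker trajectories (tab-delimited, five header
lines, blank cells for occluded samples); MOT carries generalized-coordinate
(joint-angle) time series with a free-form header block terminated by the
literal line ``endheader``.  These are the files an OpenCap session leaves
behind after triangulation and inverse kinematics; everything downstream in
this package consumes the two container types defined here.

Coordinate convention: OpenSim's default lab frame, with Y vertical and the
walking plane spanned by X and Z (configurable downstream via the
``vertical_axis`` key).  The reader performs no unit rescaling — it stores the
declared unit tag and :func:`to_metres` is the single conversion point.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

__all__ = [
    "FormatError",
    "MarkerTrajectorySet",
    "JointAngleSeries",
    "read_trc",
    "write_trc",
    "read_mot",
    "write_mot",
    "to_metres",
]


class FormatError(ValueError):
    """Raised when a TRC/MOT file violates the expected layout."""


# ---------------------------------------------------------------------------
# container types
# ---------------------------------------------------------------------------

@dataclass
class MarkerTrajectorySet:
    """Time-stamped 3-D positions for named markers at a fixed frame rate.

    ``positions`` has shape ``(T, n_markers, 3)``; missing (occluded) samples
    are NaN.  ``units`` is the declared length unit tag (``mm`` or ``m``).
    """

    frame_rate: float
    units: str
    marker_names: list[str]
    time: np.ndarray
    positions: np.ndarray

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.positions = np.asarray(self.positions, dtype=float)
        self.validate()

    def validate(self) -> None:
        if self.units not in ("mm", "m"):
            raise FormatError(f"unsupported units tag {self.units!r} (expected 'mm' or 'm')")
        if self.time.ndim != 1:
            raise FormatError("time must be a 1-D array")
        t = self.time
        if len(t) >= 2 and not np.all(np.diff(t) > 0):
            raise FormatError("time must be strictly increasing")
        if self.positions.shape != (len(t), len(self.marker_names), 3):
            raise FormatError(
                f"positions shape {self.positions.shape} does not match "
                f"(T={len(t)}, markers={len(self.marker_names)}, 3)"
            )
        if len(set(self.marker_names)) != len(self.marker_names):
            raise FormatError("marker names must be unique")
        if len(t) >= 2:
            span_frames = (t[-1] - t[0]) * self.frame_rate
            if abs(span_frames - (len(t) - 1)) > 0.5:
                raise FormatError(
                    "time span inconsistent with frame rate: "
                    f"{span_frames:.2f} frames spanned by {len(t)} samples"
                )

    def marker(self, name: str) -> np.ndarray:
        """Return the (T, 3) trajectory of one marker."""
        try:
            idx = self.marker_names.index(name)
        except ValueError:
            raise KeyError(f"marker {name!r} not in set {self.marker_names}") from None
        return self.positions[:, idx, :]

    def copy(self) -> "MarkerTrajectorySet":
        return replace(
            self,
            marker_names=list(self.marker_names),
            time=self.time.copy(),
            positions=self.positions.copy(),
        )


@dataclass
class JointAngleSeries:
    """Time-stamped joint angles in degrees for named degrees of freedom."""

    frame_rate: float
    time: np.ndarray
    dof_names: list[str]
    angles: np.ndarray  # (T, n_dofs), degrees

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.angles = np.asarray(self.angles, dtype=float)
        self.validate()

    def validate(self) -> None:
        if len(self.time) >= 2 and not np.all(np.diff(self.time) > 0):
            raise FormatError("time must be strictly increasing")
        if len(set(self.dof_names)) != len(self.dof_names):
            raise FormatError("dof names must be unique")
        if self.angles.shape != (len(self.time), len(self.dof_names)):
            raise FormatError(
                f"angle array shape {self.angles.shape} does not match "
                f"(T={len(self.time)}, dofs={len(self.dof_names)})"
            )
        if not np.all(np.isfinite(self.angles)):
            raise FormatError("joint angles must be finite")

    def dof(self, name: str) -> np.ndarray:
        try:
            idx = self.dof_names.index(name)
        except ValueError:
            raise KeyError(f"dof {name!r} not in series {self.dof_names}") from None
        return self.angles[:, idx]

    def copy(self) -> "JointAngleSeries":
        return replace(
            self, dof_names=list(self.dof_names), time=self.time.copy(), angles=self.angles.copy()
        )


def to_metres(markers: MarkerTrajectorySet) -> MarkerTrajectorySet:
    """Return a copy of *markers* expressed in metres (single conversion point)."""
    out = markers.copy()
    if out.units == "mm":
        out.positions = out.positions / 1000.0
        out.units = "m"
    return out


# ---------------------------------------------------------------------------
# TRC
# ---------------------------------------------------------------------------

def read_trc(path: str | Path) -> MarkerTrajectorySet:
    """Read an OpenSim TRC marker file.

    Layout: path line; field-name line; field-value line (DataRate, Units,
    NumMarkers...); marker-name line (``Frame#``, ``Time``, then one name per
    marker, padded by two empty cells each); ``X1/Y1/Z1`` subheader; data rows.
    Blank coordinate cells are read as missing (NaN).
    """
    path = Path(path)
    lines = path.read_text().splitlines()
    if len(lines) < 6:
        raise FormatError(f"{path}: too short to be a TRC file ({len(lines)} lines)")

    fields = lines[1].rstrip("\n").split("\t")
    values = lines[2].rstrip("\n").split("\t")
    if "DataRate" not in fields or "Units" not in fields:
        raise FormatError(f"{path}: line 2 must declare DataRate and Units, got: {lines[1]!r}")
    meta = dict(zip(fields, values))
    try:
        frame_rate = float(meta["DataRate"])
    except (KeyError, ValueError):
        raise FormatError(f"{path}: line 3 has no numeric DataRate value: {lines[2]!r}") from None
    units = meta.get("Units", "").strip()

    name_cells = lines[3].rstrip("\n").split("\t")
    if len(name_cells) < 3 or name_cells[0] != "Frame#":
        raise FormatError(f"{path}: line 4 must start with 'Frame#\\tTime', got: {lines[3]!r}")
    marker_names = [c.strip() for c in name_cells[2:] if c.strip()]
    if not marker_names:
        raise FormatError(f"{path}: no marker names on line 4")

    n_cols = 2 + 3 * len(marker_names)
    time, rows = [], []
    for lineno, line in enumerate(lines[5:], start=6):
        if not line.strip():
            continue
        cells = line.rstrip("\n").split("\t")
        if len(cells) < n_cols:
            cells = cells + [""] * (n_cols - len(cells))
        elif len(cells) > n_cols:
            raise FormatError(
                f"{path}:{lineno}: {len(cells)} columns, expected {n_cols} "
                f"(2 + 3 x {len(marker_names)} markers)"
            )
        try:
            time.append(float(cells[1]))
        except ValueError:
            raise FormatError(f"{path}:{lineno}: non-numeric Time cell {cells[1]!r}") from None
        row = np.full(3 * len(marker_names), np.nan)
        for j, cell in enumerate(cells[2:]):
            cell = cell.strip()
            if cell:
                try:
                    row[j] = float(cell)
                except ValueError:
                    raise FormatError(
                        f"{path}:{lineno}: non-numeric coordinate {cell!r} in column {j + 3}"
                    ) from None
        rows.append(row)
    if not rows:
        raise FormatError(f"{path}: no data rows")

    positions = np.asarray(rows).reshape(len(rows), len(marker_names), 3)
    return MarkerTrajectorySet(
        frame_rate=frame_rate,
        units=units,
        marker_names=marker_names,
        time=np.asarray(time),
        positions=positions,
    )


def write_trc(markers: MarkerTrajectorySet, path: str | Path) -> None:
    """Write *markers* as a TRC file re-readable by :func:`read_trc`."""
    markers.validate()
    path = Path(path)
    n_frames, n_markers = len(markers.time), len(markers.marker_names)
    header = [
        f"PathFileType\t4\t(X/Y/Z)\t{path.name}",
        "DataRate\tCameraRate\tNumFrames\tNumMarkers\tUnits\tOrigDataRate\tOrigDataStartFrame\tOrigNumFrames",
        f"{markers.frame_rate:g}\t{markers.frame_rate:g}\t{n_frames}\t{n_markers}\t"
        f"{markers.units}\t{markers.frame_rate:g}\t1\t{n_frames}",
        "Frame#\tTime\t" + "\t\t\t".join(markers.marker_names) + "\t\t",
        "\t\t" + "\t".join(f"X{i + 1}\tY{i + 1}\tZ{i + 1}" for i in range(n_markers)),
    ]
    rows = []
    flat = markers.positions.reshape(n_frames, -1)
    for i in range(n_frames):
        cells = [str(i + 1), f"{markers.time[i]:.8f}"]
        cells += ["" if not np.isfinite(v) else f"{v:.8f}" for v in flat[i]]
        rows.append("\t".join(cells))
    path.write_text("\n".join(header + rows) + "\n")


# ---------------------------------------------------------------------------
# MOT
# ---------------------------------------------------------------------------

def read_mot(path: str | Path) -> JointAngleSeries:
    """Read an OpenSim MOT joint-angle file (header ends at ``endheader``)."""
    path = Path(path)
    lines = path.read_text().splitlines()
    try:
        end = next(i for i, ln in enumerate(lines) if ln.strip() == "endheader")
    except StopIteration:
        raise FormatError(f"{path}: missing 'endheader' line") from None

    col_line = None
    for i in range(end + 1, len(lines)):
        if lines[i].strip():
            col_line = i
            break
    if col_line is None:
        raise FormatError(f"{path}: no column-header line after endheader")
    columns = lines[col_line].rstrip("\n").split("\t")
    columns = [c.strip() for c in columns if c.strip()]
    if not columns or columns[0] != "time":
        raise FormatError(f"{path}: first data column must be 'time', got {columns[:1]}")
    dof_names = columns[1:]

    time, rows = [], []
    for lineno, line in enumerate(lines[col_line + 1 :], start=col_line + 2):
        if not line.strip():
            continue
        cells = line.split("\t")
        cells = [c for c in (c.strip() for c in cells) if c != ""]
        if len(cells) != len(columns):
            raise FormatError(
                f"{path}:{lineno}: {len(cells)} cells, expected {len(columns)}"
            )
        vals = []
        for j, cell in enumerate(cells):
            try:
                vals.append(float(cell))
            except ValueError:
                raise FormatError(
                    f"{path}:{lineno}: non-numeric cell {cell!r} in column {j + 1} "
                    f"({columns[j]})"
                ) from None
        time.append(vals[0])
        rows.append(vals[1:])
    if not rows:
        raise FormatError(f"{path}: empty data block")

    t = np.asarray(time)
    if len(t) >= 2:
        frame_rate = 1.0 / float(np.median(np.diff(t)))
    else:
        frame_rate = float("nan")
    return JointAngleSeries(
        frame_rate=frame_rate, time=t, dof_names=dof_names, angles=np.asarray(rows)
    )


def write_mot(series: JointAngleSeries, path: str | Path) -> None:
    """Write *series* as a MOT file re-readable by :func:`read_mot`."""
    series.validate()
    path = Path(path)
    n_rows = len(series.time)
    header = [
        path.stem,
        "version=1",
        f"nRows={n_rows}",
        f"nColumns={1 + len(series.dof_names)}",
        "inDegrees=yes",
        "endheader",
        "time\t" + "\t".join(series.dof_names),
    ]
    rows = [
        f"{series.time[i]:.8f}\t" + "\t".join(f"{v:.8f}" for v in series.angles[i])
        for i in range(n_rows)
    ]
    path.write_text("\n".join(header + rows) + "\n")
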