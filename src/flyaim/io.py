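"""Reading, validating and writing single-fly trajectories.

Trajectories are plain delimited text (CSV) with a mandatory header
``frame,x,y,orientation`` — the shape of per-frame output exported from a
video tracker such as Ctrax: one row per frame with the animal's centroid
position and body heading. Positions are converted to millimetres at load
using the arena calibration; orientations are wrapped to [-180, 180) degrees.
Loading never silently repairs data: a missing or duplicated frame, or a
non-numeric cell, is a hard error naming the offending row.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "ArenaCalibration",
    "Trajectory",
    "TrajectoryFormatError",
    "read_trajectory",
    "write_trajectory",
    "wrap_degrees",
    "load_config",
]

#: columns a trajectory file must declare, in canonical order
TRAJECTORY_COLUMNS = ("frame", "x", "y", "orientation")


class TrajectoryFormatError(ValueError):
    """A trajectory file or object violates the format contract."""


def wrap_degrees(angle):
    """Wrap angle(s) in degrees to the half-open interval [-180, 180)."""
    return np.mod(np.asarray(angle, dtype=float) + 180.0, 360.0) - 180.0


@dataclass(frozen=True)
class ArenaCalibration:
    """Spatial and temporal calibration of a recording.

    Parameters
    ----------
    pixels_per_mm:
        Scale of the camera image. Tracker output in pixels is divided by
        this at load; pass 1.0 for data already in millimetres.
    frame_rate:
        Frames per second of the recording. Default 30.06 fps, i.e. one
        frame every ~0.033 s over a 5-minute (9018-frame) recording.
    arena_diameter_mm:
        Optional arena size used for bounds checking only.
    """

    pixels_per_mm: float = 1.0
    frame_rate: float = 30.06
    arena_diameter_mm: float | None = None

    def __post_init__(self) -> None:
        if not (math.isfinite(self.pixels_per_mm) and self.pixels_per_mm > 0):
            raise ValueError(f"pixels_per_mm must be positive, got {self.pixels_per_mm}")
        if not (math.isfinite(self.frame_rate) and self.frame_rate > 0):
            raise ValueError(f"frame_rate must be positive, got {self.frame_rate}")
        if self.arena_diameter_mm is not None and self.arena_diameter_mm <= 0:
            raise ValueError("arena_diameter_mm must be positive when given")


@dataclass
class Trajectory:
    """A validated single-animal trajectory.

    Positions are stored in millimetres (``position_unit`` records the
    conversion provenance), orientations in degrees wrapped to [-180, 180).
    Frame indices start at 0 and increase strictly by 1 — the recording spans
    the first to the last frame with no gaps.
    """

    frame_index: np.ndarray
    x_mm: np.ndarray
    y_mm: np.ndarray
    orientation_deg: np.ndarray
    calibration: ArenaCalibration = field(default_factory=ArenaCalibration)
    position_unit: str = "mm"

    def __post_init__(self) -> None:
        self.frame_index = np.asarray(self.frame_index, dtype=int)
        self.x_mm = np.asarray(self.x_mm, dtype=float)
        self.y_mm = np.asarray(self.y_mm, dtype=float)
        self.orientation_deg = wrap_degrees(self.orientation_deg)
        self.validate()

    @property
    def n_frames(self) -> int:
        return int(self.frame_index.size)

    @property
    def duration_s(self) -> float:
        return (self.n_frames - 1) / self.calibration.frame_rate

    def validate(self) -> None:
        n = self.frame_index.size
        if n < 2:
            raise TrajectoryFormatError(f"trajectory needs >= 2 frames, got {n}")
        for name, arr in (("x", self.x_mm), ("y", self.y_mm),
                          ("orientation", self.orientation_deg)):
            if arr.size != n:
                raise TrajectoryFormatError(
                    f"column '{name}' has {arr.size} rows, expected {n}")
            if not np.all(np.isfinite(arr)):
                bad = int(np.flatnonzero(~np.isfinite(arr))[0])
                raise TrajectoryFormatError(
                    f"non-finite value in column '{name}' at frame "
                    f"{int(self.frame_index[bad]) if bad < n else bad}")
        if self.frame_index[0] != 0:
            raise TrajectoryFormatError(
                f"frame indices must start at 0, got {int(self.frame_index[0])}")
        diffs = np.diff(self.frame_index)
        if np.any(diffs != 1):
            i = int(np.flatnonzero(diffs != 1)[0])
            prev = int(self.frame_index[i])
            nxt = int(self.frame_index[i + 1])
            if nxt == prev:
                raise TrajectoryFormatError(f"duplicated frame {prev}")
            raise TrajectoryFormatError(f"missing frame {prev + 1}")

    def translated(self, dx: float, dy: float) -> "Trajectory":
        """Rigid translation (testing aid; metrics must be invariant)."""
        return replace(self, x_mm=self.x_mm + dx, y_mm=self.y_mm + dy)

    def rotated(self, angle_deg: float) -> "Trajectory":
        """Rigid rotation about the origin, headings co-rotated."""
        a = math.radians(angle_deg)
        c, s = math.cos(a), math.sin(a)
        return replace(
            self,
            x_mm=c * self.x_mm - s * self.y_mm,
            y_mm=s * self.x_mm + c * self.y_mm,
            orientation_deg=wrap_degrees(self.orientation_deg + angle_deg),
        )


def read_trajectory(
    path: str | Path,
    calibration: ArenaCalibration,
    *,
    input_units: str = "px",
) -> Trajectory:
    """Read and validate a trajectory CSV.

    Parameters
    ----------
    path:
        CSV file with header ``frame,x,y,orientation``, rows sorted by frame.
    calibration:
        Arena calibration; positions are divided by ``pixels_per_mm`` when
        ``input_units`` is ``"px"``.
    input_units:
        ``"px"`` (tracker pixels, default) or ``"mm"`` (already calibrated).

    Raises
    ------
    TrajectoryFormatError
        On a missing/duplicated frame (naming the first offending frame), a
        non-numeric cell (naming the row), or a malformed header.
    """
    if input_units not in ("px", "mm"):
        raise ValueError(f"input_units must be 'px' or 'mm', got {input_units!r}")
    path = Path(path)
    df = pd.read_csv(path, dtype=str, skipinitialspace=True)
    cols = [c.strip() for c in df.columns]
    if cols[: len(TRAJECTORY_COLUMNS)] != list(TRAJECTORY_COLUMNS):
        raise TrajectoryFormatError(
            f"{path.name}: header must declare columns "
            f"{','.join(TRAJECTORY_COLUMNS)}; found {','.join(cols)}")
    df.columns = cols
    numeric = {}
    for col in TRAJECTORY_COLUMNS:
        parsed = pd.to_numeric(df[col], errors="coerce")
        bad = parsed.isna() & df[col].notna()
        if bad.any() or parsed.isna().any():
            row = int(np.flatnonzero(parsed.isna().to_numpy())[0])
            raise TrajectoryFormatError(
                f"{path.name}: non-numeric value {df[col].iloc[row]!r} in column "
                f"'{col}' at data row {row}")
        numeric[col] = parsed.to_numpy(dtype=float)

    scale = calibration.pixels_per_mm if input_units == "px" else 1.0
    return Trajectory(
        frame_index=numeric["frame"].astype(int),
        x_mm=numeric["x"] / scale,
        y_mm=numeric["y"] / scale,
        orientation_deg=numeric["orientation"],
        calibration=calibration,
        position_unit="mm",
    )


def write_trajectory(traj: Trajectory, path: str | Path) -> None:
    """Write a trajectory as CSV, re-readable by :func:`read_trajectory`.

    Positions are written in millimetres with fixed 6-decimal formatting and
    deterministic column order, so write-then-read is the identity to 1e-6
    (read back with ``input_units="mm"``).
    """
    traj.validate()
    df = pd.DataFrame(
        {
            "frame": traj.frame_index,
            "x": traj.x_mm,
            "y": traj.y_mm,
            "orientation": wrap_degrees(traj.orientation_deg),
        }
    )
    df.to_csv(path, index=False, float_format="%.6f")


def load_config(path: str | Path) -> dict:
    """Load the shared run-parameter config (YAML mapping).

    Recognised keys: ``pixels_per_mm``, ``frame_rate``, ``window_s``,
    ``threshold_c``, ``freeze_epsilon_mm``. Unknown keys are preserved.
    """
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValueError(f"config {path} must be a mapping, got {type(cfg).__name__}")
    return cfg
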