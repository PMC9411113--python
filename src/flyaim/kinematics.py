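"""Per-frame kinematics and the three locomotor parameters.

From a trajectory of n frames this module derives n-1 per-step quantities:
the displacement d_i between consecutive centroid positions, the
instantaneous speed v_i (displacement scaled by the frame rate, so values
are frame-rate independent), and the yaw theta_i (signed wrapped change in
body heading). The three summary parameters used to phenotype locomotion
are the mean speed (mm/s), the yawing metric (mean absolute heading change,
deg/frame), and the freezing fraction (share of steps with near-zero
displacement).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io import ArenaCalibration, Trajectory, wrap_degrees

__all__ = [
    "KinematicSeries",
    "displacement_series",
    "yaw_series",
    "kinematic_series",
    "mean_speed",
    "yawing_metric",
    "freezing_fraction",
]


@dataclass
class KinematicSeries:
    """Per-step kinematic quantities of one trajectory.

    All arrays have length ``n_steps = n_frames - 1``; entry i describes the
    step from frame i to frame i+1. Displacements are non-negative, yaw is
    wrapped to [-180, 180).
    """

    displacement_mm: np.ndarray
    speed_mm_per_s: np.ndarray
    yaw_deg: np.ndarray
    frame_rate: float

    def __post_init__(self) -> None:
        self.displacement_mm = np.asarray(self.displacement_mm, dtype=float)
        self.speed_mm_per_s = np.asarray(self.speed_mm_per_s, dtype=float)
        self.yaw_deg = np.asarray(self.yaw_deg, dtype=float)
        n = self.displacement_mm.size
        if self.speed_mm_per_s.size != n or self.yaw_deg.size != n:
            raise ValueError("kinematic series arrays must have equal length")
        if n < 1:
            raise ValueError("kinematic series needs at least one step")
        if np.any(self.displacement_mm < 0):
            raise ValueError("displacement must be non-negative")
        if self.frame_rate <= 0:
            raise ValueError("frame_rate must be positive")

    @property
    def n_steps(self) -> int:
        return int(self.displacement_mm.size)

    @classmethod
    def from_speeds(cls, speed_mm_per_s, frame_rate: float = 30.06) -> "KinematicSeries":
        """Build a series from instantaneous speeds alone (yaw zeroed).

        Convenience for constructing scoring inputs directly, e.g. the
        worked burst-train example.
        """
        v = np.asarray(speed_mm_per_s, dtype=float)
        return cls(
            displacement_mm=v / frame_rate,
            speed_mm_per_s=v,
            yaw_deg=np.zeros_like(v),
            frame_rate=frame_rate,
        )


def kinematic_series(traj: Trajectory) -> KinematicSeries:
    """Compute displacement, speed and yaw for every frame step."""
    if traj.n_frames < 2:
        raise ValueError("need at least 2 frames to compute kinematics")
    dx = np.diff(traj.x_mm)
    dy = np.diff(traj.y_mm)
    d = np.hypot(dx, dy)
    fr = traj.calibration.frame_rate
    yaw = wrap_degrees(np.diff(traj.orientation_deg))
    return KinematicSeries(
        displacement_mm=d,
        speed_mm_per_s=d * fr,
        yaw_deg=yaw,
        frame_rate=fr,
    )


def displacement_series(traj: Trajectory) -> KinematicSeries:
    """Per-step Euclidean displacement in mm (alias of :func:`kinematic_series`)."""
    return kinematic_series(traj)


def yaw_series(traj: Trajectory) -> KinematicSeries:
    """Signed wrapped heading change per step (alias of :func:`kinematic_series`)."""
    return kinematic_series(traj)


def mean_speed(series: KinematicSeries) -> float:
    """Mean instantaneous speed in mm/s (per-step displacement x frame rate)."""
    if series.n_steps < 1:
        raise ValueError("empty kinematic series")
    return float(np.mean(series.speed_mm_per_s))


def yawing_metric(series: KinematicSeries, mode: str = "mean_abs") -> float:
    """Aggregate yaw over the recording.

    ``mean_abs`` (default) is the mean absolute per-step heading change in
    deg/frame; ``sum`` is the total absolute turning in degrees; ``rate``
    is mean_abs scaled to deg/s. The per-frame mean is the default because
    it is length-independent and comparable across recordings.
    """
    if series.n_steps < 1:
        raise ValueError("empty kinematic series")
    mean_abs = float(np.mean(np.abs(series.yaw_deg)))
    if mode == "mean_abs":
        return mean_abs
    if mode == "sum":
        return float(np.sum(np.abs(series.yaw_deg)))
    if mode == "rate":
        return mean_abs * series.frame_rate
    raise ValueError(f"unknown yawing mode {mode!r}")


def freezing_fraction(series: KinematicSeries, epsilon_mm: float = 0.05) -> float:
    """Fraction of steps with displacement <= epsilon_mm, in [0, 1].

    The literal definition of freezing is zero distance moved; tracked
    centroids jitter, so a small tolerance (default 0.05 mm) absorbs
    sub-pixel noise. epsilon_mm = 0 recovers the exact d = 0 definition on
    noiseless data.
    """
    if series.n_steps < 1:
        raise ValueError("empty kinematic series")
    if not (epsilon_mm >= 0):
        raise ValueError(f"epsilon_mm must be non-negative, got {epsilon_mm}")
    return float(np.mean(series.displacement_mm <= epsilon_mm))
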