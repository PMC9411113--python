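"""Seeded generative model of single-fly arena locomotion.

The generator is a correlated random walk with three hidden behavioural
states per frame:

* WALK — heading diffuses by Normal(0, turn_sd) per frame; step length is
  walk_speed / frame_rate times multiplicative lognormal noise (unit mean).
* FREEZE — no displacement and no heading change. Entry and exit are
  per-frame Bernoulli events, so dwell times are geometric and the
  stationary frozen occupancy has the closed form
  enter_p / (enter_p + exit_p) — used as ground truth in recovery tests.
* BURST — a single-frame multiplicative speed spike (gain x the walk step)
  co-occurring with a large heading kick, emulating the abrupt
  accelerations-at-direction-changes that the AIM score is built to
  detect. Bursts arrive homogeneously within WALK at burst_rate_per_min.

A scalar dose in [0, 1] stands in for L-DOPA exposure (concentration or
diet duration) and maps linearly onto the generative parameters: walking
speed down, freeze entry up, heading diffusion up, burst rate up. The
slopes are calibrated analytically so the dose = 1 cohort shows roughly a
58% drop in mean speed, a 235% rise in freezing and a 250% rise in yawing
relative to dose = 0 — the magnitudes characteristic of dyskinetic fly
locomotion — with a matching rise in AIM-qualifying burst frames.

Movement is confined to a circular arena; a proposed position outside the
wall is folded back radially (reflective boundary) and the heading reset to
the realised displacement direction. Identical seed + config gives a
bit-identical trajectory; cohort seeds are derived from the master seed by
counter-based splitting, so per-fly streams are order-independent.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from enum import IntEnum

import numpy as np

from .io import ArenaCalibration, Trajectory, wrap_degrees

__all__ = [
    "BehavioralState",
    "SimulationConfig",
    "EffectiveParams",
    "effective_params",
    "simulate_trajectory",
    "simulate_cohort",
    "CohortFly",
]


class BehavioralState(IntEnum):
    WALK = 0
    FREEZE = 1
    BURST = 2


# Linear dose -> parameter slopes, calibrated from the closed forms
# (stationary occupancy of the freeze chain; E|N(0,s)| = s*sqrt(2/pi)) so
# the dose=1 expectations approximate the reported dyskinesia effect sizes.
DOSE_SPEED_DROP = 0.487        # walk speed multiplier: 1 - drop * dose
DOSE_FREEZE_ENTER_SLOPE = 0.025  # added to freeze_enter_p
DOSE_TURN_GAIN = 3.1           # turn_sd multiplier: 1 + gain * dose
DOSE_BURST_RATE_SLOPE = 12.0   # added bursts/min at dose = 1


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of one simulated recording (defaults = control fly).

    Defaults mirror the real assay: 9018 frames at 30.06 fps (5 minutes) in
    a circular arena of 27.5 mm radius (a 60 mm dish with a silicone
    insert). The control fly walks at 8 mm/s with 25% multiplicative speed
    noise, freezes ~7% of the time (enter 0.008 / exit 0.10 per frame),
    turns with 5 deg/frame heading diffusion and shows almost no bursts.
    """

    n_frames: int = 9018
    frame_rate: float = 30.06
    walk_speed_mm_s: float = 8.0
    speed_noise_cv: float = 0.25
    freeze_enter_p: float = 0.008
    freeze_exit_p: float = 0.10
    turn_sd_deg: float = 5.0
    burst_rate_per_min: float = 0.5
    burst_gain: float = 6.0
    burst_turn_deg: float = 90.0
    dose: float = 0.0
    arena_radius_mm: float = 27.5
    seed: int = 0

    def __post_init__(self) -> None:
        checks = {
            "n_frames": self.n_frames >= 2,
            "frame_rate": self.frame_rate > 0,
            "walk_speed_mm_s": self.walk_speed_mm_s > 0,
            "speed_noise_cv": self.speed_noise_cv >= 0,
            "freeze_enter_p": 0 <= self.freeze_enter_p <= 1,
            "freeze_exit_p": 0 <= self.freeze_exit_p <= 1,
            "turn_sd_deg": self.turn_sd_deg >= 0,
            "burst_rate_per_min": self.burst_rate_per_min >= 0,
            "burst_gain": self.burst_gain > 1,
            "burst_turn_deg": self.burst_turn_deg >= 0,
            "dose": 0 <= self.dose <= 1,
            "arena_radius_mm": self.arena_radius_mm > 0,
        }
        for name, ok in checks.items():
            value = getattr(self, name)
            if not (ok and np.isfinite(value)):
                raise ValueError(f"invalid {name}: {value}")

    @property
    def calibration(self) -> ArenaCalibration:
        return ArenaCalibration(
            pixels_per_mm=1.0,
            frame_rate=self.frame_rate,
            arena_diameter_mm=2 * self.arena_radius_mm,
        )


@dataclass(frozen=True)
class EffectiveParams:
    """Dose-adjusted generative parameters actually used per frame."""

    walk_speed_mm_s: float
    freeze_enter_p: float
    freeze_exit_p: float
    turn_sd_deg: float
    burst_p_per_frame: float

    @property
    def freeze_occupancy(self) -> float:
        """Closed-form stationary frozen fraction of the 2-state chain."""
        total = self.freeze_enter_p + self.freeze_exit_p
        return self.freeze_enter_p / total if total > 0 else 0.0


def effective_params(config: SimulationConfig) -> EffectiveParams:
    """Apply the linear dose mapping to the base parameters."""
    d = config.dose
    burst_per_min = config.burst_rate_per_min + DOSE_BURST_RATE_SLOPE * d
    return EffectiveParams(
        walk_speed_mm_s=config.walk_speed_mm_s * (1.0 - DOSE_SPEED_DROP * d),
        freeze_enter_p=min(1.0, config.freeze_enter_p + DOSE_FREEZE_ENTER_SLOPE * d),
        freeze_exit_p=config.freeze_exit_p,
        turn_sd_deg=config.turn_sd_deg * (1.0 + DOSE_TURN_GAIN * d),
        burst_p_per_frame=burst_per_min / (60.0 * config.frame_rate),
    )


def simulate_trajectory(
    config: SimulationConfig,
) -> tuple[Trajectory, np.ndarray]:
    """Simulate one recording; returns (trajectory, hidden state sequence).

    The state array (length n_frames, values of :class:`BehavioralState`)
    is ground truth for testing: the displacement of step i is produced by
    the state at frame i+1, so frozen frames give exactly zero displacement
    and burst frames give the spiked step.
    """
    p = effective_params(config)
    rng = np.random.default_rng(config.seed)
    n = config.n_frames
    radius = config.arena_radius_mm
    base_step = p.walk_speed_mm_s / config.frame_rate

    # unit-mean lognormal multiplicative speed noise
    if config.speed_noise_cv > 0:
        sigma = math.sqrt(math.log(1.0 + config.speed_noise_cv**2))
        mu = -0.5 * sigma**2
    else:
        sigma = mu = 0.0

    states = np.empty(n, dtype=np.int8)
    x = np.empty(n)
    y = np.empty(n)
    heading = np.empty(n)

    states[0] = BehavioralState.WALK
    r0 = radius * 0.5 * math.sqrt(rng.uniform())
    a0 = rng.uniform(0, 2 * math.pi)
    x[0], y[0] = r0 * math.cos(a0), r0 * math.sin(a0)
    heading[0] = rng.uniform(-180.0, 180.0)

    for t in range(1, n):
        prev_frozen = states[t - 1] == BehavioralState.FREEZE
        if prev_frozen:
            frozen = rng.uniform() >= p.freeze_exit_p
        else:
            frozen = rng.uniform() < p.freeze_enter_p

        if frozen:
            states[t] = BehavioralState.FREEZE
            x[t], y[t] = x[t - 1], y[t - 1]
            heading[t] = heading[t - 1]
            continue

        burst = rng.uniform() < p.burst_p_per_frame
        states[t] = BehavioralState.BURST if burst else BehavioralState.WALK

        h = heading[t - 1] + rng.normal(0.0, p.turn_sd_deg)
        step = base_step
        if sigma > 0:
            step *= math.exp(mu + sigma * rng.normal())
        if burst:
            h += config.burst_turn_deg * (1.0 if rng.uniform() < 0.5 else -1.0)
            step *= config.burst_gain

        rad = math.radians(h)
        px = x[t - 1] + step * math.cos(rad)
        py = y[t - 1] + step * math.sin(rad)
        r = math.hypot(px, py)
        if r > radius:
            # reflective boundary: fold the overshoot back radially and
            # realign the heading with the realised displacement
            fold = (2.0 * radius - r) / r
            px *= fold
            py *= fold
            h = math.degrees(math.atan2(py - y[t - 1], px - x[t - 1]))
        x[t], y[t] = px, py
        heading[t] = float(wrap_degrees(h))

    traj = Trajectory(
        frame_index=np.arange(n),
        x_mm=x,
        y_mm=y,
        orientation_deg=heading,
        calibration=config.calibration,
        position_unit="mm",
    )
    return traj, states


@dataclass
class CohortFly:
    """One simulated fly of a cohort, with its provenance."""

    fly_id: str
    dose: float
    seed: int
    trajectory: Trajectory
    states: np.ndarray


def _derived_seed(master_seed: int, dose_index: int, fly_index: int) -> int:
    """Counter-based per-fly seed: reproducible and order-independent."""
    ss = np.random.SeedSequence([int(master_seed), dose_index, fly_index])
    return int(ss.generate_state(1)[0] % (2**31))


def simulate_cohort(
    config: SimulationConfig,
    n_flies: int,
    dose_levels,
) -> list[CohortFly]:
    """Simulate n_flies independent recordings at each dose level.

    Per-fly seeds are derived from ``config.seed`` (the master seed) and
    the (dose, fly) counters, so any subset of the cohort is reproducible
    without simulating the rest.
    """
    dose_levels = list(dose_levels)
    if n_flies < 1:
        raise ValueError("n_flies must be >= 1")
    if not dose_levels:
        raise ValueError("dose_levels must be non-empty")
    flies: list[CohortFly] = []
    for d_idx, dose in enumerate(dose_levels):
        for f_idx in range(n_flies):
            seed = _derived_seed(config.seed, d_idx, f_idx)
            cfg = replace(config, dose=float(dose), seed=seed)
            traj, states = simulate_trajectory(cfg)
            flies.append(
                CohortFly(
                    fly_id=f"dose{dose:g}_fly{f_idx}",
                    dose=float(dose),
                    seed=seed,
                    trajectory=traj,
                    states=states,
                )
            )
    return flies
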