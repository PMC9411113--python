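"""Sliding-window AIM (abnormal involuntary movement) scoring.

Dyskinetic locomotion shows abrupt single-frame accelerations that deviate
from the animal's own movement at nearby time points. The AIM score counts
such frames: each instantaneous speed v_i is compared with the mean speed
v_s of a centred sliding window of s frames,

    v_s(i) = (1/s) * ( sum_{j=i-floor(s/2)}^{i-1} v_j
                     + sum_{k=i}^{i+floor(s/2)} v_k ),

and a frame scores 1 when |log10(v_i / v_s)| exceeds a threshold constant c.
The raw score H is the sum over all scored frames of the recording. With
the defaults (s = 21 frames, c = 0.4, a 9018-frame / 5-minute recording at
30.06 fps) a frame qualifies when its speed deviates from the local mean by
more than a factor of 10**0.4 ~ 2.5 in either direction. Scores are
reported relative to a control cohort: the control mean is subtracted so
control flies average exactly 0.

The two window sums cover s frames only when s is odd, so an odd window is
enforced; the half-width is (s-1)/2. Edge frames without a full window are
unscored, which keeps H comparable across equal-length recordings. Frames
where v_i or v_s is at or below a small guard are excluded (log undefined;
stationary behaviour is already captured by the freezing fraction).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .kinematics import KinematicSeries

__all__ = [
    "AimParams",
    "AimResult",
    "sliding_mean_speed",
    "aim_raw",
    "normalize_aim",
    "peak_deviation",
    "threshold_from_controls",
]


@dataclass(frozen=True)
class AimParams:
    """Parameters of the AIM score.

    window_s:
        Sliding-window size s in frames; odd and >= 3 (default 21, i.e.
        ~0.7 s of recording at 30.06 fps).
    threshold_c:
        Log10-ratio threshold c (default 0.4, determined from wild-type
        control locomotion).
    n_frames_expected:
        Nominal recording length n (default 9018 frames = 5 min); purely
        informational, recordings of other lengths score fine.
    epsilon_speed:
        Zero-speed guard in mm/s; frames with v_i or v_s at/below it are
        skipped rather than clamped.
    """

    window_s: int = 21
    threshold_c: float = 0.4
    n_frames_expected: int = 9018
    epsilon_speed: float = 1e-9

    def __post_init__(self) -> None:
        if self.window_s < 3 or self.window_s % 2 == 0:
            raise ValueError(f"window_s must be odd and >= 3, got {self.window_s}")
        if not self.threshold_c > 0:
            raise ValueError(f"threshold_c must be positive, got {self.threshold_c}")
        if self.epsilon_speed < 0:
            raise ValueError("epsilon_speed must be non-negative")

    @property
    def half_width(self) -> int:
        return (self.window_s - 1) // 2


@dataclass
class AimResult:
    """Outcome of scoring one recording.

    raw_H is the integer AIM score (count of qualifying frames);
    log_ratio holds log10(v_i/v_s) per step, NaN where unscored (edge) or
    skipped (zero-speed guard). scored_frame_count excludes skipped frames.
    """

    raw_H: int
    qualifying_frames: np.ndarray
    scored_frame_count: int
    skipped_frame_count: int
    log_ratio: np.ndarray
    all_skipped: bool = False
    normalized_H: float | None = None
    params: AimParams = field(default_factory=AimParams)

    def __post_init__(self) -> None:
        assert self.raw_H == len(self.qualifying_frames)
        assert 0 <= self.raw_H <= max(self.scored_frame_count, 0)


def sliding_mean_speed(series: KinematicSeries, params: AimParams) -> np.ndarray:
    """Centred sliding-window mean speed v_s, NaN where no full window fits.

    Returns an array of length n_steps; entry i is the mean of the s speeds
    at steps i - (s-1)/2 ... i + (s-1)/2 when that window lies fully inside
    the series, NaN otherwise (no shrinking edge windows).
    """
    v = series.speed_mm_per_s
    s = params.window_s
    if v.size < s:
        raise ValueError(
            f"series has {v.size} steps, shorter than window {s}")
    windows = np.lib.stride_tricks.sliding_window_view(v, s)
    vs = np.full(v.size, np.nan)
    h = params.half_width
    vs[h : v.size - h] = windows.mean(axis=-1)
    return vs


def aim_raw(
    series: KinematicSeries,
    params: AimParams | None = None,
    *,
    mode: str = "absolute",
) -> AimResult:
    """Raw AIM score H of one recording.

    mode ``"absolute"`` (default) scores |log10(v_i/v_s)| > c, so abrupt
    decelerations count as well as accelerations; ``"signed"`` scores only
    log10(v_i/v_s) > c (accelerations), provided for sensitivity analysis.

    Frames where v_i or v_s falls at/below the zero-speed guard are skipped.
    If every frame is skipped the result carries raw_H = 0 and the
    ``all_skipped`` flag, with a warning.
    """
    if params is None:
        params = AimParams()
    if mode not in ("absolute", "signed"):
        raise ValueError(f"mode must be 'absolute' or 'signed', got {mode!r}")
    v = series.speed_mm_per_s
    vs = sliding_mean_speed(series, params)
    in_window = np.isfinite(vs)
    usable = in_window & (v > params.epsilon_speed) & (vs > params.epsilon_speed)
    skipped = int(in_window.sum() - usable.sum())

    log_ratio = np.full(v.size, np.nan)
    with np.errstate(divide="ignore", invalid="ignore"):
        log_ratio[usable] = np.log10(v[usable] / vs[usable])

    if mode == "absolute":
        qualifies = usable & (np.abs(log_ratio) > params.threshold_c)
    else:
        qualifies = usable & (log_ratio > params.threshold_c)

    all_skipped = usable.sum() == 0
    if all_skipped:
        warnings.warn(
            "all frames skipped by zero-speed guard; raw AIM score is 0",
            RuntimeWarning,
            stacklevel=2,
        )
    idx = np.flatnonzero(qualifies)
    return AimResult(
        raw_H=int(idx.size),
        qualifying_frames=idx,
        scored_frame_count=int(usable.sum()),
        skipped_frame_count=skipped,
        log_ratio=log_ratio,
        all_skipped=bool(all_skipped),
        params=params,
    )


def normalize_aim(raw_scores, control_raw_scores) -> np.ndarray:
    """Subtract the control-cohort mean so controls average exactly 0.

    The baseline is the mean raw score of the user-designated control group
    of the same experiment; no global constant is assumed.
    """
    control = np.asarray(control_raw_scores, dtype=float)
    if control.size == 0:
        raise ValueError("control cohort is empty")
    return np.asarray(raw_scores, dtype=float) - control.mean()


def peak_deviation(series: KinematicSeries, params: AimParams | None = None) -> float:
    """Maximal percent deviation of v_i from the local mean v_s.

    max over scored frames of (v_i - v_s) / v_s * 100 — e.g. a frame at
    twice the local mean speed deviates by 100%.
    """
    if params is None:
        params = AimParams()
    v = series.speed_mm_per_s
    vs = sliding_mean_speed(series, params)
    usable = np.isfinite(vs) & (vs > params.epsilon_speed)
    if not usable.any():
        raise ValueError("no scored frames for peak deviation")
    return float(np.max((v[usable] - vs[usable]) / vs[usable]) * 100.0)


def threshold_from_controls(
    control_series: list[KinematicSeries],
    params: AimParams | None = None,
    percentile: float = 99.5,
) -> float:
    """Derive a threshold c from a control cohort (convenience helper).

    Pools |log10(v_i/v_s)| across all control recordings and returns the
    given percentile (default 99.5), so roughly 0.5% of control frames
    would qualify before normalization. This is one documented convention
    for calibrating c from wild-type movement, not a canonical procedure.
    """
    if params is None:
        params = AimParams()
    if not control_series:
        raise ValueError("control cohort is empty")
    pooled = []
    for series in control_series:
        res = aim_raw(series, params)
        ratios = res.log_ratio[np.isfinite(res.log_ratio)]
        pooled.append(np.abs(ratios))
    pooled = np.concatenate(pooled)
    if pooled.size == 0:
        raise ValueError("no scorable frames in control cohort")
    return float(np.percentile(pooled, percentile))
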