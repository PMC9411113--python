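"""Per-fly metric tables, group summaries and dose-trend statistics.

Aggregates the kinematic and AIM outputs into the tables an experimenter
reports: one tidy row per fly, per-group mean +/- SEM with percent change
versus a designated control group, and a rank-correlation trend test of a
metric against dose (or diet duration) with a seeded permutation p-value.
Between-group inference (ANOVA + post-hoc) is routine statistics and is
delegated to scipy/statsmodels by the caller; it is not re-implemented
here.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .aim import AimParams, aim_raw, normalize_aim, peak_deviation
from .io import Trajectory
from .kinematics import (
    freezing_fraction,
    kinematic_series,
    mean_speed,
    yawing_metric,
)

__all__ = [
    "FlyRecord",
    "summarize_fly",
    "records_to_frame",
    "summarize_group",
    "percent_change",
    "dose_trend",
    "TrendResult",
]

#: metrics carried through group summaries, in reporting order
METRICS = (
    "mean_speed_mm_s",
    "yawing_deg_per_frame",
    "freezing_fraction",
    "raw_H",
    "normalized_H",
    "peak_deviation_pct",
)


@dataclass
class FlyRecord:
    """One fly's full metric row."""

    fly_id: str
    group: str
    mean_speed_mm_s: float
    yawing_deg_per_frame: float
    freezing_fraction: float
    raw_H: int
    peak_deviation_pct: float
    n_frames: int
    aim_all_skipped: bool = False
    normalized_H: float = np.nan
    dose: float = np.nan


def summarize_fly(
    traj: Trajectory,
    params: AimParams | None = None,
    epsilon_mm: float = 0.05,
    *,
    fly_id: str = "fly",
    group: str = "group",
    dose: float = np.nan,
) -> FlyRecord:
    """Compute every locomotor metric for one trajectory.

    Deterministic composition of the kinematics and AIM operations; the
    normalized score is filled in later once the control cohort is known.
    A fully frozen fly gets raw_H = 0 with the ``aim_all_skipped`` flag and
    no peak deviation (NaN).
    """
    if params is None:
        params = AimParams()
    if not group:
        raise ValueError("group label must be non-empty")
    series = kinematic_series(traj)
    res = aim_raw(series, params)
    try:
        peak = peak_deviation(series, params)
    except ValueError:
        peak = np.nan
    return FlyRecord(
        fly_id=fly_id,
        group=group,
        mean_speed_mm_s=mean_speed(series),
        yawing_deg_per_frame=yawing_metric(series),
        freezing_fraction=freezing_fraction(series, epsilon_mm),
        raw_H=res.raw_H,
        peak_deviation_pct=peak,
        n_frames=traj.n_frames,
        aim_all_skipped=res.all_skipped,
        dose=dose,
    )


def records_to_frame(records: list[FlyRecord]) -> pd.DataFrame:
    """Tidy one-row-per-fly table."""
    return pd.DataFrame([asdict(r) for r in records])


def percent_change(treated_mean: float, control_mean: float) -> float:
    """(treated - control) / control * 100; e.g. 1.2 -> 0.5 is -58.33%."""
    return (treated_mean - control_mean) / control_mean * 100.0


def summarize_group(
    records: list[FlyRecord],
    control_label: str,
) -> pd.DataFrame:
    """Per-group mean, SEM and percent change vs the control group.

    Fills each record's normalized_H (raw minus control mean) before
    aggregating. SEM uses the sample standard deviation over sqrt(n); a
    single-fly group reports SEM 0 with the ``degenerate_n`` flag rather
    than erroring, so toy fixtures run end-to-end. The control group's
    percent change is 0 by construction for every metric.
    """
    df = records_to_frame(records)
    if control_label not in set(df["group"]):
        raise ValueError(f"control label {control_label!r} not among groups")

    control_raw = df.loc[df["group"] == control_label, "raw_H"].to_numpy()
    df["normalized_H"] = normalize_aim(df["raw_H"].to_numpy(), control_raw)
    for rec, norm in zip(records, df["normalized_H"]):
        rec.normalized_H = float(norm)

    control_means = df[df["group"] == control_label][list(METRICS)].mean()
    rows = []
    for group, sub in df.groupby("group", sort=False):
        n = len(sub)
        row: dict = {"group": group, "n": n, "degenerate_n": n == 1}
        for metric in METRICS:
            vals = sub[metric].to_numpy(dtype=float)
            mean = float(np.nanmean(vals))
            sem = 0.0 if n == 1 else float(stats.sem(vals, nan_policy="omit"))
            row[f"{metric}_mean"] = mean
            row[f"{metric}_sem"] = sem
            ctrl = control_means[metric]
            if np.isfinite(ctrl) and ctrl != 0:
                row[f"{metric}_pct_change"] = percent_change(mean, ctrl)
            elif group == control_label:
                row[f"{metric}_pct_change"] = 0.0
            else:
                row[f"{metric}_pct_change"] = np.nan
        if group == control_label:
            # control vs itself is identically zero, independent of rounding
            for metric in METRICS:
                if np.isfinite(row[f"{metric}_pct_change"]):
                    row[f"{metric}_pct_change"] = 0.0
        rows.append(row)
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class TrendResult:
    """Spearman trend of a metric against dose, with permutation p."""

    rho: float
    p_value: float
    n: int
    n_doses: int
    n_permutations: int

    @property
    def sign(self) -> int:
        return int(np.sign(self.rho))


def dose_trend(
    doses,
    values,
    *,
    n_permutations: int = 999,
    seed: int = 0,
    alternative: str = "two-sided",
) -> TrendResult:
    """Rank-correlation trend test of per-fly values against dose.

    Spearman rho between dose and metric, with a permutation p-value
    obtained by shuffling values over flies (>= 999 permutations, seeded).
    ``alternative`` may be "two-sided", "greater" or "less" (sign of rho).
    Requires at least 3 distinct dose levels.
    """
    doses = np.asarray(doses, dtype=float)
    values = np.asarray(values, dtype=float)
    if doses.shape != values.shape:
        raise ValueError("doses and values must have equal length")
    n_doses = np.unique(doses).size
    if n_doses < 3:
        raise ValueError(f"need >= 3 distinct dose levels, got {n_doses}")
    if n_permutations < 999:
        raise ValueError("use at least 999 permutations")

    rho = stats.spearmanr(doses, values).statistic
    rng = np.random.default_rng(seed)
    perm_rho = np.empty(n_permutations)
    for i in range(n_permutations):
        perm_rho[i] = stats.spearmanr(doses, rng.permutation(values)).statistic
    if alternative == "two-sided":
        extreme = np.abs(perm_rho) >= abs(rho)
    elif alternative == "greater":
        extreme = perm_rho >= rho
    elif alternative == "less":
        extreme = perm_rho <= rho
    else:
        raise ValueError(f"unknown alternative {alternative!r}")
    p = (1 + int(extreme.sum())) / (n_permutations + 1)
    return TrendResult(
        rho=float(rho),
        p_value=float(p),
        n=int(doses.size),
        n_doses=int(n_doses),
        n_permutations=n_permutations,
    )
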