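"""Step-level and window-level movement metrics.

Steps join consecutive valid GPS fixes; a step whose duration exceeds
``gap_tolerance_factor`` times the nominal fix interval is flagged as
spanning a missed fix and contributes no turning angle (a composite step
biases the angle distribution).  Sinuosity is the mean cosine of turning
angles: 1 for straight-line movement, 0 for Brownian-like motion, negative
for back-tracking paths.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence
from zoneinfo import ZoneInfo

import numpy as np
import pandas as pd

from .config import AnalysisConfig
from .io import Trajectory


class UndefinedMetricError(ValueError):
    """The metric is undefined for this input (e.g. no turning angles)."""


@dataclass
class StepSeries:
    """Steps between consecutive valid fixes.

    ``steps`` columns: ``t0``, ``t1`` (UTC), ``duration_min``, ``length_m``,
    ``heading_rad``, ``turn_angle_rad`` (NaN where undefined), ``spans_gap``.
    """

    steps: pd.DataFrame

    @property
    def n_gap_steps(self) -> int:
        return int(self.steps["spans_gap"].sum()) if len(self.steps) else 0

    def __len__(self) -> int:
        return len(self.steps)


_EMPTY = pd.DataFrame(
    {
        "t0": pd.Series(dtype="datetime64[ns, UTC]"),
        "t1": pd.Series(dtype="datetime64[ns, UTC]"),
        "duration_min": pd.Series(dtype=float),
        "length_m": pd.Series(dtype=float),
        "heading_rad": pd.Series(dtype=float),
        "turn_angle_rad": pd.Series(dtype=float),
        "spans_gap": pd.Series(dtype=bool),
    }
)


def build_steps(
    traj: Trajectory,
    window: tuple[pd.Timestamp, pd.Timestamp] | None = None,
    nominal_interval_min: float = 2.0,
    gap_tolerance_factor: float = 2.0,
) -> StepSeries:
    """Build the step series of ``traj`` restricted to ``window`` (inclusive).

    Fewer than two valid fixes yield an empty series, not an error.  Turning
    angles are defined only between consecutive non-gap steps and wrapped to
    (-pi, pi].
    """
    fixes = traj.valid
    if window is not None:
        lo, hi = window
        ts = fixes["timestamp"]
        fixes = fixes[(ts >= lo) & (ts <= hi)]
    if len(fixes) < 2:
        return StepSeries(_EMPTY.copy())
    t = fixes["timestamp"].reset_index(drop=True)
    x = fixes["x"].to_numpy(dtype=float)
    y = fixes["y"].to_numpy(dtype=float)
    dx = np.diff(x)
    dy = np.diff(y)
    dur_min = np.diff(t.astype("int64").to_numpy()) / 60e9
    length = np.hypot(dx, dy)
    heading = np.arctan2(dy, dx)
    heading[length == 0] = np.nan
    spans_gap = dur_min > gap_tolerance_factor * nominal_interval_min

    turn = np.full(len(length), np.nan)
    if len(length) > 1:
        d = heading[1:] - heading[:-1]
        d = _wrap_angle(d)
        usable = ~(spans_gap[1:] | spans_gap[:-1])
        usable &= ~(np.isnan(heading[1:]) | np.isnan(heading[:-1]))
        turn[1:] = np.where(usable, d, np.nan)

    return StepSeries(
        pd.DataFrame(
            {
                "t0": t.iloc[:-1].to_numpy(),
                "t1": t.iloc[1:].to_numpy(),
                "duration_min": dur_min,
                "length_m": length,
                "heading_rad": heading,
                "turn_angle_rad": turn,
                "spans_gap": spans_gap,
            }
        )
    )


def _wrap_angle(a: np.ndarray) -> np.ndarray:
    """Wrap to (-pi, pi]."""
    w = np.mod(a + np.pi, 2 * np.pi) - np.pi
    return np.where(w == -np.pi, np.pi, w)


def sinuosity(steps: StepSeries) -> float:
    """Mean cosine of the defined turning angles, in [-1, 1]."""
    angles = steps.steps["turn_angle_rad"].dropna() if len(steps) else pd.Series(dtype=float)
    if len(angles) == 0:
        raise UndefinedMetricError("no defined turning angles")
    return float(np.cos(angles.to_numpy()).mean())


def max_speed(steps: StepSeries) -> float:
    """Maximum per-step speed over non-gap steps, km/h."""
    if len(steps) == 0:
        raise UndefinedMetricError("empty step series")
    sub = steps.steps[~steps.steps["spans_gap"]]
    if len(sub) == 0:
        raise UndefinedMetricError("all steps span gaps")
    kmh = (sub["length_m"] / 1000.0) / (sub["duration_min"] / 60.0)
    return float(kmh.max())


def cumulative_distance(steps: StepSeries) -> float:
    """Sum of step lengths, metres (gap-spanning steps included; see
    :attr:`StepSeries.n_gap_steps` for their count).  Empty series sum to 0."""
    if len(steps) == 0:
        return 0.0
    return float(steps.steps["length_m"].sum())


def net_displacement(
    traj: Trajectory,
    reference_point: tuple[float, float],
    times: Sequence[pd.Timestamp],
    tolerance_min: float,
) -> np.ndarray:
    """Distance from ``reference_point`` to the valid fix nearest each
    requested time (within ``tolerance_min``); NaN where no fix qualifies."""
    rx, ry = reference_point
    if not (np.isfinite(rx) and np.isfinite(ry)):
        raise ValueError("reference point must be finite")
    fixes = traj.valid
    out = np.full(len(times), np.nan)
    if len(fixes) == 0:
        return out
    ft = fixes["timestamp"].astype("int64").to_numpy()
    fx = fixes["x"].to_numpy(dtype=float)
    fy = fixes["y"].to_numpy(dtype=float)
    tol_ns = tolerance_min * 60e9
    for i, t in enumerate(times):
        tn = pd.Timestamp(t).value
        j = np.searchsorted(ft, tn)
        best, bd = -1, np.inf
        for k in (j - 1, j):
            if 0 <= k < len(ft):
                d = abs(ft[k] - tn)
                if d < bd:
                    best, bd = k, d
        if best >= 0 and bd <= tol_ns:
            out[i] = float(np.hypot(fx[best] - rx, fy[best] - ry))
    return out


def displacement_profile(
    events: Iterable,
    trajectories: dict[str, Trajectory],
    hunts_by_id: dict[str, "object"],
    config: AnalysisConfig | None = None,
) -> pd.DataFrame:
    """Net-displacement dynamics over the five days centred on each hunt.

    The window runs from 08:00 local two days before the hunt to 08:00 three
    days after, tiled into day (08:00-18:00) and night (18:00-08:00) periods.
    For each event the per-period median distance of its valid fixes from the
    encounter point is taken; medians and quartiles are then aggregated across
    events separately for the fleeing and staying groups.  Periods ending
    before hunt start are labelled ``baseline``.

    Returns a frame with columns group, day_offset, period, phase,
    median_m, q1_m, q3_m, n_events.
    """
    config = config or AnalysisConfig()
    tz = ZoneInfo(config.study_timezone)
    rows: dict[tuple, list[float]] = {}
    groups_seen = set()
    for ev in events:
        if ev.classification is None:
            continue
        group = ev.classification
        groups_seen.add(group)
        traj = trajectories[ev.individual_id]
        hunt = hunts_by_id[ev.hunt_id]
        day0 = hunt.start.tz_convert(tz).normalize()
        for off in range(-2, 3):
            day = day0 + pd.Timedelta(days=off)
            periods = {
                "day": (
                    day + pd.Timedelta(hours=config.day_start.hour),
                    day + pd.Timedelta(hours=config.day_end.hour),
                ),
                "night": (
                    day + pd.Timedelta(hours=config.day_end.hour),
                    day + pd.Timedelta(days=1, hours=config.day_start.hour),
                ),
            }
            for label, (lo, hi) in periods.items():
                lo_u, hi_u = lo.tz_convert("UTC"), hi.tz_convert("UTC")
                fixes = traj.valid
                ts = fixes["timestamp"]
                sub = fixes[(ts >= lo_u) & (ts < hi_u)]
                if len(sub) == 0:
                    continue
                d = np.hypot(
                    sub["x"].to_numpy() - ev.encounter_point[0],
                    sub["y"].to_numpy() - ev.encounter_point[1],
                )
                phase = "baseline" if hi_u <= hunt.start else "response"
                rows.setdefault((group, off, label, phase), []).append(
                    float(np.median(d))
                )
    out = []
    for (group, off, label, phase), vals in sorted(rows.items()):
        v = np.asarray(vals)
        out.append(
            {
                "group": group,
                "day_offset": off,
                "period": label,
                "phase": phase,
                "median_m": float(np.median(v)),
                "q1_m": float(np.percentile(v, 25)),
                "q3_m": float(np.percentile(v, 75)),
                "n_events": len(v),
            }
        )
    return pd.DataFrame(
        out,
        columns=[
            "group",
            "day_offset",
            "period",
            "phase",
            "median_m",
            "q1_m",
            "q3_m",
            "n_events",
        ],
    )
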