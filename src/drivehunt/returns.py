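"""Censored return times to the hunted area and their Kaplan-Meier curves.

For every hunting event two durations are built: the post-hunt return time
(from the animal's flight out of the area until its first fix back inside)
and a control duration measured on a reversed time scale before the hunt
(the outside spell separating the presence spell containing hunt start from
the previous presence).  Both are right-censored at a 144-hour horizon —
six days, chosen so consecutive weekly hunts do not overlap.  Return times
under 72 h define the short-return dichotomy used by the logistic model.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from shapely.geometry import Point
from shapely.prepared import prep

from .config import AnalysisConfig
from .events import HuntEvent, _hunt_polygon
from .io import DriveHunt, HuntedArea, Trajectory

logger = logging.getLogger("drivehunt")


@dataclass
class ReturnRecord:
    """One censored duration: a post-hunt return or its pre-hunt control."""

    event_id: str
    condition: str  # 'post_hunt' | 'control'
    duration_h: float
    censored: bool
    individual_id: str | None = None

    def __post_init__(self) -> None:
        if self.duration_h <= 0:
            raise ValueError("duration must be positive")
        if self.condition not in ("post_hunt", "control"):
            raise ValueError("condition must be 'post_hunt' or 'control'")


@dataclass
class SurvivalCurve:
    """Product-limit estimate of staying away from the area.

    ``survival[i]`` is S(t) just after ``times[i]``; the 95% band is the
    Greenwood/log-log band of lifelines.  ``median_h`` is the first time S
    drops to 0.5 or below (inf if never reached).
    """

    times: np.ndarray
    survival: np.ndarray
    ci_lower: np.ndarray
    ci_upper: np.ndarray
    n_at_risk: np.ndarray
    median_h: float
    n_records: int


def _presence(traj: Trajectory, area: HuntedArea, config: AnalysisConfig):
    """(timestamps int64 ns, inside flags) of valid fixes."""
    poly = prep(_hunt_polygon(area, config))
    fixes = traj.valid
    ts = fixes["timestamp"].astype("int64").to_numpy()
    inside = np.fromiter(
        (poly.covers(Point(x, y)) for x, y in zip(fixes["x"], fixes["y"])),
        dtype=bool,
        count=len(fixes),
    )
    return ts, inside


_H = 3600e9  # ns per hour


def forward_return_time(
    event: HuntEvent,
    traj: Trajectory,
    hunt: DriveHunt,
    area: HuntedArea,
    config: AnalysisConfig | None = None,
) -> ReturnRecord | None:
    """Post-hunt return time: clock starts at the first valid fix outside the
    polygon at/after hunt start (for stayers this is their first exit after
    hunt end) and stops at the first return, censored at the horizon.

    A return needs ``min_dwell_fixes`` consecutive inside fixes.  Returns
    None when the animal never exits within the horizon (logged).
    """
    config = config or AnalysisConfig()
    ts, inside = _presence(traj, area, config)
    start = hunt.start.value
    horizon_ns = config.censor_horizon_h * _H
    after = ts >= start
    idx = np.nonzero(after & ~inside)[0]
    idx = idx[ts[idx] <= start + horizon_ns]
    if len(idx) == 0:
        logger.info("forward_return_time: %s never exited within horizon", event.event_id)
        return None
    exit_t = ts[idx[0]]
    # first inside run of length >= min_dwell after exit
    k = config.min_dwell_fixes
    cand = np.nonzero((ts > exit_t) & inside)[0]
    ret_t = None
    for i in cand:
        if all(j < len(inside) and inside[j] for j in range(i, i + k)):
            ret_t = ts[i]
            break
    if ret_t is None or (ret_t - exit_t) / _H > config.censor_horizon_h:
        return ReturnRecord(
            event.event_id, "post_hunt", config.censor_horizon_h, True,
            event.individual_id,
        )
    return ReturnRecord(
        event.event_id, "post_hunt", (ret_t - exit_t) / _H, False, event.individual_id
    )


def control_return_time(
    event: HuntEvent,
    traj: Trajectory,
    hunt: DriveHunt,
    area: HuntedArea,
    config: AnalysisConfig | None = None,
) -> ReturnRecord | None:
    """Control duration on a reversed time scale before the hunt.

    Scanning back from hunt start: the entry fix of the presence spell
    containing the start, then the preceding exit fix (last inside fix before
    the outside gap); duration = entry - exit.  Censored at the horizon when
    the animal was continuously present for the prior six days or the exit
    lies beyond it.  None (dropped, logged) on insufficient history.
    """
    config = config or AnalysisConfig()
    ts, inside = _presence(traj, area, config)
    start = hunt.start.value
    horizon_ns = config.censor_horizon_h * _H
    before = np.nonzero(ts <= start)[0]
    if len(before) == 0 or ts[0] > start - horizon_ns:
        logger.info("control_return_time: %s lacks pre-hunt history", event.event_id)
        return None
    i = before[-1]
    # the fix nearest the start may jitter outside; anchor on the latest
    # inside fix at/before hunt start
    while i >= 0 and not inside[i]:
        i -= 1
    if i < 0:
        logger.info("control_return_time: %s not present before hunt", event.event_id)
        return None
    # walk back through the presence spell containing hunt start
    while i >= 0 and inside[i]:
        i -= 1
    if i < 0:
        # continuously present back to the start of the record
        if ts[0] <= start - horizon_ns:
            return ReturnRecord(
                event.event_id, "control", config.censor_horizon_h, True,
                event.individual_id,
            )
        logger.info("control_return_time: %s no pre-hunt exit in data", event.event_id)
        return None
    entry_t = ts[i + 1]
    # i indexes the last outside fix of the gap; continue back to the exit fix
    while i >= 0 and not inside[i]:
        i -= 1
    if i < 0:
        # outside since the start of the record
        if ts[0] <= start - horizon_ns:
            return ReturnRecord(
                event.event_id, "control", config.censor_horizon_h, True,
                event.individual_id,
            )
        logger.info("control_return_time: %s insufficient history", event.event_id)
        return None
    exit_t = ts[i]
    if exit_t < start - horizon_ns or (entry_t - exit_t) / _H > config.censor_horizon_h:
        return ReturnRecord(
            event.event_id, "control", config.censor_horizon_h, True, event.individual_id
        )
    return ReturnRecord(
        event.event_id, "control", (entry_t - exit_t) / _H, False, event.individual_id
    )


def build_return_records(
    events: Iterable[HuntEvent],
    trajectories: Mapping[str, Trajectory],
    hunts_by_id: Mapping[str, DriveHunt],
    areas: Mapping[str, HuntedArea],
    config: AnalysisConfig | None = None,
) -> list[ReturnRecord]:
    """Post-hunt and control records for every classified event."""
    config = config or AnalysisConfig()
    out: list[ReturnRecord] = []
    for ev in events:
        if ev.classification is None:
            continue
        traj = trajectories[ev.individual_id]
        hunt = hunts_by_id[ev.hunt_id]
        area = areas[ev.area_id]
        for fn in (forward_return_time, control_return_time):
            rec = fn(ev, traj, hunt, area, config)
            if rec is not None:
                out.append(rec)
    return out


def km_estimate(
    records: Iterable[ReturnRecord], condition: str | None = None
) -> SurvivalCurve:
    """Kaplan-Meier estimate of the probability of not yet having returned.

    Censored records leave the risk set after their time; the band is the
    default lifelines 95% interval.  All-censored input yields S = 1
    throughout.
    """
    recs = [r for r in records if condition is None or r.condition == condition]
    if not recs:
        raise ValueError("no records for the requested condition")
    durations = np.array([r.duration_h for r in recs])
    observed = np.array([not r.censored for r in recs])
    kmf = KaplanMeierFitter()
    kmf.fit(durations, event_observed=observed)
    sf = kmf.survival_function_
    ci = kmf.confidence_interval_survival_function_
    times = sf.index.to_numpy(dtype=float)
    surv = sf.iloc[:, 0].to_numpy()
    at_risk = kmf.event_table["at_risk"].reindex(sf.index).to_numpy(dtype=float)
    median = float(kmf.median_survival_time_)
    return SurvivalCurve(
        times=times,
        survival=surv,
        ci_lower=ci.iloc[:, 0].to_numpy(),
        ci_upper=ci.iloc[:, 1].to_numpy(),
        n_at_risk=at_risk,
        median_h=median,
        n_records=len(recs),
    )


def short_return_indicator(
    record: ReturnRecord, threshold_h: float = 72.0
) -> int | None:
    """Binary short-return coding: 0 for a return under the threshold, 1 for
    a longer (or censored-beyond-threshold) one, None when censoring before
    the threshold leaves it unresolved.  Exactly-threshold durations code 1."""
    if record.censored:
        return 1 if record.duration_h >= threshold_h else None
    return 0 if record.duration_h < threshold_h else 1


def returns_table(
    records: Iterable[ReturnRecord], threshold_h: float = 72.0
) -> pd.DataFrame:
    """Flatten records, adding the short-return indicator and the Hunt dummy
    (1 = post-hunt, 0 = control)."""
    rows = []
    for r in records:
        rows.append(
            {
                "event_id": r.event_id,
                "individual_id": r.individual_id,
                "condition": r.condition,
                "hunt": int(r.condition == "post_hunt"),
                "duration_h": r.duration_h,
                "censored": r.censored,
                "short_return": short_return_indicator(r, threshold_h),
            }
        )
    return pd.DataFrame(rows)


def bimodality_summary(
    records: Iterable[ReturnRecord],
    bin_width_h: float = 12.0,
    include_censored: bool = True,
) -> dict:
    """Descriptive screen for the bimodal shape of return times: a histogram
    plus the ratio of the deepest internal valley to the smaller flanking
    peak (values well under 1 indicate two modes).  Censored durations are
    included at the horizon by default — the long-return mode consists
    largely of animals that never re-entered within the observation window."""
    durs = np.array(
        [r.duration_h for r in records if include_censored or not r.censored]
    )
    if len(durs) == 0:
        return {"n": 0, "bins": [], "counts": [], "valley_ratio": float("nan")}
    edges = np.arange(0, durs.max() + bin_width_h, bin_width_h)
    counts, edges = np.histogram(durs, bins=edges)
    ratio = float("nan")
    if len(counts) >= 3:
        best = np.inf
        for i in range(1, len(counts) - 1):
            left = counts[:i].max()
            right = counts[i + 1 :].max()
            if left > 0 and right > 0:
                best = min(best, counts[i] / min(left, right))
        if np.isfinite(best):
            ratio = float(best)
    return {
        "n": int(len(durs)),
        "bins": edges.tolist(),
        "counts": counts.tolist(),
        "valley_ratio": ratio,
    }
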