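"""Hunting-event detection, flee/stay classification and the immediate and
delayed distance responses.

A hunting event is one monitored individual present inside the hunted-area
polygon at the start of one drive hunt.  The immediate response is *fleeing*
if any valid fix during the hunt lies strictly outside the polygon (the
animal crossed the shooting line) and *staying* otherwise; a fix on the
boundary counts as inside.  DistI is the cumulative two-minute step distance
over the hunt window; DistD the cumulative hourly step distance from the
hunt (start, by default) to the first subsequent 08:00 local dawn.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping
from zoneinfo import ZoneInfo

import numpy as np
import pandas as pd
from shapely.prepared import prep

from .config import AnalysisConfig
from .io import DriveHunt, HuntedArea, Trajectory
from .metrics import build_steps, cumulative_distance, max_speed, sinuosity
from .metrics import UndefinedMetricError

logger = logging.getLogger("drivehunt")


@dataclass
class HuntEvent:
    """One individual exposed to one drive hunt, with its responses."""

    event_id: str
    individual_id: str
    hunt_id: str
    area_id: str
    encounter_point: tuple[float, float]
    encounter_time: pd.Timestamp
    classification: str | None = None  # 'fleeing' | 'staying' | None
    dist_immediate: float | None = None
    dist_delayed: float | None = None
    delayed_complete: bool = True
    speed_max_kmh: float | None = None
    sinuosity: float | None = None
    n_gap_steps: int = 0
    # covariates
    bush: float | None = None
    fam: float | None = None
    dogs_per_ha: float | None = None
    beaters_per_ha: float | None = None
    gunshots: int | None = None


def _hunt_polygon(area: HuntedArea, config: AnalysisConfig):
    poly = area.polygon
    if config.boundary_buffer_m:
        poly = poly.buffer(config.boundary_buffer_m)
    return poly


def _fix_near(traj: Trajectory, when: pd.Timestamp, tolerance_min: float):
    """Nearest valid fix within ``tolerance_min`` of ``when``, or None."""
    fixes = traj.valid
    if len(fixes) == 0:
        return None
    ts = fixes["timestamp"].astype("int64").to_numpy()
    tn = pd.Timestamp(when).value
    j = int(np.searchsorted(ts, tn))
    best, bd = None, tolerance_min * 60e9
    for k in (j - 1, j):
        if 0 <= k < len(ts) and abs(ts[k] - tn) <= bd:
            best, bd = k, abs(ts[k] - tn)
    if best is None:
        return None
    return fixes.iloc[best]


def detect_events(
    trajectories: Mapping[str, Trajectory],
    hunts: Iterable[DriveHunt],
    areas: Mapping[str, HuntedArea],
    config: AnalysisConfig | None = None,
) -> list[HuntEvent]:
    """One event per (individual, hunt) whose fix nearest hunt start (within
    half the intensive fix interval) lies inside the hunted polygon.

    Membership is decided at hunt start; animals entering mid-hunt are not
    events.  Individuals with no valid fix near the start are skipped with a
    log line.  Order-independent over individuals.
    """
    config = config or AnalysisConfig()
    tol_ns = config.immediate_fix_interval_min * 30e9  # half interval in ns
    from shapely.geometry import Point

    cache = {}
    for ind in sorted(trajectories):
        v = trajectories[ind].valid
        cache[ind] = (
            v["timestamp"].astype("int64").to_numpy(),
            v["x"].to_numpy(dtype=float),
            v["y"].to_numpy(dtype=float),
            v["timestamp"].to_numpy(),
        )
    out: list[HuntEvent] = []
    for hunt in hunts:
        area = areas[hunt.area_id]
        poly = prep(_hunt_polygon(area, config))
        tn = hunt.start.value
        for ind, (ts, xs, ys, raw_ts) in cache.items():
            if len(ts) == 0:
                continue
            j = int(np.searchsorted(ts, tn))
            best, bd = -1, tol_ns
            for k in (j - 1, j):
                if 0 <= k < len(ts) and abs(ts[k] - tn) <= bd:
                    best, bd = k, abs(ts[k] - tn)
            if best < 0:
                logger.debug(
                    "detect_events: no valid fix near start of %s for %s",
                    hunt.hunt_id,
                    ind,
                )
                continue
            if poly.covers(Point(xs[best], ys[best])):
                enc_t = pd.Timestamp(raw_ts[best])
                if enc_t.tzinfo is None:
                    enc_t = enc_t.tz_localize("UTC")
                out.append(
                    HuntEvent(
                        event_id=f"{hunt.hunt_id}:{ind}",
                        individual_id=ind,
                        hunt_id=hunt.hunt_id,
                        area_id=hunt.area_id,
                        encounter_point=(float(xs[best]), float(ys[best])),
                        encounter_time=enc_t,
                    )
                )
    return out


def classify_event(
    event: HuntEvent,
    traj: Trajectory,
    hunt: DriveHunt,
    area: HuntedArea,
    config: AnalysisConfig | None = None,
) -> str | None:
    """Flee/stay classification: fleeing iff any valid fix strictly outside
    the polygon occurs within [hunt.start, hunt.end].

    A pure function of geometry: a single excursion suffices for fleeing even
    if the animal re-enters.  Events with fewer than two valid fixes, or with
    less than half the expected fixes, in the hunt window are left
    unclassified (None).
    """
    config = config or AnalysisConfig()
    fixes = traj.valid
    ts = fixes["timestamp"]
    sub = fixes[(ts >= hunt.start) & (ts <= hunt.end)]
    expected = (
        (hunt.end - hunt.start).total_seconds() / 60.0 / config.immediate_fix_interval_min
    ) + 1
    if len(sub) < 2 or len(sub) < 0.5 * expected:
        event.classification = None
        return None
    poly = prep(_hunt_polygon(area, config))
    from shapely.geometry import Point

    outside = [
        not poly.covers(Point(x, y))
        for x, y in zip(sub["x"].to_numpy(), sub["y"].to_numpy())
    ]
    event.classification = "fleeing" if any(outside) else "staying"
    return event.classification


def immediate_distance(
    event: HuntEvent,
    traj: Trajectory,
    hunt: DriveHunt,
    config: AnalysisConfig | None = None,
) -> float:
    """Cumulative two-minute step distance over the hunt window (DistI)."""
    config = config or AnalysisConfig()
    steps = build_steps(
        traj,
        (hunt.start, hunt.end),
        config.immediate_fix_interval_min,
        config.gap_tolerance_factor,
    )
    event.n_gap_steps = steps.n_gap_steps
    try:
        event.speed_max_kmh = max_speed(steps)
    except UndefinedMetricError:
        event.speed_max_kmh = None
    try:
        event.sinuosity = sinuosity(steps)
    except UndefinedMetricError:
        event.sinuosity = None
    event.dist_immediate = cumulative_distance(steps)
    return event.dist_immediate


def first_dawn_after(when: pd.Timestamp, config: AnalysisConfig) -> pd.Timestamp:
    """First 08:00 local strictly after ``when`` (UTC in, UTC out)."""
    tz = ZoneInfo(config.study_timezone)
    local = when.tz_convert(tz)
    dawn = local.normalize() + pd.Timedelta(hours=config.dawn_hour.hour, minutes=config.dawn_hour.minute)
    if dawn <= local:
        dawn += pd.Timedelta(days=1)
    return dawn.tz_convert("UTC")


def delayed_distance(
    event: HuntEvent,
    traj: Trajectory,
    hunt: DriveHunt,
    config: AnalysisConfig | None = None,
) -> float:
    """Cumulative hourly step distance from the hunt to the first following
    dawn (DistD).

    Positions are sampled at the hourly grid anchored on the configured
    origin (hunt start by default; switchable to hunt end), taking the valid
    fix nearest each grid time within half an hour.  If the trajectory ends
    before dawn the value is flagged partial (``event.delayed_complete``).
    """
    config = config or AnalysisConfig()
    origin = hunt.start if config.delayed_from == "hunt_start" else hunt.end
    dawn = first_dawn_after(hunt.end, config)
    times = pd.date_range(origin, dawn, freq=pd.Timedelta(minutes=config.delayed_fix_interval_min))
    if times[-1] < dawn:
        times = times.append(pd.DatetimeIndex([dawn]))
    tol = config.delayed_fix_interval_min / 2.0
    pos = []
    for t in times:
        fix = _fix_near(traj, t, tol)
        pos.append((fix["x"], fix["y"]) if fix is not None else None)
    dist = 0.0
    last = None
    n_defined = 0
    for p in pos:
        if p is None:
            continue
        n_defined += 1
        if last is not None:
            dist += float(np.hypot(p[0] - last[0], p[1] - last[1]))
        last = p
    event.delayed_complete = pos[-1] is not None and n_defined >= 0.5 * len(times)
    event.dist_delayed = dist
    return dist


def compute_events(
    trajectories: Mapping[str, Trajectory],
    hunts: Iterable[DriveHunt],
    areas: Mapping[str, HuntedArea],
    config: AnalysisConfig | None = None,
    fam: Mapping[tuple[str, str], float] | None = None,
) -> list[HuntEvent]:
    """Full event stage: detect, classify, distances and covariates.

    ``fam`` optionally maps (individual_id, area_id) to a familiarity index
    (e.g. from :func:`drivehunt.familiarity.familiarity_table`).
    """
    config = config or AnalysisConfig()
    hunts = list(hunts)
    by_id = {h.hunt_id: h for h in hunts}
    events = detect_events(trajectories, hunts, areas, config)
    for ev in events:
        hunt = by_id[ev.hunt_id]
        area = areas[ev.area_id]
        traj = trajectories[ev.individual_id]
        classify_event(ev, traj, hunt, area, config)
        immediate_distance(ev, traj, hunt, config)
        delayed_distance(ev, traj, hunt, config)
        ev.bush = area.bush_fraction
        ev.dogs_per_ha = hunt.dogs_per_ha(area)
        ev.beaters_per_ha = hunt.beaters_per_ha(area)
        ev.gunshots = hunt.n_gunshots
        if fam is not None:
            ev.fam = fam.get((ev.individual_id, ev.area_id))
    return events


def events_table(events: Iterable[HuntEvent]) -> pd.DataFrame:
    """Flatten events to the table consumed by the model-fitting stage."""
    rows = []
    for ev in events:
        rows.append(
            {
                "event_id": ev.event_id,
                "individual_id": ev.individual_id,
                "hunt_id": ev.hunt_id,
                "area_id": ev.area_id,
                "classification": ev.classification,
                "encounter_x": ev.encounter_point[0],
                "encounter_y": ev.encounter_point[1],
                "speed_max_kmh": ev.speed_max_kmh,
                "sinuosity": ev.sinuosity,
                "dist_immediate_m": ev.dist_immediate,
                "dist_delayed_m": ev.dist_delayed,
                "delayed_complete": ev.delayed_complete,
                "n_gap_steps": ev.n_gap_steps,
                "bush": ev.bush,
                "fam": ev.fam,
                "dogs_per_ha": ev.dogs_per_ha,
                "beaters_per_ha": ev.beaters_per_ha,
                "gunshots": ev.gunshots,
            }
        )
    return pd.DataFrame(rows)
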