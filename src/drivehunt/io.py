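"""Data model and text-file readers/writers.

Relocations and hunt logs are comma-separated UTF-8 text with a header;
hunted areas are a GeoJSON FeatureCollection in a projected metric CRS.
Timestamps are stored time-zone aware in UTC; hunt-log clock times are
interpreted in the study time zone.
"""
from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping
from zoneinfo import ZoneInfo

import numpy as np
import pandas as pd
from shapely.geometry import mapping, shape
from shapely.geometry.base import BaseGeometry

from .config import AnalysisConfig

logger = logging.getLogger("drivehunt")

RELOCATION_COLUMNS = ("individual_id", "timestamp", "x", "y", "fix_ok")
HUNT_LOG_COLUMNS = (
    "hunt_id",
    "area_id",
    "date",
    "start",
    "end",
    "n_beaters",
    "n_dogs",
    "n_shooters",
    "n_gunshots",
    "bush_fraction",
)


class FormatError(ValueError):
    """A required column or structural element is missing from an input file."""


class ValidationError(ValueError):
    """Input rows violate a data-model invariant (e.g. duplicate timestamps)."""


class DanglingReferenceError(KeyError):
    """A hunt-log row references an area id with no polygon feature."""


class GeometryError(ValueError):
    """An area polygon is invalid (self-intersecting or empty)."""


@dataclass
class Trajectory:
    """Time-ordered GPS fixes of one individual.

    ``fixes`` has columns ``timestamp`` (tz-aware UTC), ``x``, ``y`` (metres)
    and ``fix_ok``.  Rows with ``fix_ok == False`` are retained for regime
    reporting but excluded from every metric computation.
    """

    individual_id: str
    fixes: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.fixes.reset_index(drop=True)
        ts = pd.to_datetime(df["timestamp"], utc=True)
        if ts.duplicated().any():
            dup = ts[ts.duplicated()].unique()
            raise ValidationError(
                f"duplicate timestamps for individual {self.individual_id!r}: "
                f"{list(dup[:5])}"
            )
        order = ts.argsort()
        df = df.iloc[order].reset_index(drop=True)
        df["timestamp"] = ts.iloc[order].to_numpy()
        df["fix_ok"] = df["fix_ok"].astype(bool)
        ok = df["fix_ok"].to_numpy()
        bad = ok & ~(
            np.isfinite(df["x"].to_numpy(dtype=float))
            & np.isfinite(df["y"].to_numpy(dtype=float))
        )
        if bad.any():
            raise ValidationError(
                f"non-finite coordinates on fix_ok rows for {self.individual_id!r}"
            )
        self.fixes = df

    @property
    def valid(self) -> pd.DataFrame:
        """Fixes usable for metrics (``fix_ok`` true)."""
        return self.fixes[self.fixes["fix_ok"]]

    @property
    def span(self) -> tuple[pd.Timestamp, pd.Timestamp]:
        return self.fixes["timestamp"].iloc[0], self.fixes["timestamp"].iloc[-1]

    def __len__(self) -> int:
        return len(self.fixes)


@dataclass
class HuntedArea:
    """A drive-hunted polygon with its habitat covariate.

    ``bush_fraction`` is the proportion of the area under dense understorey
    (shelter during the drive), in [0, 1].
    """

    area_id: str
    polygon: BaseGeometry
    bush_fraction: float | None = None

    def __post_init__(self) -> None:
        if self.polygon.is_empty or not self.polygon.is_valid:
            raise GeometryError(f"invalid polygon for area {self.area_id!r}")
        if self.bush_fraction is not None and not 0.0 <= self.bush_fraction <= 1.0:
            raise ValidationError(
                f"bush_fraction out of [0, 1] for area {self.area_id!r}"
            )

    @property
    def area_ha(self) -> float:
        return self.polygon.area / 1e4


@dataclass
class DriveHunt:
    """One drive: a hunted area swept by beaters and dogs toward a shooting line."""

    hunt_id: str
    area_id: str
    start: pd.Timestamp
    end: pd.Timestamp
    n_beaters: int
    n_dogs: int
    n_shooters: int
    n_gunshots: int

    def __post_init__(self) -> None:
        self.start = pd.Timestamp(self.start)
        self.end = pd.Timestamp(self.end)
        if self.start.tzinfo is None or self.end.tzinfo is None:
            raise ValidationError(f"hunt {self.hunt_id!r}: timestamps must be tz-aware")
        self.start = self.start.tz_convert("UTC")
        self.end = self.end.tz_convert("UTC")
        if not self.start < self.end:
            raise ValidationError(f"hunt {self.hunt_id!r}: start must precede end")
        for name in ("n_beaters", "n_dogs", "n_shooters", "n_gunshots"):
            if getattr(self, name) < 0:
                raise ValidationError(f"hunt {self.hunt_id!r}: {name} negative")

    def dogs_per_ha(self, area: HuntedArea) -> float:
        return self.n_dogs / area.area_ha

    def beaters_per_ha(self, area: HuntedArea) -> float:
        return self.n_beaters / area.area_ha


# ---------------------------------------------------------------------------
# relocations


def read_relocations(
    path: str | Path, config: AnalysisConfig | None = None
) -> dict[str, Trajectory]:
    """Read a relocation table into one :class:`Trajectory` per individual.

    Malformed rows (unparseable timestamp, or non-finite coordinates flagged
    fix_ok) are dropped with a logged count; duplicate ``(individual,
    timestamp)`` pairs raise :class:`ValidationError`.
    """
    df = pd.read_csv(path)
    missing = [c for c in RELOCATION_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"relocation file missing column(s): {', '.join(missing)}")
    n_raw = len(df)
    ts = pd.to_datetime(df["timestamp"], utc=True, errors="coerce", format="ISO8601")
    keep = ts.notna()
    df = df[keep].copy()
    df["timestamp"] = ts[keep]
    df["fix_ok"] = _coerce_bool(df["fix_ok"])
    df["x"] = pd.to_numeric(df["x"], errors="coerce")
    df["y"] = pd.to_numeric(df["y"], errors="coerce")
    bad = df["fix_ok"] & ~(np.isfinite(df["x"]) & np.isfinite(df["y"]))
    df = df[~bad]
    dropped = n_raw - len(df)
    if dropped:
        logger.warning("read_relocations: dropped %d malformed row(s)", dropped)
    out: dict[str, Trajectory] = {}
    for ind, sub in df.groupby("individual_id", sort=True):
        out[str(ind)] = Trajectory(
            str(ind), sub[["timestamp", "x", "y", "fix_ok"]].reset_index(drop=True)
        )
    return out


def _coerce_bool(s: pd.Series) -> pd.Series:
    if s.dtype == bool:
        return s
    return s.astype(str).str.strip().str.lower().isin(("true", "1", "t", "yes"))


def write_relocations(trajectories: Mapping[str, Trajectory], path: str | Path) -> None:
    """Write trajectories back to the delimited format read by
    :func:`read_relocations` (timestamps to the second, coordinates to 1e-6 m)."""
    frames = []
    for ind in trajectories:
        t = trajectories[ind]
        df = t.fixes.copy()
        df.insert(0, "individual_id", t.individual_id)
        frames.append(df)
    allf = pd.concat(frames, ignore_index=True)
    allf["timestamp"] = allf["timestamp"].dt.strftime("%Y-%m-%dT%H:%M:%S%z")
    allf.to_csv(path, index=False, float_format="%.6f")


# ---------------------------------------------------------------------------
# hunts and areas


def read_areas(path: str | Path) -> dict[str, HuntedArea]:
    """Read hunted-area polygons from a GeoJSON FeatureCollection.

    Each feature must carry an ``area_id`` property; ``bush_fraction`` is
    attached later from the hunt log.
    """
    with open(path, encoding="utf-8") as fh:
        gj = json.load(fh)
    if gj.get("type") != "FeatureCollection":
        raise FormatError("areas file is not a GeoJSON FeatureCollection")
    areas: dict[str, HuntedArea] = {}
    for feat in gj.get("features", []):
        props = feat.get("properties") or {}
        if "area_id" not in props:
            raise FormatError("area feature missing 'area_id' property")
        aid = str(props["area_id"])
        geom = shape(feat["geometry"])
        if not geom.is_valid or geom.is_empty:
            raise GeometryError(f"invalid polygon geometry for feature {aid!r}")
        bush = props.get("bush_fraction")
        areas[aid] = HuntedArea(aid, geom, None if bush is None else float(bush))
    return areas


def write_areas(areas: Mapping[str, HuntedArea], path: str | Path) -> None:
    feats = []
    for aid in areas:
        a = areas[aid]
        feats.append(
            {
                "type": "Feature",
                "properties": {
                    "area_id": a.area_id,
                    "bush_fraction": a.bush_fraction,
                    "area_ha": a.area_ha,
                },
                "geometry": mapping(a.polygon),
            }
        )
    with open(path, "w", encoding="utf-8") as fh:
        json.dump({"type": "FeatureCollection", "features": feats}, fh)


def read_hunts(
    hunt_log_path: str | Path,
    areas_path: str | Path,
    config: AnalysisConfig | None = None,
) -> tuple[list[DriveHunt], dict[str, HuntedArea]]:
    """Read the drive-hunt log and its area polygons.

    ``date`` is ``YYYY-MM-DD`` and ``start``/``end`` are ``HH:MM[:SS]`` clock
    times in the study time zone (or full ISO timestamps with an offset).
    Every ``area_id`` must resolve to a polygon feature.
    """
    config = config or AnalysisConfig()
    tz = ZoneInfo(config.study_timezone)
    areas = read_areas(areas_path)
    log = pd.read_csv(hunt_log_path, dtype={"hunt_id": str, "area_id": str})
    missing = [c for c in HUNT_LOG_COLUMNS if c not in log.columns]
    if missing:
        raise FormatError(f"hunt log missing column(s): {', '.join(missing)}")
    hunts: list[DriveHunt] = []
    for _, row in log.iterrows():
        aid = str(row["area_id"])
        if aid not in areas:
            raise DanglingReferenceError(
                f"hunt {row['hunt_id']!r} references unknown area {aid!r}"
            )
        start = _combine(row["date"], row["start"], tz)
        end = _combine(row["date"], row["end"], tz)
        hunts.append(
            DriveHunt(
                hunt_id=str(row["hunt_id"]),
                area_id=aid,
                start=start,
                end=end,
                n_beaters=int(row["n_beaters"]),
                n_dogs=int(row["n_dogs"]),
                n_shooters=int(row["n_shooters"]),
                n_gunshots=int(row["n_gunshots"]),
            )
        )
        bush = float(row["bush_fraction"])
        area = areas[aid]
        if area.bush_fraction is None:
            area.bush_fraction = bush
        elif abs(area.bush_fraction - bush) > 1e-9:
            raise ValidationError(
                f"inconsistent bush_fraction for area {aid!r} across hunt-log rows"
            )
    return hunts, areas


def _combine(date: object, clock: object, tz: ZoneInfo) -> pd.Timestamp:
    s = str(clock)
    if "T" in s or "+" in s or s.endswith("Z"):
        return pd.Timestamp(s).tz_convert("UTC")
    local = pd.Timestamp(f"{date} {s}").tz_localize(tz)
    return local.tz_convert("UTC")


def write_hunts(
    hunts: Iterable[DriveHunt],
    areas: Mapping[str, HuntedArea],
    path: str | Path,
    config: AnalysisConfig | None = None,
) -> None:
    config = config or AnalysisConfig()
    tz = ZoneInfo(config.study_timezone)
    rows = []
    for h in hunts:
        start_l = h.start.tz_convert(tz)
        end_l = h.end.tz_convert(tz)
        rows.append(
            {
                "hunt_id": h.hunt_id,
                "area_id": h.area_id,
                "date": start_l.strftime("%Y-%m-%d"),
                "start": start_l.strftime("%H:%M:%S"),
                "end": end_l.strftime("%H:%M:%S"),
                "n_beaters": h.n_beaters,
                "n_dogs": h.n_dogs,
                "n_shooters": h.n_shooters,
                "n_gunshots": h.n_gunshots,
                "bush_fraction": areas[h.area_id].bush_fraction,
            }
        )
    pd.DataFrame(rows, columns=list(HUNT_LOG_COLUMNS)).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# fix-regime reporting


def regime_report(
    traj: Trajectory,
    hunts: Iterable[DriveHunt],
    config: AnalysisConfig | None = None,
) -> dict[str, dict[str, float]]:
    """Achieved fix-success per GPS duty-cycle regime.

    The intensive regime schedules one fix every ``immediate_fix_interval_min``
    minutes from 08:00 to 20:00 local on hunt days; the routine regime one fix
    per ``delayed_fix_interval_min`` on all other days.  A scheduled fix counts
    as achieved when a fix_ok relocation lies within half the nominal interval
    of it.  Regimes with no scheduled fixes inside the trajectory span are
    reported as absent.
    """
    if len(traj) == 0:
        raise ValidationError("regime_report requires a non-empty trajectory")
    config = config or AnalysisConfig()
    tz = ZoneInfo(config.study_timezone)
    t0, t1 = traj.span
    hunt_dates = {h.start.tz_convert(tz).date() for h in hunts}
    valid_ns = traj.valid["timestamp"].astype("int64").to_numpy()
    valid_ns.sort()

    report: dict[str, dict[str, float]] = {}
    for regime, interval_min in (
        ("intensive", config.immediate_fix_interval_min),
        ("routine", config.delayed_fix_interval_min),
    ):
        sched = _schedule(t0, t1, hunt_dates, regime, interval_min, tz)
        if len(sched) == 0:
            report[regime] = {"n_scheduled": 0, "n_achieved": 0, "success_rate": float("nan")}
            continue
        tol_ns = int(interval_min * 30 * 1e9)  # half interval in ns
        sched_ns = sched.astype("int64")
        idx = np.searchsorted(valid_ns, sched_ns)
        achieved = np.zeros(len(sched_ns), dtype=bool)
        for off in (-1, 0):
            j = np.clip(idx + off, 0, max(len(valid_ns) - 1, 0))
            if len(valid_ns):
                achieved |= np.abs(valid_ns[j] - sched_ns) <= tol_ns
        rate = float(achieved.mean())
        report[regime] = {
            "n_scheduled": int(len(sched_ns)),
            "n_achieved": int(achieved.sum()),
            "success_rate": rate,
            "below_floor": bool(rate < config.regime_success_floor),
        }
    return report


def _schedule(t0, t1, hunt_dates, regime, interval_min, tz):
    """Scheduled fix timestamps (UTC int64-convertible DatetimeIndex)."""
    days = pd.date_range(
        t0.tz_convert(tz).normalize(), t1.tz_convert(tz).normalize(), freq="D", tz=tz
    )
    chunks = []
    for day in days:
        is_hunt = day.date() in hunt_dates
        if regime == "intensive":
            if not is_hunt:
                continue
            lo = day + pd.Timedelta(hours=8)
            hi = day + pd.Timedelta(hours=20)
        else:
            if is_hunt:
                continue
            lo = day
            hi = day + pd.Timedelta(days=1)
        chunks.append(
            pd.date_range(lo, hi, freq=pd.Timedelta(minutes=interval_min), inclusive="left")
        )
    if not chunks:
        return pd.DatetimeIndex([], tz="UTC")
    sched = chunks[0].append(chunks[1:]) if len(chunks) > 1 else chunks[0]
    sched = sched.tz_convert("UTC")
    return sched[(sched >= t0) & (sched <= t1)]
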