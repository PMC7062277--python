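"""Synthetic herd, hunts and GPS observation model with ground-truth labels.

The generator emulates the monitoring design of a fenced lowland deer park:
14 collared hinds with stationary annual home ranges (mean 561 ha, SD
282 ha), 23 drive-hunt days over a mid-November-to-February season with 4-6
roughly hour-long drives per day over 47-201 ha convex hunted areas, dual
GPS duty cycles (2-minute fixes 08:00-20:00 local on hunt days, hourly
otherwise), 82%/86% fix success and a 5.8 m median radial location error.

Background movement is a centre-attracted (Ornstein-Uhlenbeck) walk whose
stationary spread is calibrated so the 95% kernel home range matches the
drawn range size.  Each exposed individual draws a flee/stay branch
(flee probability 0.68): fleeing is a fast, near-straight crossing of the
shooting line during the drive; staying is a slow, reversing, confined walk
with a delayed departure after the hunters leave.  Both branches retreat
roughly 2.2 km from the encounter site by the first dawn.  Area-presence
spells (pre-hunt control spell, post-hunt return lag) are drawn directly
from configured mixture distributions — a non-return mass censored beyond
the 6-day horizon plus a lognormal mode of returners whose marginal median
matches the configured Kaplan-Meier median — and the walk is conditioned to
honour the spell schedule.
"""
from __future__ import annotations

import math
from dataclasses import dataclass
from datetime import date
from zoneinfo import ZoneInfo

import numpy as np
import pandas as pd
from scipy import stats
from shapely.geometry import Point, Polygon
from shapely.prepared import prep

from .io import DriveHunt, HuntedArea, Trajectory
from .returns import ReturnRecord


@dataclass
class GeneratorConfig:
    """Study-design parameters of the synthetic population (defaults are the
    monitored system's values; behavioural scales are chosen to reproduce its
    reported movement statistics)."""

    n_individuals: int = 14
    hr_mean_ha: float = 561.1
    hr_sd_ha: float = 282.5
    n_hunt_days: int = 23
    hunts_per_day: tuple[int, int] = (4, 6)
    hunt_duration_min: float = 60.0
    area_ha_mean: float = 101.0
    area_ha_sd: float = 30.0
    area_ha_range: tuple[float, float] = (47.0, 201.0)
    flee_probability: float = 0.68
    # kinematics (km/h scales; heading noise in radians per 2-min step)
    flee_speed_kmh: float = 16.0
    flee_speed_sd_kmh: float = 3.5
    flee_heading_sd: float = 0.15
    flee_escape_buffer_m: float = 400.0
    flee_wander_speed_kmh: float = 1.5
    flee_wander_speed_sd_kmh: float = 0.8
    flee_wander_heading_sd: float = 2.2
    stay_burst_prob: float = 0.08
    stay_burst_speed_kmh: float = 8.5
    stay_burst_speed_sd_kmh: float = 2.0
    stay_base_speed_kmh: float = 0.45
    stay_base_speed_sd_kmh: float = 0.25
    stay_turn_sd: float = 1.5
    stay_margin_m: float = 40.0
    dawn_displacement_m: float = 2158.0
    dawn_displacement_range: tuple[float, float] = (1078.0, 3254.0)
    # area-presence spells
    posthunt_return_median_h: float = 34.0
    posthunt_nonreturn_mass: float = 0.38
    control_return_median_h: float = 17.0
    control_nonreturn_mass: float = 0.12
    return_log_sd: float = 0.25
    censor_horizon_h: float = 144.0
    # covariate ranges
    bush_range: tuple[float, float] = (0.036, 0.459)
    gunshot_range: tuple[int, int] = (10, 85)
    dogs_per_ha_range: tuple[float, float] = (0.21, 0.88)
    beaters_per_ha_range: tuple[float, float] = (0.20, 0.76)
    # observation model
    gps_noise_median_m: float = 5.8
    fix_success_intensive: float = 0.82
    fix_success_routine: float = 0.86
    # scheduling / landscape
    exposure_probability: float = 0.30  # per drive: one exposed individual
    ou_relaxation_h: float = 12.0
    landscape_size_m: float = 7400.0
    monitor_start: date = date(2017, 2, 1)
    monitor_end: date = date(2018, 2, 28)
    season_start: date = date(2017, 11, 15)
    season_end: date = date(2018, 2, 23)
    timezone: str = "Europe/Paris"
    rng_seed: int = 0

    def __post_init__(self) -> None:
        for p in (
            self.flee_probability,
            self.posthunt_nonreturn_mass,
            self.control_nonreturn_mass,
            self.fix_success_intensive,
            self.fix_success_routine,
        ):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")
        for rng_ in (self.area_ha_range, self.bush_range, self.dogs_per_ha_range):
            if rng_[0] > rng_[1]:
                raise ValueError("ranges must be ordered")
        if self.area_ha_range[1] * 1e4 > self.landscape_size_m**2:
            raise ValueError("hunted area larger than the landscape")


@dataclass
class GroundTruth:
    """Generating-branch record: per-event labels/spells and per-individual
    home-range parameters — the reference surface for recovery tests."""

    events: pd.DataFrame
    individuals: pd.DataFrame


@dataclass
class SimulationResult:
    trajectories: dict[str, Trajectory]
    hunts: list[DriveHunt]
    areas: dict[str, HuntedArea]
    ground_truth: GroundTruth
    config: GeneratorConfig


# ---------------------------------------------------------------------------
# low-level pieces

_LN20 = -math.log(0.05)


def stationary_sd_for_range(area_ha: float, n_ud_points: int = 730) -> float:
    """Stationary spread (per-axis sd, metres) of the centre-attracted walk
    whose 95% fixed-kernel home range has the requested area.

    For Gaussian use, the 95% kernel isopleth encloses
    ``2*pi*(sigma^2 + h^2)*(-ln 0.05)`` with the reference bandwidth
    ``h = sigma * n**(-1/6)``."""
    infl = 1.0 + n_ud_points ** (-1.0 / 3.0)
    return math.sqrt(area_ha * 1e4 / (2 * math.pi * _LN20 * infl))


def gps_noise_sd(config: GeneratorConfig) -> float:
    """Per-axis Gaussian sd giving the configured median radial error
    (radial error is Rayleigh; median = sd*sqrt(2 ln 2))."""
    return config.gps_noise_median_m / math.sqrt(2 * math.log(2))


def truncated_normal(mean, sd, lo, hi, rng, size=None):
    a, b = (lo - mean) / sd, (hi - mean) / sd
    return stats.truncnorm.rvs(a, b, loc=mean, scale=sd, size=size, random_state=rng)


def random_convex_area(centre: tuple[float, float], area_ha: float, rng) -> Polygon:
    """Random convex polygon of the requested area centred on ``centre``."""
    k = 10
    ang = np.sort(rng.uniform(0, 2 * np.pi, k))
    rad = 1.0 + 0.45 * rng.uniform(-1, 1, k)
    pts = np.column_stack([rad * np.cos(ang), rad * np.sin(ang)])
    poly = Polygon(pts).convex_hull
    scale = math.sqrt(area_ha * 1e4 / poly.area)
    pts = np.asarray(poly.exterior.coords)[:-1] * scale
    pts -= pts.mean(axis=0)
    return Polygon(pts + np.asarray(centre))


def random_point_in(poly: Polygon, rng) -> tuple[float, float]:
    minx, miny, maxx, maxy = poly.bounds
    prepped = prep(poly)
    for _ in range(10_000):
        x = rng.uniform(minx, maxx)
        y = rng.uniform(miny, maxy)
        if prepped.covers(Point(x, y)):
            return (float(x), float(y))
    raise RuntimeError("rejection sampling failed; degenerate polygon?")


# --- area-presence spell sampler -------------------------------------------


def _returner_log_median(median_h: float, nonreturn_mass: float, log_sd: float) -> float:
    """Median of the returner lognormal mode such that the *marginal* spell
    distribution (non-returners counted as beyond the horizon) has the
    configured median, which is what a Kaplan-Meier median reads off."""
    z = stats.norm.ppf(0.5 / (1.0 - nonreturn_mass))
    return math.log(median_h) - z * log_sd


def draw_return_lag(condition: str, config: GeneratorConfig, rng) -> float | None:
    """One area-absence spell, hours; None = no return within the horizon."""
    if condition == "post_hunt":
        q, med = config.posthunt_nonreturn_mass, config.posthunt_return_median_h
    elif condition == "control":
        q, med = config.control_nonreturn_mass, config.control_return_median_h
    else:
        raise ValueError("condition must be 'post_hunt' or 'control'")
    if rng.random() < q:
        return None
    mu = _returner_log_median(med, q, config.return_log_sd)
    for _ in range(100):
        lag = math.exp(rng.normal(mu, config.return_log_sd))
        if lag < 0.95 * config.censor_horizon_h:
            return lag
    return None


def sample_return_records(
    condition: str, n: int, config: GeneratorConfig | None = None, rng=None
) -> list[ReturnRecord]:
    """Draw ``n`` spell-level return records under the generator defaults
    (censored at the horizon), ready for the product-limit estimator."""
    config = config or GeneratorConfig()
    rng = np.random.default_rng(rng)
    out = []
    for i in range(n):
        lag = draw_return_lag(condition, config, rng)
        if lag is None:
            out.append(
                ReturnRecord(f"sim{i}", condition, config.censor_horizon_h, True)
            )
        else:
            out.append(ReturnRecord(f"sim{i}", condition, lag, False))
    return out


# --- hunt-response kinematics ----------------------------------------------


def simulate_hunt_response(
    encounter: tuple[float, float],
    polygon: Polygon,
    hunt_start: pd.Timestamp,
    hunt_end: pd.Timestamp,
    branch: str,
    config: GeneratorConfig,
    rng,
) -> tuple[pd.DatetimeIndex, np.ndarray, pd.Timestamp | None]:
    """True 2-minute path of one exposed individual during the drive.

    Fleeing: fast near-straight outward run crossing the shooting line, then
    a slow wander outside.  Staying: slow reversing walk confined inside the
    polygon (eroded by a safety margin so location error cannot fake a
    crossing).  Returns (times, positions, crossing time or None).
    """
    dt_min = 2.0
    times = pd.date_range(hunt_start, hunt_end, freq=pd.Timedelta(minutes=dt_min))
    pos = np.array(encounter, dtype=float)
    cx, cy = polygon.centroid.x, polygon.centroid.y
    out = [pos.copy()]
    exit_time: pd.Timestamp | None = None
    prepped = prep(polygon)
    if branch == "flee":
        d = pos - np.array([cx, cy])
        heading = math.atan2(d[1], d[0]) if np.hypot(*d) > 1 else rng.uniform(0, 2 * np.pi)
        escaped = False
        for t in times[1:]:
            if not escaped:
                # intense straight run until well past the shooting line
                v = max(rng.normal(config.flee_speed_kmh, config.flee_speed_sd_kmh), 4.0)
                heading += rng.normal(0, config.flee_heading_sd)
            else:
                # tortuous settling wander outside
                v = max(
                    rng.normal(
                        config.flee_wander_speed_kmh, config.flee_wander_speed_sd_kmh
                    ),
                    0.2,
                )
                heading += rng.normal(0, config.flee_wander_heading_sd)
            step = v * 1000.0 * dt_min / 60.0
            pos = pos + step * np.array([math.cos(heading), math.sin(heading)])
            if not escaped and not prepped.covers(Point(pos)):
                if exit_time is None:
                    exit_time = t
                if polygon.exterior.distance(Point(pos)) > config.flee_escape_buffer_m:
                    escaped = True
            out.append(pos.copy())
    elif branch == "stay":
        interior = polygon.buffer(-config.stay_margin_m)
        if interior.is_empty:
            interior = polygon.buffer(-2.0)
        prepped_int = prep(interior)
        heading = rng.uniform(0, 2 * np.pi)
        enc = np.array(encounter, dtype=float)
        for _t in times[1:]:
            # reversing walk: turning angles cluster near pi (cover-seeking
            # back-and-forth), giving the negative mean-cosine of stayers
            heading += math.pi + rng.normal(0, config.stay_turn_sd)
            if rng.random() < config.stay_burst_prob:
                # flushed by a passing beater or dog: short burst
                v = max(
                    rng.normal(
                        config.stay_burst_speed_kmh, config.stay_burst_speed_sd_kmh
                    ),
                    0.5,
                )
            else:
                v = max(
                    rng.normal(
                        config.stay_base_speed_kmh, config.stay_base_speed_sd_kmh
                    ),
                    0.05,
                )
            step = v * 1000.0 * dt_min / 60.0
            cand = pos + step * np.array([math.cos(heading), math.sin(heading)])
            if not prepped_int.covers(Point(cand)):
                back = enc - pos
                heading = math.atan2(back[1], back[0]) + rng.normal(0, 0.3)
                cand = pos + min(step, 0.8 * np.hypot(*back) + 1.0) * np.array(
                    [math.cos(heading), math.sin(heading)]
                )
                if not prepped_int.covers(Point(cand)):
                    cand = pos
            pos = cand
            out.append(pos.copy())
    else:
        raise ValueError("branch must be 'flee' or 'stay'")
    return times, np.asarray(out), exit_time


# --- observation model ------------------------------------------------------


def apply_observation_model(
    times: pd.DatetimeIndex,
    xy: np.ndarray,
    intensive: np.ndarray,
    config: GeneratorConfig,
    rng,
) -> pd.DataFrame:
    """Observe a true path: isotropic Gaussian position noise plus
    independent per-fix dropout at one minus the regime's fix success.
    Dropped fixes are emitted as ``fix_ok = False`` rows with no coordinates.
    """
    xy = np.asarray(xy, dtype=float)
    intensive = np.asarray(intensive, dtype=bool)
    sd = gps_noise_sd(config)
    noise = rng.normal(0.0, sd, size=xy.shape) if sd > 0 else np.zeros_like(xy)
    success = np.where(
        intensive, config.fix_success_intensive, config.fix_success_routine
    )
    ok = rng.random(len(times)) < success
    obs = xy + noise
    obs[~ok] = np.nan
    return pd.DataFrame(
        {"timestamp": times, "x": obs[:, 0], "y": obs[:, 1], "fix_ok": ok}
    )


# ---------------------------------------------------------------------------
# standalone labelled events (scalable event-count studies)


def simulate_events(
    n_events: int,
    config: GeneratorConfig | None = None,
    rng=None,
    noise: bool = True,
    with_delayed: bool = True,
) -> SimulationResult:
    """Generate standalone labelled hunting events with default behaviour.

    Each event is one individual exposed to one hour-long drive over its own
    hunted area on its own day: a short pre-hunt presence, the 2-minute
    drive-window response path and (optionally) the hourly retreat to first
    dawn, passed through the observation model.  Events whose start fix is
    lost to dropout are regenerated so exactly ``n_events`` detectable events
    are returned.  ``noise=False`` disables both GPS error and dropout.
    """
    config = config or GeneratorConfig()
    rng = np.random.default_rng(rng)
    tz = ZoneInfo(config.timezone)
    trajectories: dict[str, Trajectory] = {}
    hunts: list[DriveHunt] = []
    areas: dict[str, HuntedArea] = {}
    truth_rows = []
    base = pd.Timestamp(config.season_start).tz_localize(tz)
    i = 0
    attempts = 0
    while i < n_events:
        attempts += 1
        if attempts > 20 * n_events:
            raise RuntimeError("event generation kept failing; check config")
        day = base + pd.Timedelta(days=i)
        start = (day.normalize() + pd.Timedelta(hours=11)).tz_convert("UTC")
        end = start + pd.Timedelta(minutes=config.hunt_duration_min)
        area_ha = truncated_normal(
            config.area_ha_mean, config.area_ha_sd, *config.area_ha_range, rng
        )
        centre = (float(rng.uniform(-1, 1) * 500), float(rng.uniform(-1, 1) * 500))
        poly = random_convex_area(centre, float(area_ha), rng)
        interior = poly.buffer(-config.stay_margin_m)
        if interior.is_empty:
            continue
        encounter = random_point_in(interior, rng)
        branch = "flee" if rng.random() < config.flee_probability else "stay"
        t_hunt, xy_hunt, _exit = simulate_hunt_response(
            encounter, poly, start, end, branch, config, rng
        )
        # short inside presence before the drive so the start fix has context
        pre_t = pd.date_range(
            start - pd.Timedelta(minutes=10), start - pd.Timedelta(minutes=2),
            freq=pd.Timedelta(minutes=2),
        )
        pre_xy = np.asarray(encounter) + rng.normal(0, 10, size=(len(pre_t), 2))
        times = pre_t.append(t_hunt)
        xy = np.vstack([pre_xy, xy_hunt])
        intensive = np.ones(len(times), dtype=bool)
        if with_delayed:
            dawn = (day.normalize() + pd.Timedelta(days=1, hours=8)).tz_convert("UTC")
            post_t = pd.date_range(
                end + pd.Timedelta(hours=1), dawn, freq=pd.Timedelta(hours=1)
            )
            d_retreat = truncated_normal(
                config.dawn_displacement_m, 450.0, *config.dawn_displacement_range, rng
            )
            theta = rng.uniform(0, 2 * np.pi)
            retreat = np.asarray(encounter) + d_retreat * np.array(
                [math.cos(theta), math.sin(theta)]
            )
            post_xy = _retreat_track(xy[-1], retreat, len(post_t), poly, branch, rng)
            # hunt-day intensive duty cycle runs to 20:00 local
            cut = (day.normalize() + pd.Timedelta(hours=20)).tz_convert("UTC")
            times = times.append(post_t)
            xy = np.vstack([xy, post_xy])
            intensive = np.concatenate([intensive, post_t < cut])
        if noise:
            fixes = apply_observation_model(times, xy, intensive, config, rng)
        else:
            fixes = pd.DataFrame(
                {"timestamp": times, "x": xy[:, 0], "y": xy[:, 1],
                 "fix_ok": np.ones(len(times), bool)}
            )
        if not bool(fixes["fix_ok"].iloc[len(pre_t)]):
            continue  # start fix lost to dropout: event undetectable, redraw
        ind = f"ev{i:04d}"
        hunt_id = f"h{i:04d}"
        area_id = f"a{i:04d}"
        trajectories[ind] = Trajectory(ind, fixes)
        areas[area_id] = HuntedArea(
            area_id, poly, float(rng.uniform(*config.bush_range))
        )
        dogs = rng.uniform(*config.dogs_per_ha_range) * area_ha
        beat = rng.uniform(*config.beaters_per_ha_range) * area_ha
        hunts.append(
            DriveHunt(
                hunt_id, area_id, start, end,
                n_beaters=max(int(round(beat)), 1),
                n_dogs=max(int(round(dogs)), 1),
                n_shooters=33,
                n_gunshots=int(rng.integers(config.gunshot_range[0], config.gunshot_range[1] + 1)),
            )
        )
        truth_rows.append(
            {
                "event_id": f"{hunt_id}:{ind}",
                "individual_id": ind,
                "hunt_id": hunt_id,
                "branch": branch,
                "encounter_x": encounter[0],
                "encounter_y": encounter[1],
            }
        )
        i += 1
    truth = GroundTruth(
        events=pd.DataFrame(truth_rows),
        individuals=pd.DataFrame(
            {"individual_id": list(trajectories), "centre_x": np.nan, "centre_y": np.nan}
        ),
    )
    return SimulationResult(trajectories, hunts, areas, truth, config)


def _retreat_track(
    start_pos: np.ndarray,
    retreat: np.ndarray,
    n_steps: int,
    polygon: Polygon,
    branch: str,
    rng,
    depart_after: int = 0,
) -> np.ndarray:
    """Hourly waypoints from the end-of-hunt position to a retreat site
    (reached within ~5 h), then wandering around it, kept out of the hunted
    polygon once departed."""
    out = np.zeros((n_steps, 2))
    pos = np.asarray(start_pos, dtype=float)
    prepped = prep(polygon)
    cx, cy = polygon.centroid.x, polygon.centroid.y
    travel = max(1, min(5, n_steps - 1))
    for j in range(n_steps):
        if branch == "stay" and j < depart_after:
            pos = pos + rng.normal(0, 30, 2)  # lingering inside before leaving
        else:
            to = retreat - pos
            dist = float(np.hypot(*to))
            hop = min(dist, max(dist / max(travel - j, 1), 400.0))
            if dist > 1.0:
                pos = pos + hop * to / dist + rng.normal(0, 60, 2)
            else:
                pos = pos + rng.normal(0, 120, 2)
            if prepped.covers(Point(pos)):
                d = pos - np.array([cx, cy])
                nrm = np.hypot(*d)
                ray = d / nrm if nrm > 1 else np.array([1.0, 0.0])
                pos = np.array([cx, cy]) + ray * (_poly_radius(polygon, ray) + 80.0)
        out[j] = pos
    return out


def _poly_radius(polygon: Polygon, ray: np.ndarray) -> float:
    """Approximate centroid-to-boundary distance along ``ray``."""
    c = np.array([polygon.centroid.x, polygon.centroid.y])
    far = c + ray * 1e5
    from shapely.geometry import LineString

    inter = polygon.exterior.intersection(LineString([c, far]))
    if inter.is_empty:
        return math.sqrt(polygon.area / math.pi)
    if inter.geom_type == "Point":
        return float(np.hypot(inter.x - c[0], inter.y - c[1]))
    pts = [g for g in getattr(inter, "geoms", []) if g.geom_type == "Point"]
    if not pts:
        return math.sqrt(polygon.area / math.pi)
    return float(max(np.hypot(p.x - c[0], p.y - c[1]) for p in pts))


# ---------------------------------------------------------------------------
# full population

_H = pd.Timedelta(hours=1)


def simulate_population(
    config: GeneratorConfig | None = None, rng=None
) -> SimulationResult:
    """Simulate the full monitored population: a year of relocations per
    individual on the dual duty cycle, a season of drive hunts with exposed
    individuals scripted through their control spell, drive-window response
    and post-hunt retreat/return, everything else centre-attracted wandering.

    Fully reproducible from the seed.  Ground truth records each event's
    branch and spell schedule and each individual's home-range parameters.
    """
    config = config or GeneratorConfig()
    rng = np.random.default_rng(config.rng_seed if rng is None else rng)
    tz = ZoneInfo(config.timezone)

    # individuals: home-range centre and calibrated stationary spread
    ids = [f"deer{i:02d}" for i in range(1, config.n_individuals + 1)]
    half = config.landscape_size_m / 2.0
    centres = rng.uniform(-0.55 * half, 0.55 * half, size=(config.n_individuals, 2))
    hr_ha = np.clip(
        rng.normal(config.hr_mean_ha, config.hr_sd_ha, config.n_individuals), 80, None
    )
    sigma = np.array([stationary_sd_for_range(a) for a in hr_ha])

    # hunt calendar: n_hunt_days dates evenly spread over the season
    season_days = (
        pd.Timestamp(config.season_end) - pd.Timestamp(config.season_start)
    ).days
    offsets = np.linspace(0, season_days, config.n_hunt_days).round().astype(int)
    hunt_dates = [pd.Timestamp(config.season_start) + pd.Timedelta(days=int(o)) for o in offsets]

    hunts: list[DriveHunt] = []
    areas: dict[str, HuntedArea] = {}
    schedule_events: dict[str, list[dict]] = {i: [] for i in ids}
    truth_rows = []
    last_event_start = {i: None for i in ids}
    min_sep = pd.Timedelta(hours=400)

    for di, d in enumerate(hunt_dates):
        n_drives = int(rng.integers(config.hunts_per_day[0], config.hunts_per_day[1] + 1))
        day_local = pd.Timestamp(d).tz_localize(tz)
        exposed_today: set[str] = set()
        for k in range(n_drives):
            hunt_id = f"hunt{di:02d}_{k}"
            area_id = f"area{di:02d}_{k}"
            start = (day_local + pd.Timedelta(hours=9) + k * pd.Timedelta(minutes=90)).tz_convert("UTC")
            end = start + pd.Timedelta(minutes=config.hunt_duration_min)
            area_ha = float(
                truncated_normal(config.area_ha_mean, config.area_ha_sd, *config.area_ha_range, rng)
            )
            exposed = None
            if rng.random() < config.exposure_probability:
                eligible = [
                    i
                    for i in ids
                    if i not in exposed_today
                    and (
                        last_event_start[i] is None
                        or start - last_event_start[i] > min_sep
                    )
                ]
                if eligible:
                    exposed = eligible[int(rng.integers(len(eligible)))]
            if exposed is not None:
                ci = ids.index(exposed)
                centre = tuple(centres[ci] + rng.normal(0, 350, 2))
            else:
                # keep unexposed drives off the monitored home ranges so the
                # collared sample is exposed only through scripted events
                centre, best_d = None, -1.0
                for _ in range(60):
                    cand = rng.uniform(-0.9 * half, 0.9 * half, 2)
                    dmin = float(
                        np.min(np.hypot(*(centres - cand[None, :]).T))
                    )
                    if dmin > best_d:
                        centre, best_d = tuple(cand), dmin
                    if dmin > 2200.0:
                        break
            poly = random_convex_area(centre, area_ha, rng)
            areas[area_id] = HuntedArea(area_id, poly, float(rng.uniform(*config.bush_range)))
            dogs = rng.uniform(*config.dogs_per_ha_range) * area_ha
            beat = rng.uniform(*config.beaters_per_ha_range) * area_ha
            hunts.append(
                DriveHunt(
                    hunt_id, area_id, start, end,
                    n_beaters=max(int(round(beat)), 1),
                    n_dogs=max(int(round(dogs)), 1),
                    n_shooters=33,
                    n_gunshots=int(
                        rng.integers(config.gunshot_range[0], config.gunshot_range[1] + 1)
                    ),
                )
            )
            if exposed is None:
                continue
            exposed_today.add(exposed)
            last_event_start[exposed] = start
            interior = poly.buffer(-config.stay_margin_m)
            if interior.is_empty:
                interior = poly.buffer(-2.0)
            encounter = random_point_in(interior, rng)
            branch = "flee" if rng.random() < config.flee_probability else "stay"
            entry_offset = float(rng.uniform(1.0, 6.0))
            control_lag = draw_return_lag("control", config, rng)
            post_lag = draw_return_lag("post_hunt", config, rng)
            d_retreat = float(
                truncated_normal(
                    config.dawn_displacement_m, 450.0, *config.dawn_displacement_range, rng
                )
            )
            ev = {
                "hunt_id": hunt_id,
                "area_id": area_id,
                "start": start,
                "end": end,
                "polygon": poly,
                "encounter": encounter,
                "branch": branch,
                "entry_offset_h": entry_offset,
                "control_lag_h": control_lag,
                "post_lag_h": post_lag,
                "d_retreat_m": d_retreat,
            }
            schedule_events[exposed].append(ev)
            truth_rows.append(
                {
                    "event_id": f"{hunt_id}:{exposed}",
                    "individual_id": exposed,
                    "hunt_id": hunt_id,
                    "area_id": area_id,
                    "branch": branch,
                    "entry_offset_h": entry_offset,
                    "control_lag_h": np.nan if control_lag is None else control_lag,
                    "control_censored": control_lag is None,
                    "post_lag_h": np.nan if post_lag is None else post_lag,
                    "post_censored": post_lag is None,
                    "encounter_x": encounter[0],
                    "encounter_y": encounter[1],
                }
            )

    sched_times, intensive = _fix_schedule(config, hunt_dates, tz)

    trajectories: dict[str, Trajectory] = {}
    for ci, ind in enumerate(ids):
        scripts = [
            _build_event_script(ev, config, rng) for ev in schedule_events[ind]
        ]
        xy = _assemble_path(
            sched_times, centres[ci], sigma[ci], scripts, config, rng
        )
        fixes = apply_observation_model(sched_times, xy, intensive, config, rng)
        trajectories[ind] = Trajectory(ind, fixes)

    truth = GroundTruth(
        events=pd.DataFrame(truth_rows),
        individuals=pd.DataFrame(
            {
                "individual_id": ids,
                "centre_x": centres[:, 0],
                "centre_y": centres[:, 1],
                "target_hr_ha": hr_ha,
                "sigma_m": sigma,
            }
        ),
    )
    return SimulationResult(trajectories, hunts, areas, truth, config)


def _fix_schedule(config, hunt_dates, tz):
    """Scheduled fix times over the monitoring span plus an intensive-regime
    flag (2-min 08:00-20:00 local on hunt days, hourly otherwise)."""
    hunt_set = {pd.Timestamp(d).date() for d in hunt_dates}
    days = pd.date_range(
        config.monitor_start, pd.Timestamp(config.monitor_end) + pd.Timedelta(days=1), freq="D"
    )
    chunks, flags = [], []
    for day, nxt in zip(days[:-1], days[1:]):
        local = pd.Timestamp(day).tz_localize(tz)
        local_next = pd.Timestamp(nxt).tz_localize(tz)  # honours DST shifts
        if day.date() in hunt_set:
            a = pd.date_range(local, local + pd.Timedelta(hours=8), freq=_H, inclusive="left")
            b = pd.date_range(
                local + pd.Timedelta(hours=8),
                local + pd.Timedelta(hours=20),
                freq=pd.Timedelta(minutes=2),
                inclusive="left",
            )
            c = pd.date_range(
                local + pd.Timedelta(hours=20), local_next, freq=_H, inclusive="left"
            )
            chunks += [a, b, c]
            flags += [np.zeros(len(a), bool), np.ones(len(b), bool), np.zeros(len(c), bool)]
        else:
            a = pd.date_range(local, local_next, freq=_H, inclusive="left")
            chunks.append(a)
            flags.append(np.zeros(len(a), bool))
    times = chunks[0].append(chunks[1:]).tz_convert("UTC")
    return times, np.concatenate(flags)


def _build_event_script(ev, config: GeneratorConfig, rng) -> dict:
    """Waypoint series (hourly around the hunt, 2-minute inside it) realizing
    one event's spell schedule; sampled by interpolation during assembly."""
    poly: Polygon = ev["polygon"]
    start: pd.Timestamp = ev["start"]
    end: pd.Timestamp = ev["end"]
    enc = np.asarray(ev["encounter"], dtype=float)
    horizon = pd.Timedelta(hours=config.censor_horizon_h)
    entry_t = (start - pd.Timedelta(hours=ev["entry_offset_h"])).floor("h")
    if ev["control_lag_h"] is None:
        exit_c = entry_t - horizon - pd.Timedelta(hours=30)
    else:
        exit_c = entry_t - pd.Timedelta(hours=max(round(ev["control_lag_h"]), 1))
    w0 = exit_c - pd.Timedelta(hours=3)

    cx, cy = poly.centroid.x, poly.centroid.y
    d = enc - np.array([cx, cy])
    nrm = float(np.hypot(*d))
    ray = d / nrm if nrm > 1 else np.array([1.0, 0.0])
    away = np.array([cx, cy]) + ray * (_poly_radius(poly, ray) + 450.0)

    interior = poly.buffer(-config.stay_margin_m)
    if interior.is_empty:
        interior = poly.buffer(-2.0)
    prepped_int = prep(interior)

    t_way = []
    p_way = []
    t = w0
    pos = enc + rng.normal(0, 40, 2)
    while t < start:
        if t <= exit_c or t >= entry_t:
            cand = enc + rng.normal(0, 50, 2)
            if not prepped_int.covers(Point(cand)):
                cand = enc
            pos = cand
        else:
            pos = away + rng.normal(0, 120, 2)
        t_way.append(t)
        p_way.append(pos.copy())
        t += _H

    t_hunt, xy_hunt, exit_time = simulate_hunt_response(
        tuple(enc), poly, start, end, ev["branch"], config, rng
    )
    t_way += list(t_hunt)
    p_way += list(xy_hunt)

    # post-hunt: flight exit anchors the return lag
    if ev["branch"] == "flee":
        exit_f = exit_time if exit_time is not None else end
    else:
        exit_f = (end + pd.Timedelta(hours=1)).ceil("h")
    if ev["post_lag_h"] is None:
        return_t = None
        w1 = start + horizon + pd.Timedelta(hours=30)
    else:
        return_t = exit_f + pd.Timedelta(hours=max(round(ev["post_lag_h"]), 1))
        w1 = return_t + pd.Timedelta(hours=3)

    theta = math.atan2(ray[1], ray[0]) + rng.normal(0, 0.6)
    retreat = enc + ev["d_retreat_m"] * np.array([math.cos(theta), math.sin(theta)])
    pos = np.asarray(p_way[-1], dtype=float)
    prepped = prep(poly)
    t = end.ceil("h")
    if t <= end:
        t += _H
    depart = exit_f if ev["branch"] == "stay" else end
    while t <= w1:
        if ev["branch"] == "stay" and t < depart:
            pos = enc + rng.normal(0, 30, 2)
        elif return_t is not None and t >= return_t and t < return_t + pd.Timedelta(hours=3):
            cand = enc + rng.normal(0, 40, 2)
            pos = cand if prepped_int.covers(Point(cand)) else enc
        else:
            to = retreat - pos
            dist = float(np.hypot(*to))
            if dist > 500.0:
                pos = pos + min(dist, 1200.0) * to / dist + rng.normal(0, 60, 2)
            else:
                pos = retreat + rng.normal(0, 220, 2)
            if prepped.covers(Point(pos)):
                dd = pos - np.array([cx, cy])
                nn = float(np.hypot(*dd))
                rr = dd / nn if nn > 1 else np.array([1.0, 0.0])
                pos = np.array([cx, cy]) + rr * (_poly_radius(poly, rr) + 80.0)
        t_way.append(t)
        p_way.append(np.asarray(pos, dtype=float).copy())
        t += _H

    tns = np.array([pd.Timestamp(x).value for x in t_way], dtype=np.int64)
    order = np.argsort(tns, kind="stable")
    tns = tns[order]
    pw = np.asarray(p_way, dtype=float)[order]
    keep = np.concatenate([[True], np.diff(tns) > 0])
    return {"t0": int(tns[keep][0]), "t1": int(tns[keep][-1]),
            "t": tns[keep], "xy": pw[keep]}


def _assemble_path(times, centre, sigma_s, scripts, config: GeneratorConfig, rng):
    """Forward pass over the fix schedule: scripted interpolation inside
    event windows, centre-attracted OU steps elsewhere."""
    tns = times.astype("int64").to_numpy()
    n = len(tns)
    xy = np.zeros((n, 2))
    pos = centre + rng.normal(0, sigma_s, 2)
    tau_ns = config.ou_relaxation_h * 3600e9
    scripts = sorted(scripts, key=lambda s: s["t0"])
    si = 0
    prev_t = tns[0]
    for j in range(n):
        t = tns[j]
        while si < len(scripts) and t > scripts[si]["t1"]:
            # window passed: hand the OU state its last scripted position
            pos = scripts[si]["xy"][-1].copy()
            si += 1
        if si < len(scripts) and scripts[si]["t0"] <= t <= scripts[si]["t1"]:
            s = scripts[si]
            pos = np.array(
                [
                    np.interp(t, s["t"], s["xy"][:, 0]),
                    np.interp(t, s["t"], s["xy"][:, 1]),
                ]
            )
        else:
            dt = max(t - prev_t, 1)
            phi = math.exp(-dt / tau_ns)
            sd = sigma_s * math.sqrt(max(1 - phi * phi, 0.0))
            pos = centre + phi * (pos - centre) + rng.normal(0, sd, 2)
        xy[j] = pos
        prev_t = t
    return xy


# ---------------------------------------------------------------------------
# direct model-data simulators (parameter-recovery studies)

#: arbitrary but plausible generating coefficients for recovery studies
DEFAULT_DISTANCE_COEFS = {
    "intercept": 7.0,
    "bush": -1.2,
    "fam": 0.8,
    "dogs_per_ha": 0.9,
    "beaters_per_ha": -0.7,
    "gunshots": 0.01,
}
DEFAULT_RETURN_COEFS = {"intercept": -0.5, "hunt": 1.2, "fam": -1.5, "hunt_fam": 1.0}


def simulate_distance_model_data(
    n_events: int = 200,
    n_individuals: int = 20,
    coefs: dict | None = None,
    sigma_u: float = 0.3,
    sigma_eps: float = 0.5,
    config: GeneratorConfig | None = None,
    rng=None,
) -> pd.DataFrame:
    """Events table drawn from the log-distance linear mixed model itself:
    covariates uniform on their observed ranges, Gaussian random intercept
    per individual, Gaussian residual."""
    config = config or GeneratorConfig()
    rng = np.random.default_rng(rng)
    coefs = dict(DEFAULT_DISTANCE_COEFS if coefs is None else coefs)
    ind = rng.integers(n_individuals, size=n_events)
    u = rng.normal(0, sigma_u, n_individuals)
    df = pd.DataFrame(
        {
            "individual_id": [f"id{i:02d}" for i in ind],
            "bush": rng.uniform(*config.bush_range, n_events),
            "fam": rng.uniform(0.0, 0.82, n_events),
            "dogs_per_ha": rng.uniform(*config.dogs_per_ha_range, n_events),
            "beaters_per_ha": rng.uniform(*config.beaters_per_ha_range, n_events),
            "gunshots": rng.integers(
                config.gunshot_range[0], config.gunshot_range[1] + 1, n_events
            ).astype(float),
        }
    )
    eta = coefs["intercept"] + sum(
        coefs[c] * df[c].to_numpy() for c in DISTANCE_COVARIATES
    )
    y = eta + u[ind] + rng.normal(0, sigma_eps, n_events)
    df["dist_immediate_m"] = np.exp(y)
    df["dist_delayed_m"] = np.exp(y)
    return df


DISTANCE_COVARIATES = ("bush", "fam", "dogs_per_ha", "beaters_per_ha", "gunshots")


def simulate_return_model_data(
    n_records: int = 200,
    n_individuals: int = 20,
    coefs: dict | None = None,
    sigma_u: float = 0.5,
    rng=None,
) -> pd.DataFrame:
    """Records table drawn from the short-return logistic mixed model."""
    rng = np.random.default_rng(rng)
    coefs = dict(DEFAULT_RETURN_COEFS if coefs is None else coefs)
    ind = rng.integers(n_individuals, size=n_records)
    u = rng.normal(0, sigma_u, n_individuals)
    hunt = rng.integers(0, 2, n_records).astype(float)
    fam = rng.uniform(0.0, 0.82, n_records)
    eta = (
        coefs["intercept"]
        + coefs["hunt"] * hunt
        + coefs["fam"] * fam
        + coefs["hunt_fam"] * hunt * fam
        + u[ind]
    )
    p = 1.0 / (1.0 + np.exp(-eta))
    return pd.DataFrame(
        {
            "individual_id": [f"id{i:02d}" for i in ind],
            "hunt": hunt,
            "fam": fam,
            "short_return": (rng.random(n_records) < p).astype(float),
        }
    )
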