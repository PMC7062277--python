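"""Analysis configuration shared across the pipeline stages."""
from __future__ import annotations

from dataclasses import dataclass, field
from datetime import time


@dataclass
class AnalysisConfig:
    """Tunable parameters of the drive-hunt response analysis.

    Times of day (``day_start``, ``day_end``, ``dawn_hour``) are civil clock
    times evaluated in ``study_timezone``; everything else is stored and
    compared in UTC.  Distances are Euclidean metres in a projected CRS.

    Attributes
    ----------
    day_start, day_end : datetime.time
        Bounds of the diurnal period used when partitioning displacement
        profiles into day (08:00-18:00) and night (18:00-08:00) blocks.
    dawn_hour : datetime.time
        Civil time taken as "dawn" when closing the delayed-response window
        (fixed clock time, not a solar ephemeris).
    censor_horizon_h : float
        Right-censoring horizon for return times, hours (6 days).
    short_return_threshold_h : float
        Threshold of the short-return dichotomy, hours.
    immediate_fix_interval_min, delayed_fix_interval_min : float
        Nominal GPS fix spacing of the intensive (hunt-day) and routine
        regimes, minutes.
    gap_tolerance_factor : float
        A step longer than this multiple of the nominal interval is flagged
        as spanning a missed fix.
    delayed_from : str
        Origin of the delayed cumulative-distance window: ``"hunt_start"``
        (default) or ``"hunt_end"``.
    boundary_buffer_m : float
        Signed buffer applied to the hunted polygon before the inside/outside
        test (0 = the shooting line itself; boundary counts as inside).
    min_dwell_fixes : int
        Number of consecutive inside fixes required to score a "return".
    ud_grid_cell_m : float
        Cell size of the utilization-distribution raster, metres.
    ud_bandwidth_rule : str
        ``"reference"`` (ad hoc rule of the kernel home-range literature) or
        ``"fixed"`` together with ``ud_bandwidth_m``.
    crs_id : str
        Declared projected CRS of all coordinates.  Geographic identifiers
        are rejected: the analysis is defined on Euclidean metres.
    """

    day_start: time = time(8, 0)
    day_end: time = time(18, 0)
    dawn_hour: time = time(8, 0)
    censor_horizon_h: float = 144.0
    short_return_threshold_h: float = 72.0
    immediate_fix_interval_min: float = 2.0
    delayed_fix_interval_min: float = 60.0
    gap_tolerance_factor: float = 2.0
    delayed_from: str = "hunt_start"
    boundary_buffer_m: float = 0.0
    min_dwell_fixes: int = 1
    ud_grid_cell_m: float = 10.0
    ud_bandwidth_rule: str = "reference"
    ud_bandwidth_m: float | None = None
    crs_id: str = "EPSG:2154"
    study_timezone: str = "Europe/Paris"
    regime_success_floor: float = 0.5
    rng_seed: int = 0

    _GEOGRAPHIC_CRS_IDS = ("4326", "4269", "4258", "CRS84", "WGS84")

    def __post_init__(self) -> None:
        for name in (
            "censor_horizon_h",
            "short_return_threshold_h",
            "immediate_fix_interval_min",
            "delayed_fix_interval_min",
            "gap_tolerance_factor",
            "ud_grid_cell_m",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.short_return_threshold_h > self.censor_horizon_h:
            raise ValueError("short_return_threshold_h must not exceed censor_horizon_h")
        if self.delayed_from not in ("hunt_start", "hunt_end"):
            raise ValueError("delayed_from must be 'hunt_start' or 'hunt_end'")
        if self.ud_bandwidth_rule not in ("reference", "fixed"):
            raise ValueError("ud_bandwidth_rule must be 'reference' or 'fixed'")
        if self.ud_bandwidth_rule == "fixed" and not self.ud_bandwidth_m:
            raise ValueError("ud_bandwidth_m required when ud_bandwidth_rule='fixed'")
        if any(tag in self.crs_id.upper() for tag in self._GEOGRAPHIC_CRS_IDS):
            raise ValueError(
                f"crs_id {self.crs_id!r} looks geographic; coordinates must be "
                "in a projected metric CRS (distances are Euclidean metres)"
            )
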