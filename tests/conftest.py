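"""Shared fixtures: a Gaussian reference UD, small synthetic datasets, and a
trajectory builder."""
from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from drivehunt import (
    Trajectory,
    estimate_ud,
    isopleth_regions,
    simulate_events,
    simulate_population,
)

GAUSS_SD = 500.0
GAUSS_N = 1000


def make_traj(
    points,
    t0="2018-01-10T10:00:00+00:00",
    interval_min=2.0,
    individual="a",
    fix_ok=None,
):
    """Trajectory from a point sequence at a fixed sampling interval."""
    pts = np.asarray(points, dtype=float)
    times = pd.date_range(
        pd.Timestamp(t0), periods=len(pts), freq=pd.Timedelta(minutes=interval_min)
    )
    ok = np.ones(len(pts), bool) if fix_ok is None else np.asarray(fix_ok, bool)
    return Trajectory(
        individual,
        pd.DataFrame({"timestamp": times, "x": pts[:, 0], "y": pts[:, 1], "fix_ok": ok}),
    )


@pytest.fixture(scope="session")
def gaussian_points():
    rng = np.random.default_rng(1)
    return rng.normal(0.0, GAUSS_SD, (GAUSS_N, 2))


@pytest.fixture(scope="session")
def gaussian_ud(gaussian_points):
    return estimate_ud(gaussian_points, cell_size=20.0)


@pytest.fixture(scope="session")
def gaussian_regions(gaussian_ud):
    return isopleth_regions(gaussian_ud)


def band_square(band, shrink=35.0, side=40.0):
    """A small square guaranteed inside a band polygon (shrink > half the
    square's diagonal)."""
    from shapely.geometry import box

    core = band.buffer(-shrink)
    assert not core.is_empty, "band too thin for the test square"
    p = core.representative_point()
    sq = box(p.x - side / 2, p.y - side / 2, p.x + side / 2, p.y + side / 2)
    assert band.contains(sq)
    return sq


@pytest.fixture(scope="session")
def events_sim_small():
    """60 standalone labelled events, default behaviour, observed with noise."""
    return simulate_events(60, rng=42)


@pytest.fixture(scope="session")
def population_sim():
    """Full default population (14 individuals, 23 hunt days)."""
    return simulate_population(rng=7)
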