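"""Fixed-kernel utilization distribution, isopleth bands and the
site-familiarity index.

The annual home range is the 95% utilization distribution (UD) estimated by
a fixed (isotropic Gaussian) kernel on 12-hourly relocations.  The UD is
split into ten nested probability bands — iso(0-10), iso(10-20), ...,
iso(90-95) — and the familiarity of a hunted area is the overlap fraction of
each band with the area, weighted by a coefficient decreasing from 1.0 in
the core to 0.15 in the outermost band:

    Fam = sum_bands w_band * area(band ∩ hunted) / area(hunted)

so Fam = 1 when the area sits wholly inside the core band and 0 when it lies
outside the 95% home range.  The intermediate weights descend linearly
(1.0, 0.9, ..., 0.2) with 0.15 for the half-width terminal band iso(90-95).
"""
from __future__ import annotations

from dataclasses import dataclass
from functools import reduce

import numpy as np
import pandas as pd
from shapely.geometry import MultiPolygon, Polygon
from shapely.ops import unary_union
from skimage import measure

from .io import HuntedArea, Trajectory

ISO_LEVELS: tuple[int, ...] = (10, 20, 30, 40, 50, 60, 70, 80, 90, 95)

#: Band weights of the familiarity index, core outwards.
BAND_WEIGHTS: dict[tuple[int, int], float] = {
    (0, 10): 1.0,
    (10, 20): 0.9,
    (20, 30): 0.8,
    (30, 40): 0.7,
    (40, 50): 0.6,
    (50, 60): 0.5,
    (60, 70): 0.4,
    (70, 80): 0.3,
    (80, 90): 0.2,
    (90, 95): 0.15,
}


class BandwidthError(ValueError):
    """Kernel bandwidth cannot be computed (degenerate point set)."""


class ResolutionError(ValueError):
    """The grid is too coarse to resolve a requested isopleth level."""


@dataclass
class UDGrid:
    """Utilization distribution on a regular grid.

    ``density`` has shape ``(ny, nx)`` in probability per m²; ``x``/``y``
    hold cell-centre coordinates.  Total mass (sum x cell area) is 1.
    """

    x: np.ndarray
    y: np.ndarray
    density: np.ndarray
    cell_size: float
    bandwidth: float

    @property
    def mass(self) -> float:
        return float(self.density.sum() * self.cell_size**2)


@dataclass
class IsoplethRegionSet:
    """Nested UD isopleth regions and the bands between them.

    ``level_polygons`` maps each level L to the minimal-area region holding
    L% of the use probability; ``bands`` lists ``(lo, hi, weight, polygon)``
    for the ten familiarity bands (set differences of successive levels).
    """

    levels: tuple[int, ...]
    level_polygons: dict[int, MultiPolygon]
    bands: list[tuple[int, int, float, MultiPolygon]]

    @property
    def home_range(self) -> MultiPolygon:
        return self.level_polygons[max(self.levels)]


def annual_relocation_subsample(traj: Trajectory, interval_h: float = 12.0) -> Trajectory:
    """Thin a trajectory to one valid fix per ``interval_h``-hour bin.

    The fix nearest each bin centre is retained; empty bins are skipped.
    Deterministic, and idempotent on already-thinned data.
    """
    fixes = traj.valid.reset_index(drop=True)
    if len(fixes) == 0:
        return Trajectory(traj.individual_id, fixes)
    ns = fixes["timestamp"].astype("int64").to_numpy()
    bin_ns = int(interval_h * 3600e9)
    bins = (ns - ns[0]) // bin_ns
    centre = ns[0] + (bins + 0.5) * bin_ns
    offset = np.abs(ns - centre)
    keep = (
        pd.DataFrame({"bin": bins, "off": offset})
        .groupby("bin")["off"]
        .idxmin()
        .to_numpy()
    )
    out = fixes.iloc[np.sort(keep)].reset_index(drop=True)
    if len(out) < 30:
        import logging

        logging.getLogger("drivehunt").warning(
            "annual_relocation_subsample: only %d fixes retained; UD unreliable",
            len(out),
        )
    return Trajectory(traj.individual_id, out)


def reference_bandwidth(points: np.ndarray) -> float:
    """Ad hoc (reference) bandwidth for a bivariate fixed kernel:
    ``sigma * n**(-1/6)`` with ``sigma**2`` the mean of the marginal
    variances."""
    pts = np.asarray(points, dtype=float)
    n = len(pts)
    sigma2 = 0.5 * (pts[:, 0].var(ddof=1) + pts[:, 1].var(ddof=1))
    if not np.isfinite(sigma2) or sigma2 <= 0:
        raise BandwidthError("degenerate point set: zero spatial variance")
    return float(np.sqrt(sigma2) * n ** (-1.0 / 6.0))


def estimate_ud(
    points: np.ndarray,
    bandwidth: float | None = None,
    cell_size: float = 10.0,
    pad_bandwidths: float = 3.0,
) -> UDGrid:
    """Gaussian fixed-kernel density of relocation points on a regular grid.

    The grid extends ``pad_bandwidths`` bandwidths beyond the data extent so
    the density is effectively zero at the border, and is renormalized to
    total mass 1.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValueError("points must be an (n, 2) array")
    if len(pts) < 5:
        raise ValueError("need at least 5 points for a kernel UD")
    if not np.isfinite(pts).all():
        raise ValueError("points must be finite")
    h = float(bandwidth) if bandwidth is not None else reference_bandwidth(pts)
    if h <= 0:
        raise BandwidthError("bandwidth must be positive")
    pad = pad_bandwidths * h
    x0, x1 = pts[:, 0].min() - pad, pts[:, 0].max() + pad
    y0, y1 = pts[:, 1].min() - pad, pts[:, 1].max() + pad
    nx = max(int(np.ceil((x1 - x0) / cell_size)) + 1, 8)
    ny = max(int(np.ceil((y1 - y0) / cell_size)) + 1, 8)
    gx = x0 + cell_size * np.arange(nx)
    gy = y0 + cell_size * np.arange(ny)

    density = np.zeros((ny, nx))
    # separable per-point Gaussian: density = sum_i g_y(i) ⊗ g_x(i)
    for lo in range(0, len(pts), 2048):
        chunk = pts[lo : lo + 2048]
        ex = np.exp(-0.5 * ((gx[None, :] - chunk[:, 0:1]) / h) ** 2)
        ey = np.exp(-0.5 * ((gy[None, :] - chunk[:, 1:2]) / h) ** 2)
        density += ey.T @ ex
    density /= 2 * np.pi * h**2 * len(pts)
    total = density.sum() * cell_size**2
    if total <= 0:
        raise BandwidthError("kernel density vanished on the grid")
    density /= total
    return UDGrid(gx, gy, density, cell_size, h)


def isopleth_threshold(ud: UDGrid, level: float) -> float:
    """Density threshold whose superlevel set is the minimal-area region
    holding ``level``/100 of the probability mass."""
    flat = np.sort(ud.density.ravel())[::-1]
    cmass = np.cumsum(flat) * ud.cell_size**2
    target = level / 100.0
    idx = int(np.searchsorted(cmass, target))
    if idx >= len(flat):
        raise ResolutionError(f"grid cannot resolve the {level}% isopleth")
    return float(flat[idx])


def _rings_to_region(contours: list[np.ndarray]) -> MultiPolygon:
    """Even-odd assembly of marching-squares rings into a region.

    Nested rings alternate shell/hole, so the filled region is the symmetric
    difference of the ring polygons.
    """
    polys = []
    for ring in contours:
        if len(ring) < 4:
            continue
        p = Polygon(ring)
        if not p.is_valid:
            p = p.buffer(0)
        if not p.is_empty:
            polys.append(p)
    if not polys:
        return MultiPolygon([])
    region = reduce(lambda a, b: a.symmetric_difference(b), polys)
    if region.geom_type == "Polygon":
        region = MultiPolygon([region])
    elif region.geom_type != "MultiPolygon":
        region = MultiPolygon(
            [g for g in getattr(region, "geoms", []) if g.geom_type == "Polygon"]
        )
    return region


def level_region(ud: UDGrid, level: float) -> MultiPolygon:
    """Polygonized minimal-area region holding ``level``% of the UD mass
    (marching squares on the zero-padded density grid)."""
    c = isopleth_threshold(ud, level)
    padded = np.pad(ud.density, 1, constant_values=0.0)
    contours = measure.find_contours(padded, c)
    world = []
    for cont in contours:
        # rows index y, cols index x; padding shifts indices by one cell
        xy = np.column_stack(
            [
                ud.x[0] + (cont[:, 1] - 1) * ud.cell_size,
                ud.y[0] + (cont[:, 0] - 1) * ud.cell_size,
            ]
        )
        world.append(xy)
    return _rings_to_region(world)


def isopleth_regions(
    ud: UDGrid, levels: tuple[int, ...] = ISO_LEVELS
) -> IsoplethRegionSet:
    """Extract the nested isopleth regions and the familiarity bands."""
    levels = tuple(sorted(levels))
    level_polygons = {lv: level_region(ud, lv) for lv in levels}
    bands = []
    prev_level = 0
    prev_poly: MultiPolygon | None = None
    for lv in levels:
        cur = level_polygons[lv]
        band = cur if prev_poly is None else cur.difference(prev_poly)
        weight = BAND_WEIGHTS.get((prev_level, lv))
        if weight is None:
            # non-default level partition: interpolate the linear descent
            weight = max(0.15, 1.0 - prev_level / 100.0)
        bands.append((prev_level, lv, weight, band))
        prev_level, prev_poly = lv, cur
    return IsoplethRegionSet(levels, level_polygons, bands)


def familiarity_index(
    regions: IsoplethRegionSet, area: HuntedArea | Polygon | MultiPolygon
) -> float:
    """Weighted band-overlap familiarity of a hunted area, in [0, 1].

    Any part of the hunted area outside the 95% home range contributes 0.
    """
    poly = area.polygon if isinstance(area, HuntedArea) else area
    if poly.area <= 0:
        raise ValueError("hunted area polygon has zero area")
    fam = 0.0
    for _lo, _hi, w, band in regions.bands:
        if band.is_empty:
            continue
        fam += w * band.intersection(poly).area / poly.area
    return float(min(max(fam, 0.0), 1.0))


def band_overlap_fractions(
    regions: IsoplethRegionSet, area: HuntedArea | Polygon | MultiPolygon
) -> pd.DataFrame:
    """Per-band overlap fractions behind the familiarity index."""
    poly = area.polygon if isinstance(area, HuntedArea) else area
    rows = []
    for lo, hi, w, band in regions.bands:
        frac = 0.0 if band.is_empty else band.intersection(poly).area / poly.area
        rows.append({"band": f"iso({lo}-{hi})", "weight": w, "overlap_fraction": frac})
    return pd.DataFrame(rows)


def familiarity_table(
    trajectories: dict[str, Trajectory],
    areas: dict[str, HuntedArea],
    cell_size: float = 10.0,
    bandwidth: float | None = None,
    subsample_interval_h: float = 12.0,
) -> pd.DataFrame:
    """Familiarity of every hunted area for every individual.

    One kernel UD per individual from 12-hourly subsampled relocations, then
    the weighted overlap with each area polygon.
    """
    rows = []
    for ind, traj in trajectories.items():
        sub = annual_relocation_subsample(traj, subsample_interval_h)
        pts = sub.valid[["x", "y"]].to_numpy(dtype=float)
        regions = isopleth_regions(estimate_ud(pts, bandwidth, cell_size))
        for aid, area in areas.items():
            rows.append(
                {
                    "individual_id": ind,
                    "area_id": aid,
                    "fam_index": familiarity_index(regions, area),
                }
            )
    return pd.DataFrame(rows)
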