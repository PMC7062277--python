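"""Kernel home range, isopleth bands and the familiarity index.

The annual utilization distribution (UD) is split into ten nested bands
between the 10, 20, ..., 90 and 95% isopleths.  A hunted area overlapping
the core scores near 1; one outside the 95% home range scores 0.
"""
import numpy as np
from shapely.geometry import Point

from drivehunt import estimate_ud, familiarity_index, isopleth_regions
from drivehunt.familiarity import band_overlap_fractions

# a year of 12-hourly relocations from a stationary home range
rng = np.random.default_rng(3)
points = rng.normal(0.0, 500.0, (730, 2))

ud = estimate_ud(points, cell_size=20.0)
regions = isopleth_regions(ud)
print(f"bandwidth (reference rule): {ud.bandwidth:.1f} m")
print(f"95% home range area       : {regions.home_range.area / 1e4:.0f} ha")

core_area = Point(0, 0).buffer(250)          # overlapping the UD core
edge_area = Point(1100, 0).buffer(250)       # straddling outer bands
far_area = Point(6000, 6000).buffer(250)     # outside the home range

for name, poly in (("core", core_area), ("edge", edge_area), ("far", far_area)):
    print(f"familiarity of {name} area : {familiarity_index(regions, poly):.3f}")

print("\nper-band overlap of the edge area:")
frac = band_overlap_fractions(regions, edge_area)
print(frac[frac.overlap_fraction > 0].round(3).to_string(index=False))
# The index is the overlap-weighted sum: core bands weigh 1.0 down to 0.15
# for the outermost (90-95%) band.
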