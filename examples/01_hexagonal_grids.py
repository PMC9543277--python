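"""Equal-area hexagonal grids, planar and spherical, plus DGGS arithmetic.

Global diversity analyses bin species occurrences into equal-area cells so
counts are comparable across latitudes.  This script builds a planar grid,
an equal-area grid on a latitude band of the sphere, and reproduces the
cell size of the standard aperture-3 icosahedral grid at resolution 7.
"""

import math

import paranet as pn
from paranet.grid import spherical_polygon_area

# planar: a 3300 x 2850 km rectangle tiled with ~23,323 km2 hexagons
grid = pn.build_planar_hex_grid((0, 0, 3300, 2850), 23323.0)
print(f"planar grid: {len(grid)} cells, every cell exactly "
      f"{grid.cells[0].area:,.0f} km2")

# sphere: same cell size across the +/-60 degree latitude band
sphere = pn.build_sphere_hex_grid(23323.0, 60.0)
mid = sphere.cells[len(sphere) // 2]
print(f"sphere grid: {len(sphere)} cells; spherical area of one cell = "
      f"{spherical_polygon_area(mid.polygon):,.1f} km2")
band = 2 * math.pi * pn.EARTH_RADIUS_KM**2 * 2 * math.sin(math.radians(60))
print(f"tiled area / band area = {len(sphere) * 23323.0 / band:.4f}")

# DGGS arithmetic: the aperture-3 hierarchy halves... thirds the cell area
# at each resolution; resolution 7 is the global-analysis standard
count = pn.dggs_cell_count(3, 7)
area = pn.dggs_mean_cell_area(3, 7)
print(f"aperture-3 resolution-7 grid: {count:,} cells of {area:,.0f} km2 "
      f"(the ~23,323 km2 hexagons of global bird analyses)")
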