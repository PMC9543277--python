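"""Equal-area hexagonal grids.

Global macroecological analyses commonly discretise the Earth into
equal-area hexagonal cells (a discrete global grid system, DGGS) so that
per-cell species counts are comparable everywhere.  This module provides

* an exact regular-hexagon tessellation of a planar (km) rectangle,
* an equal-area tessellation of a latitude band on the sphere, built in
  the Lambert cylindrical equal-area projection and inverse-projected,
* the cell-count / mean-cell-area arithmetic of aperture-3/4/7 icosahedral
  DGGS hierarchies (used to reproduce the ~23,323 km2 cell size of an
  aperture-3 grid at resolution 7), and
* GeoJSON persistence and land-clipping utilities.

A true icosahedral Snyder (ISEA) projection is deliberately out of scope:
the load-bearing property for downstream analysis is equal cell area, which
both tessellations here deliver exactly (planar) or to projection accuracy
(sphere).  Planar coordinates are kilometres; spherical coordinates are
lon/lat decimal degrees with lon in [-180, 180).
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy.spatial import cKDTree
from shapely.geometry import Polygon, shape, mapping
from shapely.strtree import STRtree

#: Authalic Earth radius in km (sphere with the same surface area as the
#: reference ellipsoid); the natural Earth model for equal-area grids.
EARTH_RADIUS_KM = 6371.007

_PENTAGON_COUNT = 12  # vertices of the icosahedron


class GridError(ValueError):
    """Invalid grid construction arguments or malformed grid files."""


@dataclass(frozen=True)
class GridCell:
    """One grid cell: a simple closed polygon with a stable identifier.

    ``polygon`` vertices are (x, y) km for planar grids or (lon, lat)
    degrees for spherical grids, counter-clockwise, not repeating the
    first vertex.  ``area`` is km2.
    """

    cell_id: str
    polygon: tuple[tuple[float, float], ...]
    centroid: tuple[float, float]
    area: float

    def shapely(self) -> Polygon:
        return Polygon(self.polygon)


@dataclass
class Grid:
    """An ordered collection of cells sharing one coordinate convention.

    ``crs_kind`` is ``"planar_km"`` or ``"lonlat_sphere"``.
    """

    cells: list[GridCell]
    crs_kind: str
    target_area: float
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        ids = [c.cell_id for c in self.cells]
        if len(set(ids)) != len(ids):
            raise GridError("duplicate cell_ids in grid")

    def __len__(self) -> int:
        return len(self.cells)

    @property
    def cell_ids(self) -> list[str]:
        return [c.cell_id for c in self.cells]

    def centroids(self) -> np.ndarray:
        return np.array([c.centroid for c in self.cells], dtype=float)

    def cell(self, cell_id: str) -> GridCell:
        try:
            return next(c for c in self.cells if c.cell_id == cell_id)
        except StopIteration:
            raise KeyError(f"unknown cell_id {cell_id!r}") from None

    def locate(self, points: np.ndarray) -> np.ndarray:
        """Assign planar points to cells by nearest centroid.

        For a regular hexagonal lattice the Voronoi region of each centroid
        is the hexagon itself, so nearest-centroid assignment is exact and
        unique (boundary ties resolve by KD-tree order, giving the
        half-open tiling convention).  Returns an index into ``cells``.
        """
        if self.crs_kind != "planar_km":
            raise GridError("locate() supports planar grids only")
        tree = cKDTree(self.centroids())
        _, idx = tree.query(np.atleast_2d(points))
        return idx


def _hex_side(target_area: float) -> float:
    # regular hexagon area = (3*sqrt(3)/2) s^2
    return math.sqrt(2.0 * target_area / (3.0 * math.sqrt(3.0)))


def _pointy_hexagon(cx: float, cy: float, s: float) -> tuple[tuple[float, float], ...]:
    # CCW starting at 30 deg; vertices at 90/270 deg make it pointy-top
    return tuple(
        (cx + s * math.cos(math.radians(a)), cy + s * math.sin(math.radians(a)))
        for a in (30, 90, 150, 210, 270, 330)
    )


def build_planar_hex_grid(
    extent: tuple[float, float, float, float], target_area: float
) -> Grid:
    """Tile a planar rectangle with regular hexagons of exactly ``target_area``.

    Parameters
    ----------
    extent
        (xmin, ymin, xmax, ymax) in km.  Cells are laid out pointy-top in
        offset rows; boundary cells may extend beyond the extent so that
        the rectangle is covered without gaps.
    target_area
        Cell area in km2; every cell has this area (regular hexagons).

    Cell ids are deterministic row-major ``"r{row}c{col}"`` lattice indices.
    """
    xmin, ymin, xmax, ymax = extent
    if not (xmax > xmin and ymax > ymin):
        raise GridError("extent must have positive width and height")
    if not target_area > 0:
        raise GridError("target_area must be positive")
    s = _hex_side(target_area)
    dx = s * math.sqrt(3.0)  # horizontal centroid spacing
    dy = 1.5 * s             # vertical row spacing
    from shapely.geometry import box as _box

    extent_box = _box(xmin, ymin, xmax, ymax)
    j0 = math.floor((ymin - s) / dy)
    j1 = math.ceil((ymax + s) / dy)
    cells: list[GridCell] = []
    for j in range(j0, j1 + 1):
        cy = j * dy
        xoff = 0.5 * dx if (j % 2) else 0.0
        i0 = math.floor((xmin - dx - xoff) / dx)
        i1 = math.ceil((xmax + dx - xoff) / dx)
        for i in range(i0, i1 + 1):
            cx = i * dx + xoff
            # cheap bounding prefilter, then an exact positive-area check so
            # cells touching the extent only tangentially are not kept
            if cx + dx / 2 < xmin or cx - dx / 2 > xmax:
                continue
            if cy + s < ymin or cy - s > ymax:
                continue
            hexagon = _pointy_hexagon(cx, cy, s)
            if Polygon(hexagon).intersection(extent_box).area <= 1e-12 * target_area:
                continue
            cells.append(
                GridCell(
                    cell_id=f"r{j}c{i}",
                    polygon=hexagon,
                    centroid=(cx, cy),
                    area=target_area,
                )
            )
    return Grid(
        cells=cells,
        crs_kind="planar_km",
        target_area=target_area,
        metadata={"provenance": "generated:planar", "extent": list(extent), "side_km": s},
    )


def _cea_inverse(x: float, y: float, radius: float, wrap: bool = True) -> tuple[float, float]:
    """Lambert cylindrical equal-area (x = R*lon_rad, y = R*sin(lat)) inverse."""
    lon = math.degrees(x / radius)
    lat = math.degrees(math.asin(min(1.0, max(-1.0, y / radius))))
    if wrap and lon >= 180.0:
        lon -= 360.0
    return lon, lat


def build_sphere_hex_grid(
    target_area: float,
    lat_band: float,
    earth_radius: float = EARTH_RADIUS_KM,
    edge_points: int = 8,
) -> Grid:
    """Equal-area hexagonal cells covering a latitude band on the sphere.

    The band ``|lat| <= lat_band`` is mapped with the Lambert cylindrical
    equal-area projection (x = R*lon, y = R*sin(lat)), tiled there with
    regular hexagons of exactly ``target_area``, and each hexagon is mapped
    back to lon/lat.  Because the projection preserves area, every returned
    cell encloses ``target_area`` km2 on the sphere; cell *shapes* distort
    towards high latitude, which is accepted.  Hexagon edges are densified
    with ``edge_points`` intermediate vertices so the lon/lat polygon
    follows the true image of the planar hexagon.

    Cells whose planar hexagon crosses the antimeridian seam are dropped
    (a thin gap of less than one cell width), as are cells with centroids
    outside the band.
    """
    sphere_area = 4.0 * math.pi * earth_radius**2
    if not (0 < target_area < sphere_area):
        raise GridError("target_area must be in (0, Earth surface area)")
    if not (0 < abs(lat_band) <= 85.0):
        raise GridError(
            "lat_band must be non-zero and within +/-85 degrees "
            "(polar caps are not supported by the cylindrical tessellation)"
        )
    lat_band = abs(lat_band)
    ymax = earth_radius * math.sin(math.radians(lat_band))
    xmax = math.pi * earth_radius
    s = _hex_side(target_area)
    dx = s * math.sqrt(3.0)
    dy = 1.5 * s
    cells: list[GridCell] = []
    # number of hexagon rows that best tiles the band height: each row tiles
    # a strip of height dy, so round(2*ymax/dy) rows make the total tiled
    # area match the band area to within half a row
    n_rows = max(1, round(2.0 * ymax / dy))
    j0 = -(n_rows // 2)
    for j in range(j0, j0 + n_rows):
        cy = j * dy
        if abs(cy) + s > earth_radius:  # vertex would leave the projection domain
            continue
        xoff = 0.5 * dx if (j % 2) else 0.0
        i0 = math.floor((-xmax - xoff) / dx)
        i1 = math.ceil((xmax - xoff) / dx)
        for i in range(i0, i1 + 1):
            cx = i * dx + xoff
            if not (-xmax <= cx < xmax):  # centroid criterion at the seam
                continue
            # cells straddling the antimeridian keep a continuous (unwrapped)
            # lon ring so the polygon stays simple; lon may slightly exceed
            # the principal range, mirroring planar boundary cells
            wrap = cx + dx / 2 <= xmax and cx - dx / 2 >= -xmax
            hexagon = _pointy_hexagon(cx, cy, s)
            ring: list[tuple[float, float]] = []
            for k in range(6):
                x0, y0 = hexagon[k]
                x1, y1 = hexagon[(k + 1) % 6]
                for t in range(edge_points):
                    f = t / edge_points
                    ring.append(
                        _cea_inverse(x0 + f * (x1 - x0), y0 + f * (y1 - y0),
                                     earth_radius, wrap=wrap)
                    )
            cells.append(
                GridCell(
                    cell_id=f"b{j}i{i}",
                    polygon=tuple(ring),
                    centroid=_cea_inverse(cx, cy, earth_radius),
                    area=target_area,
                )
            )
    return Grid(
        cells=cells,
        crs_kind="lonlat_sphere",
        target_area=target_area,
        metadata={
            "provenance": "generated:cea_sphere",
            "lat_band": lat_band,
            "earth_radius_km": earth_radius,
            "side_km": s,
        },
    )


def dggs_cell_count(aperture: int, resolution: int) -> int:
    """Cell count of an icosahedral hexagonal DGGS: 10*aperture^resolution + 2.

    The +2 accounts for the 12 pentagonal cells minus the 10 hexagons they
    replace; equivalently, resolution 0 is the 12 icosahedron vertices.
    """
    if aperture not in (3, 4, 7):
        raise GridError(f"unsupported aperture {aperture!r}; must be 3, 4 or 7")
    if not (isinstance(resolution, (int, np.integer)) and resolution >= 0):
        raise GridError("resolution must be a non-negative integer")
    return 10 * aperture**resolution + 2


def dggs_mean_cell_area(
    aperture: int, resolution: int, earth_radius: float = EARTH_RADIUS_KM
) -> float:
    """Mean DGGS cell area in km2: sphere area / cell count.

    At aperture 3, resolution 7 this is ~23,322 km2, the standard cell
    size for global hexagonal biodiversity grids.
    """
    if not earth_radius > 0:
        raise GridError("earth_radius must be positive")
    return 4.0 * math.pi * earth_radius**2 / dggs_cell_count(aperture, resolution)


def clip_grid_to_land(grid: Grid, land: Iterable[Polygon]) -> Grid:
    """Retain cells sharing positive area with any land polygon.

    Tangential (zero-area) contact does not count.  Cell ids are preserved.
    """
    land = list(land)
    if not land:
        warnings.warn("empty land set: clipped grid has no cells", stacklevel=2)
        return Grid([], grid.crs_kind, grid.target_area, dict(grid.metadata, clipped=True))
    tree = STRtree(land)
    kept = []
    for cell in grid.cells:
        poly = cell.shapely()
        for k in tree.query(poly):
            if poly.intersection(land[k]).area > 1e-12:
                kept.append(cell)
                break
    return Grid(kept, grid.crs_kind, grid.target_area, dict(grid.metadata, clipped=True))


def planar_polygon_area(coords: Sequence[tuple[float, float]]) -> float:
    return Polygon(coords).area


def spherical_polygon_area(
    coords: Sequence[tuple[float, float]], radius: float = EARTH_RADIUS_KM
) -> float:
    """Area (km2) of a geodesic polygon given lon/lat vertices.

    Triangulates from the vertex mean direction and sums signed spherical
    triangle areas via the van Oosterom-Strackee excess formula, which is
    numerically stable for small triangles.
    """
    lonlat = np.asarray(coords, dtype=float)
    lam = np.radians(lonlat[:, 0])
    phi = np.radians(lonlat[:, 1])
    v = np.column_stack(
        [np.cos(phi) * np.cos(lam), np.cos(phi) * np.sin(lam), np.sin(phi)]
    )
    center = v.mean(axis=0)
    center /= np.linalg.norm(center)
    total = 0.0
    n = len(v)
    for k in range(n):
        a, b, c = center, v[k], v[(k + 1) % n]
        num = np.dot(a, np.cross(b, c))
        den = 1.0 + np.dot(a, b) + np.dot(b, c) + np.dot(c, a)
        total += 2.0 * math.atan2(num, den)
    return abs(total) * radius**2


def cell_area(polygon: Sequence[tuple[float, float]], crs_kind: str,
              radius: float = EARTH_RADIUS_KM) -> float:
    if crs_kind == "planar_km":
        return planar_polygon_area(polygon)
    if crs_kind == "lonlat_sphere":
        return spherical_polygon_area(polygon, radius)
    raise GridError(f"unknown crs_kind {crs_kind!r}")


def save_grid(grid: Grid, path) -> None:
    """Write a grid as a GeoJSON FeatureCollection (cell_id, area_km2)."""
    features = []
    for c in grid.cells:
        features.append(
            {
                "type": "Feature",
                "geometry": mapping(c.shapely()),
                "properties": {"cell_id": c.cell_id, "area_km2": c.area},
            }
        )
    doc = {
        "type": "FeatureCollection",
        "crs_kind": grid.crs_kind,
        "target_area_km2": grid.target_area,
        "metadata": grid.metadata,
        "features": features,
    }
    with open(path, "w") as fh:
        json.dump(doc, fh)


def load_grid(path, crs_kind: str | None = None) -> Grid:
    """Load a GeoJSON FeatureCollection of hexagons into a Grid.

    Every feature must carry a ``cell_id`` property; areas are recomputed
    from the geometry (an externally produced file's stated areas are not
    trusted).  ``crs_kind`` falls back to the file's own declaration, then
    to ``"planar_km"``.
    """
    with open(path) as fh:
        doc = json.load(fh)
    if doc.get("type") != "FeatureCollection":
        raise GridError("grid file must be a GeoJSON FeatureCollection")
    kind = crs_kind or doc.get("crs_kind", "planar_km")
    cells = []
    seen: set[str] = set()
    for idx, feat in enumerate(doc.get("features", [])):
        props = feat.get("properties") or {}
        if "cell_id" not in props:
            raise GridError(f"feature {idx} is missing the cell_id property")
        cid = str(props["cell_id"])
        if cid in seen:
            raise GridError(f"duplicate cell_id {cid!r} at feature {idx}")
        seen.add(cid)
        geom = shape(feat["geometry"])
        if geom.geom_type != "Polygon":
            raise GridError(f"feature {idx} ({cid}): expected Polygon, got {geom.geom_type}")
        ring = tuple((float(x), float(y)) for x, y in geom.exterior.coords[:-1])
        centroid = (geom.centroid.x, geom.centroid.y)
        cells.append(GridCell(cid, ring, centroid, cell_area(ring, kind)))
    target = doc.get("target_area_km2") or (
        float(np.median([c.area for c in cells])) if cells else 0.0
    )
    return Grid(cells, kind, target, doc.get("metadata", {"provenance": "loaded"}))
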