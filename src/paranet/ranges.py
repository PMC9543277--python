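"""Species range polygons and range-by-grid presence-absence.

Reads breeding-range polygon layers (GeoJSON dialect), optionally filtering
range parts to the native breeding range (the convention of global range-map
products: presence = extant, origin = native, seasonal = resident or
breeding), and intersects ranges with a hexagonal grid to produce the
cell x species presence-absence matrix that drives all per-cell analyses.

The intersection predicate defaults to "any positive-area overlap": a
species is present in a cell if its range shares any area with the cell.
This is the inclusive reading appropriate for *potential* interaction
networks; a fractional-overlap threshold is available for sensitivity
analyses.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from shapely.geometry import shape, mapping
from shapely.geometry.base import BaseGeometry
from shapely.ops import unary_union
from shapely.strtree import STRtree

from .grid import Grid
from .species import normalize_species_name

logger = logging.getLogger(__name__)

# Integer attribute codes used by range-map products for part filtering.
PRESENCE_EXTANT = 1
ORIGIN_NATIVE = 1
SEASONAL_RESIDENT = 1
SEASONAL_BREEDING = 2


class RangeFormatError(ValueError):
    """Malformed range layer."""


@dataclass
class SpeciesRange:
    """All range polygons for one species (multi-part allowed)."""

    species_id: str
    polygons: list[BaseGeometry]
    attributes: dict = field(default_factory=dict)

    def union(self) -> BaseGeometry:
        return unary_union(self.polygons)


def _part_is_native_breeding(props: dict) -> bool:
    keys = ("presence", "origin", "seasonal")
    if not any(k in props for k in keys):
        return True  # attribute-free layer: keep everything, caller warns
    ok = True
    if "presence" in props:
        ok &= int(props["presence"]) == PRESENCE_EXTANT
    if "origin" in props:
        ok &= int(props["origin"]) == ORIGIN_NATIVE
    if "seasonal" in props:
        ok &= int(props["seasonal"]) in (SEASONAL_RESIDENT, SEASONAL_BREEDING)
    return ok


def read_ranges(
    path,
    attribute_filter: str = "native_breeding",
    species_field: str = "species",
    synonyms: dict[str, str] | None = None,
) -> list[SpeciesRange]:
    """Read a polygon layer into one SpeciesRange per species.

    Multiple features for the same (normalised) species name are merged
    into one multi-part range.  With ``attribute_filter="native_breeding"``
    parts are kept only if presence=extant, origin=native and seasonal in
    {resident, breeding}; features without those fields are kept with a
    logged warning.  ``attribute_filter="all"`` keeps every part.
    """
    if attribute_filter not in ("native_breeding", "all"):
        raise ValueError(f"unknown attribute_filter {attribute_filter!r}")
    with open(path) as fh:
        doc = json.load(fh)
    features = doc.get("features", [])
    if not features:
        warnings.warn(f"{path}: no features in range layer", stacklevel=2)
        return []
    by_species: dict[str, SpeciesRange] = {}
    missing_attrs = 0
    dropped: dict[str, int] = {}
    for idx, feat in enumerate(features):
        props = feat.get("properties") or {}
        if species_field not in props:
            raise RangeFormatError(
                f"feature {idx} is missing the species field {species_field!r}"
            )
        name = normalize_species_name(props[species_field], synonyms)
        if attribute_filter == "native_breeding":
            if not any(k in props for k in ("presence", "origin", "seasonal")):
                missing_attrs += 1
            elif not _part_is_native_breeding(props):
                dropped[name] = dropped.get(name, 0) + 1
                continue
        geom = shape(feat["geometry"])
        sr = by_species.setdefault(name, SpeciesRange(name, [], {}))
        sr.polygons.append(geom)
        for k in ("presence", "origin", "seasonal"):
            if k in props:
                sr.attributes[k] = props[k]
    if missing_attrs:
        logger.warning(
            "%d features lack presence/origin/seasonal attributes; kept as-is",
            missing_attrs,
        )
    for name, n in dropped.items():
        if name not in by_species:
            warnings.warn(
                f"species {name!r}: all {n} range parts removed by the "
                f"native_breeding filter; species dropped",
                stacklevel=2,
            )
    return list(by_species.values())


def write_ranges(ranges: list[SpeciesRange], path, species_field: str = "species") -> None:
    features = []
    for sr in ranges:
        for poly in sr.polygons:
            props = {species_field: sr.species_id, **sr.attributes}
            features.append(
                {"type": "Feature", "geometry": mapping(poly), "properties": props}
            )
    with open(path, "w") as fh:
        json.dump({"type": "FeatureCollection", "features": features}, fh)


@dataclass
class PresenceMatrix:
    """Boolean cell x species occupancy."""

    cell_ids: list[str]
    species_ids: list[str]
    present: np.ndarray  # bool, shape (n_cells, n_species)

    def __post_init__(self) -> None:
        self.present = np.asarray(self.present, dtype=bool)
        if self.present.shape != (len(self.cell_ids), len(self.species_ids)):
            raise ValueError("presence matrix shape does not match id lists")
        self._cell_index = {c: i for i, c in enumerate(self.cell_ids)}
        self._species_index = {s: j for j, s in enumerate(self.species_ids)}

    def is_present(self, cell_id: str, species_id: str) -> bool:
        j = self._species_index.get(species_id)
        if j is None:
            return False
        return bool(self.present[self._cell_index[cell_id], j])

    def species_in_cell(self, cell_id: str) -> set[str]:
        row = self.present[self._cell_index[cell_id]]
        return {self.species_ids[j] for j in np.flatnonzero(row)}

    def to_long_frame(self) -> pd.DataFrame:
        rows, cols = np.nonzero(self.present)
        return pd.DataFrame(
            {
                "cell_id": [self.cell_ids[i] for i in rows],
                "species_id": [self.species_ids[j] for j in cols],
            }
        )

    def to_wide_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.present.astype(int), index=self.cell_ids, columns=self.species_ids
        )


def presence_absence(
    grid: Grid,
    ranges: list[SpeciesRange],
    predicate: str = "any_overlap",
    min_fraction: float = 0.0,
) -> PresenceMatrix:
    """Intersect ranges with grid cells into a presence-absence matrix.

    ``predicate="any_overlap"`` marks a species present in every cell its
    range overlaps with positive area (tangential contact is absent);
    ``predicate="fraction"`` requires intersection area >= min_fraction x
    cell area.
    """
    if predicate not in ("any_overlap", "fraction"):
        raise ValueError(f"unknown predicate {predicate!r}")
    range_kind = {sr.attributes.get("crs_kind") for sr in ranges} - {None}
    if range_kind and range_kind != {grid.crs_kind}:
        raise ValueError(
            f"crs mismatch: grid is {grid.crs_kind}, ranges declare {range_kind}"
        )
    cell_polys = [c.shapely() for c in grid.cells]
    tree = STRtree(cell_polys)
    present = np.zeros((len(grid.cells), len(ranges)), dtype=bool)
    for j, sr in enumerate(ranges):
        geom = sr.union()
        if geom.is_empty:
            continue
        for i in tree.query(geom):
            inter = cell_polys[i].intersection(geom).area
            if predicate == "any_overlap":
                present[i, j] = inter > 1e-12
            else:
                present[i, j] = inter >= min_fraction * grid.cells[i].area
    return PresenceMatrix(grid.cell_ids, [sr.species_id for sr in ranges], present)


def richness(presence: PresenceMatrix, species_subset) -> pd.Series:
    """Per-cell count of present species from ``species_subset``."""
    subset = list(species_subset)
    unknown = sorted(set(subset) - set(presence.species_ids))
    if unknown:
        raise KeyError(f"unknown species in subset: {unknown}")
    cols = [presence._species_index[s] for s in subset]
    counts = (
        presence.present[:, cols].sum(axis=1) if cols
        else np.zeros(len(presence.cell_ids), dtype=int)
    )
    return pd.Series(counts, index=presence.cell_ids, name="richness")
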