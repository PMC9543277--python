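"""End-to-end orchestration: grid -> presence -> networks -> regressions.

``run_pipeline`` drives the whole analysis from one configuration: build
or load the grid, read ranges and the interaction list, assemble the
per-cell complexity table, then regress linkage density on each richness
covariate separately (parasite richness, host richness, and — when an
all-bird range layer is supplied — total bird richness), with both OLS and
the spatial-error SAR on 200 km row-standardised distance-band weights.
Regressions use only cells with a defined (non-empty-network) linkage
density.  Artifacts are written as plain text: CSV, GeoJSON, GAL weights
and one JSON model report per covariate.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from shapely.geometry import mapping

from . import networks, ranges as ranges_io, spatial
from .grid import Grid, build_planar_hex_grid, load_grid, save_grid
from .interactions import InteractionTable, read_interactions, species_summaries

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    def __init__(self, stage: str, code: str, message: str):
        super().__init__(f"[{stage}:{code}] {message}")
        self.stage = stage
        self.code = code


@dataclass
class RunConfig:
    """Everything one pipeline run needs.  Exactly one grid source."""

    out_dir: str
    interactions_path: str
    ranges_path: str
    grid_path: str | None = None
    grid_extent: tuple[float, float, float, float] | None = None
    grid_target_area: float = 23323.0
    land_path: str | None = None
    all_bird_ranges_path: str | None = None
    predicate: str = "any_overlap"
    min_fraction: float = 0.0
    threshold_km: float = 200.0
    covariates: tuple[str, ...] = ("parasite_richness", "host_richness")
    response: str = "linkage_density"
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "grid_extent" in raw and raw["grid_extent"] is not None:
            raw["grid_extent"] = tuple(raw["grid_extent"])
        if "covariates" in raw:
            raw["covariates"] = tuple(raw["covariates"])
        return cls(**raw)

    def validate(self) -> None:
        if (self.grid_path is None) == (self.grid_extent is None):
            raise ValueError("exactly one of grid_path / grid_extent is required")
        for p in (self.interactions_path, self.ranges_path, self.grid_path,
                  self.land_path, self.all_bird_ranges_path):
            if p is not None and not Path(p).exists():
                raise ValueError(f"path does not exist: {p}")


def _fit_models(df: pd.DataFrame, grid: Grid, response: str, covariates, threshold_km):
    """OLS + error-SAR of the response on each covariate, fitted separately."""
    defined = df[np.isfinite(df[response])].copy()
    if len(defined) < 10:
        raise PipelineError("stats", "too_few_cells",
                            f"only {len(defined)} cells have a defined {response}")
    order = {cid: i for i, cid in enumerate(grid.cell_ids)}
    idx = defined["cell_id"].map(order).to_numpy()
    centroids = grid.centroids()[idx]
    metric = "euclidean_km" if grid.crs_kind == "planar_km" else "great_circle"
    weights = spatial.distance_band_weights(centroids, threshold_km, metric=metric)
    if weights.islands:
        logger.warning("%d regression cells have no neighbour within %.0f km "
                       "and keep untransformed errors", len(weights.islands), threshold_km)
    y = defined[response].to_numpy(float)
    reports = {}
    for cov in covariates:
        if cov not in defined.columns:
            raise PipelineError("stats", "missing_covariate", cov)
        X = np.column_stack([np.ones(len(defined)), defined[cov].to_numpy(float)])
        ols = spatial.ols_fit(y, X)
        sar = spatial.sar_error_fit(y, X, weights)
        reports[cov] = {
            "response": response,
            "covariate": cov,
            "n": ols.n,
            "ols": {
                "beta": list(map(float, ols.beta)),
                "r2": ols.r2,
                "F": ols.F,
                "df": list(ols.df),
                "logLik": ols.logLik,
            },
            "sar": sar.report(),
            "n_islands": len(weights.islands),
        }
    return reports, weights, defined


def run_pipeline(config: RunConfig) -> dict:
    """Run the full analysis; returns a dict of artifact paths and tables."""
    config.validate()
    logging.basicConfig(level=config.log_level)
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    # --- grid ---
    if config.grid_path:
        grid = load_grid(config.grid_path)
    else:
        grid = build_planar_hex_grid(config.grid_extent, config.grid_target_area)
    logger.info("grid: %d cells (%s)", len(grid), grid.crs_kind)
    if config.land_path:
        from shapely.geometry import shape
        from .grid import clip_grid_to_land
        with open(config.land_path) as fh:
            land_doc = json.load(fh)
        land = [shape(f["geometry"]) for f in land_doc.get("features", [])]
        before = len(grid)
        grid = clip_grid_to_land(grid, land)
        logger.info("land clip: %d -> %d cells", before, len(grid))

    # --- interactions ---
    table = read_interactions(config.interactions_path)
    if not table.edges:
        raise PipelineError("interactions", "empty",
                            f"no interaction rows in {config.interactions_path}")
    logger.info("interactions: %d edges, %d parasites, %d hosts",
                len(table), len(table.parasite_ids), len(table.host_ids))

    # --- presence ---
    species_ranges = ranges_io.read_ranges(config.ranges_path)
    missing = sorted(table.species_ids - {sr.species_id for sr in species_ranges})
    if missing:
        logger.warning("%d interacting species have no range polygon and can "
                       "occur in no cell: %s", len(missing), missing[:5])
    net_ranges = [sr for sr in species_ranges if sr.species_id in table.species_ids]
    presence = ranges_io.presence_absence(
        grid, net_ranges, predicate=config.predicate, min_fraction=config.min_fraction
    )
    all_bird = None
    if config.all_bird_ranges_path:
        all_ranges = ranges_io.read_ranges(config.all_bird_ranges_path)
        all_bird = ranges_io.presence_absence(
            grid, all_ranges, predicate=config.predicate,
            min_fraction=config.min_fraction,
        )

    # --- networks ---
    df = networks.complexity_table(grid, presence, table, all_bird)
    n_defined = int(np.isfinite(df["linkage_density"]).sum())
    logger.info("networks: %d/%d cells have a non-empty potential network",
                n_defined, len(df))
    csv_path = out / "complexity.csv"
    df.to_csv(csv_path, index=False)
    geojson_path = out / "complexity.geojson"
    _write_complexity_geojson(grid, df, geojson_path)

    # --- statistics ---
    covs = list(config.covariates)
    if all_bird is not None and "total_bird_richness" not in covs:
        covs.append("total_bird_richness")
    reports, weights, defined = _fit_models(
        df, grid, config.response, covs, config.threshold_km
    )
    weights_path = out / "weights.gal"
    weights.to_gal(weights_path, ids=list(defined["cell_id"]))
    report_paths = {}
    for cov, rep in reports.items():
        rp = out / f"model_{cov}.json"
        with open(rp, "w") as fh:
            json.dump(rep, fh, indent=2)
        report_paths[cov] = rp
    summary = species_summaries(table)
    (out / "species_summary.txt").write_text(summary.report() + "\n")
    return {
        "complexity_csv": csv_path,
        "complexity_geojson": geojson_path,
        "weights_gal": weights_path,
        "model_reports": report_paths,
        "complexity": df,
        "models": reports,
        "species_summary": summary,
        "grid": grid,
    }


def _write_complexity_geojson(grid: Grid, df: pd.DataFrame, path) -> None:
    by_id = df.set_index("cell_id")
    features = []
    for cell in grid.cells:
        row = by_id.loc[cell.cell_id]
        props = {"cell_id": cell.cell_id}
        for col, val in row.items():
            props[col] = None if (isinstance(val, float) and not np.isfinite(val)) else (
                val.item() if hasattr(val, "item") else val
            )
        features.append({
            "type": "Feature",
            "geometry": mapping(cell.shapely()),
            "properties": props,
        })
    with open(path, "w") as fh:
        json.dump({"type": "FeatureCollection", "crs_kind": grid.crs_kind,
                   "features": features}, fh)


def report_summary(artifacts: dict) -> str:
    """Human-readable run summary: extremes, topology tallies, species stats."""
    df = artifacts.get("complexity")
    if df is None:
        raise ValueError("missing complexity table in artifacts")
    lines = []
    defined = df[np.isfinite(df["linkage_density"])]
    if defined.empty:
        lines.append("No non-empty potential networks in any cell.")
    else:
        lo = defined.loc[defined["linkage_density"].idxmin()]
        hi = defined.loc[defined["linkage_density"].idxmax()]
        lines.append(
            f"Linkage density ranged from {lo['linkage_density_1dp']:.1f} "
            f"(cell {lo['cell_id']}: {lo['n_interactions']} interactions among "
            f"{lo['n_species']} species) up to {hi['linkage_density_1dp']:.1f} "
            f"(cell {hi['cell_id']}: {hi['n_interactions']} interactions among "
            f"{hi['n_species']} species)."
        )
    tallies = df["topology_class"].value_counts()
    lines.append("Topology classes: " + ", ".join(
        f"{cls}={int(tallies.get(cls, 0))}" for cls in networks.TOPOLOGY_CLASSES
    ))
    summary = artifacts.get("species_summary")
    if summary is not None:
        lines.append(summary.report())
    return "\n".join(lines)
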