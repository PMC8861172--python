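"""End-to-end pipeline: configuration, stage orchestration, run manifest.

Stage order mirrors the analysis: road-density aggregation → range/PA
rasterization → species risk table → cumulative risk surface → impact levels
→ proposed-road impact report → WVC summaries.  Every run writes a manifest
recording the configuration, input checksums and the discretionary modes
used, so a rerun with identical inputs is byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import yaml

from . import cumulative as cum
from . import future as fut
from . import grid as gr
from . import risk as rk
from . import wvc as wv
from .vectorio import read_features, write_features

log = logging.getLogger("roadrisk")

ANALYSED_ROAD_TYPES = (1, 2, 3, 4)


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage and the offending input."""


@dataclass
class PipelineConfig:
    """Paths and knobs of one full run (paths are resolved relative to cwd)."""

    roads_by_type: dict[int, str] = field(default_factory=dict)   # GeoJSON polylines per type
    density_rasters: dict[int, str] = field(default_factory=dict)  # or pre-gridded .asc per type
    included_types: tuple[int, ...] = ANALYSED_ROAD_TYPES
    ranges: str = ""
    protected_areas: str = ""
    traits: str = ""
    wvc_records: str = ""
    future_roads: str = ""
    resolution_arcmin: float = 5.0
    extent: tuple[float, float, float, float] | None = None
    buffer_km: float = 10.0
    n_levels: int = 10
    binning_mode: str = "equal_width"
    rasterize_mode: str = "center"
    species_field: str = "species"
    pa_id_field: str = "pa_id"
    road_id_field: str = "id"
    outdir: str = "run"

    def __post_init__(self):
        bad = set(self.included_types) - {1, 2, 3, 4, 5}
        if bad:
            raise PipelineError(f"config: unknown road types {sorted(bad)} (valid: 1..5)")
        if 5 in self.included_types:
            warnings.warn(
                "road type 5 (local roads) is spatially biased and excluded from the "
                "reference analysis; including it because the config forces it",
                stacklevel=2,
            )

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        for key in ("roads_by_type", "density_rasters"):
            if key in raw:
                raw[key] = {int(k): v for k, v in raw[key].items()}
        if "included_types" in raw:
            raw["included_types"] = tuple(int(t) for t in raw["included_types"])
        if raw.get("extent") is not None:
            raw["extent"] = tuple(float(v) for v in raw["extent"])
        return cls(**raw)

    def validate_paths(self) -> None:
        paths = [
            *self.roads_by_type.values(),
            *self.density_rasters.values(),
            self.ranges,
            self.protected_areas,
            self.traits,
            self.wvc_records,
            self.future_roads,
        ]
        missing = [p for p in paths if p and not Path(p).exists()]
        if missing:
            raise PipelineError(f"config: input paths do not exist: {missing}")


def _sha256(path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def _stage(name: str):
    def deco(fn):
        def wrapped(*args, **kwargs):
            try:
                log.info("stage %s", name)
                return fn(*args, **kwargs)
            except PipelineError:
                raise
            except Exception as exc:  # annotate with the failing stage
                raise PipelineError(f"stage {name}: {exc}") from exc
        return wrapped
    return deco


@_stage("density")
def build_density(config: PipelineConfig, grid: gr.GridSpec, areas: gr.AreaLayer) -> gr.DensityLayer:
    """Per-type densities (from rasters or road vectors), aggregated over included types."""
    layers = []
    for t in config.included_types:
        if t in config.density_rasters:
            g, vals = gr.read_ascii_grid(config.density_rasters[t])
            if g != grid:
                raise PipelineError(
                    f"stage density: raster for type {t} is on a different grid ({config.density_rasters[t]})"
                )
            layers.append(gr.DensityLayer(grid, vals))
        elif t in config.roads_by_type:
            geoms = [g for g, _ in read_features(config.roads_by_type[t])]
            layers.append(gr.line_density(geoms, grid, areas))
        else:
            raise PipelineError(f"stage density: no input for road type {t}")
    return gr.aggregate_road_types(layers)


@_stage("rasterize")
def build_presence(config: PipelineConfig, grid: gr.GridSpec):
    """Rasterize species ranges (one layer per species) and the PA union."""
    by_species: dict[str, list] = {}
    for geom, props in read_features(config.ranges):
        name = str(props.get(config.species_field, "")).strip()
        if not name:
            raise PipelineError(f"stage rasterize: range feature lacks {config.species_field!r}")
        by_species.setdefault(name, []).append(geom)
    range_layers = {
        name: gr.rasterize_presence(geoms, grid, mode=config.rasterize_mode)
        for name, geoms in sorted(by_species.items())
    }
    pa_features = read_features(config.protected_areas) if config.protected_areas else []
    if pa_features:
        pa_layer = gr.rasterize_presence([g for g, _ in pa_features], grid, mode=config.rasterize_mode)
    else:
        pa_layer = gr.BinaryLayer(grid, np.zeros(grid.shape, dtype=np.uint8))
    return range_layers, pa_features, pa_layer


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the full analysis; returns a dict of in-memory results.

    Artifacts land under ``config.outdir`` with fixed names; the manifest
    (``manifest.json``) records config, input checksums and modes.
    """
    config.validate_paths()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    if config.extent is None:
        raise PipelineError("stage setup: config.extent is required")
    grid = gr.make_grid(config.resolution_arcmin, config.extent)
    areas = gr.cell_areas(grid)

    density = build_density(config, grid, areas)
    gr.write_ascii_grid(outdir / "road_density.asc", grid, density.values)

    range_layers, pa_features, pa_layer = build_presence(config, grid)
    rich = gr.richness(list(range_layers.values()))
    gr.write_ascii_grid(outdir / "richness.asc", grid, rich.values.astype(float))

    try:
        traits = rk.read_traits(config.traits)
        records = rk.risk_table(traits, range_layers, density, pa_layer, areas)
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError(f"stage risk: {exc}") from exc
    risk_df = rk.risk_table_to_frame(records)
    risk_df.to_csv(outdir / "risk_table.csv")

    try:
        surface = cum.cumulative_risk(records, range_layers, pa_layer)
        levels = cum.impact_levels(surface, config.n_levels, mode=config.binning_mode)
    except Exception as exc:
        raise PipelineError(f"stage cumulative: {exc}") from exc
    gr.write_ascii_grid(outdir / "cumulative_risk.asc", grid, surface.value)
    gr.write_ascii_grid(outdir / "impact_level.asc", grid, levels.level.astype(float))

    report = None
    if config.future_roads:
        try:
            network = fut.FutureRoadNetwork.from_features(
                read_features(config.future_roads), id_field=config.road_id_field
            )
            segments = fut.assign_impact(fut.segment_by_cell(network, grid), surface, levels)
            range_polys = {}
            for geom, props in read_features(config.ranges):
                name = str(props.get(config.species_field, "")).strip()
                range_polys[name] = (
                    geom if name not in range_polys else range_polys[name].union(geom)
                )
            report = fut.impact_report(
                segments,
                network,
                range_polys,
                {s: float(risk_df.loc[s, "range_area_km2"]) for s in range_polys},
                pa_features,
                n_levels=config.n_levels,
                buffer_km=config.buffer_km,
                pa_id_field=config.pa_id_field,
            )
        except fut.NetworkError as exc:
            raise PipelineError(f"stage impact: {exc}") from exc
        report["levels"].to_csv(outdir / "impact_levels_table.csv")
        report["species"].to_csv(outdir / "species_crossing.csv")
        report["protected_areas"].to_csv(outdir / "pa_intersections.csv")
        write_features(outdir / "impact_segments.geojson", fut.segments_to_features(segments))

    wvc_out = None
    if config.wvc_records:
        try:
            wvc_recs = wv.read_records(config.wvc_records)
        except wv.WVCValidationError as exc:
            raise PipelineError(f"stage wvc: {exc}") from exc
        universe = [t.species for t in traits]
        sp_table, coverage = wv.species_summary(wvc_recs, universe)
        country = wv.country_summary(wvc_recs)
        sp_table.to_csv(outdir / "wvc_species_summary.csv")
        country.to_csv(outdir / "wvc_country_summary.csv")
        wvc_out = {"species": sp_table, "country": country, "coverage": coverage}

    manifest = {
        "config": {
            k: (list(v) if isinstance(v, tuple) else v) for k, v in asdict(config).items()
        },
        "inputs_sha256": {
            str(p): _sha256(p)
            for p in [
                *config.roads_by_type.values(),
                *config.density_rasters.values(),
                config.ranges,
                config.protected_areas,
                config.traits,
                config.wvc_records,
                config.future_roads,
            ]
            if p
        },
        "modes": {
            "rasterize": config.rasterize_mode,
            "level_binning": config.binning_mode,
            "level_max_value": levels.max_value,
            "country_summary": "sum_rates",
            "included_road_types": list(config.included_types),
        },
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))

    return {
        "grid": grid,
        "areas": areas,
        "density": density,
        "range_layers": range_layers,
        "pa_layer": pa_layer,
        "richness": rich,
        "risk_records": records,
        "risk_table": risk_df,
        "cumulative": surface,
        "levels": levels,
        "impact_report": report,
        "wvc": wvc_out,
    }


def config_for_world(world_dir, outdir, **overrides) -> PipelineConfig:
    """Convenience: a config wired to the files a synthetic world wrote."""
    world_dir = Path(world_dir)
    sidecar = json.loads((world_dir / "ground_truth.json").read_text())
    p = sidecar["params"]
    cfg = dict(
        roads_by_type={t: str(world_dir / f"roads_type{t}.geojson") for t in (1, 2, 3, 4)},
        ranges=str(world_dir / "ranges.geojson"),
        protected_areas=str(world_dir / "protected_areas.geojson"),
        traits=str(world_dir / "traits.csv"),
        wvc_records=str(world_dir / "wvc_records.csv"),
        future_roads=str(world_dir / "future_roads.geojson"),
        resolution_arcmin=p["resolution_arcmin"],
        extent=tuple(p["extent"]),
        outdir=str(outdir),
    )
    cfg.update(overrides)
    return PipelineConfig(**cfg)
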