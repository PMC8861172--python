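"""Seeded synthetic worlds with analytic ground truth.

The generator emulates the six inputs the pipeline consumes — species range
polygons, road networks split by road type (1 = highways … 5 = local roads),
protected-area polygons, proposed road polylines, a species trait table and
a wildlife-vehicle-collision record table — on a small geographic window, and
writes them in exactly the formats the pipeline reads (GeoJSON, CSV).

Alongside the files it computes a :class:`GroundTruth` by *independent*
direct evaluation: range and PA cell sets are exact by construction
(rectangles snapped to cell edges), per-cell road lengths use closed-form
spherical arc lengths (meridian arcs ``R·Δφ``, parallel arcs ``R·cosφ·Δλ``)
in lattice mode or a fine densify-and-bin oracle in random-walk mode, and
the exposure/vulnerability/risk scores are recomputed with plain loops that
share no code with the scoring engine.  Fixtures are for correctness, not
realism: they do not mimic the spatial autocorrelation of real road or
range data.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import shapely
from shapely.geometry import LineString, Point, Polygon, box

from .geodesy import EARTH_RADIUS_KM
from .grid import GridSpec, make_grid
from .vectorio import write_features

ROAD_TYPES = (1, 2, 3, 4, 5)

#: IUCN status codes in ascending severity, used for trait sampling.
_STATUSES = ("LC", "NT", "VU", "EN", "CR")

_COUNTRIES = ("Atlantis", "Borduria", "Costaguana", "Florin", "Genovia", "Zubrowka")


class WorldParamError(ValueError):
    pass


@dataclass(frozen=True)
class WorldParams:
    """Knobs of the synthetic world; defaults encode the reference analysis conditions.

    The grid is 5-arcmin (the analysis resolution) on a 10°×10° window; 36
    species (the size of the analysed apex-predator set); protected-area
    coverage 0.15 (≈ global terrestrial protection); roadkill records exist
    for 30 of the 36 species (the documented coverage).  ``range_mode`` /
    ``road_mode`` select the closed-form geometry (rectangles / lattice,
    default) or irregular fuzzing geometry (blobs / walks).
    """

    resolution_arcmin: float = 5.0
    extent: tuple[float, float, float, float] = (0.0, -5.0, 10.0, 5.0)
    n_species: int = 36
    range_mode: str = "rectangles"  # or "blobs"
    road_mode: str = "lattice"      # or "walks"
    roads_per_type: tuple[int, ...] = (2, 3, 5, 8, 6)  # types 1..5; minor roads denser
    pa_coverage: float = 0.15
    n_future_roads: int = 3
    mass_range_kg: tuple[float, float] = (5.0, 300.0)
    threats_range: tuple[int, int] = (0, 12)
    wvc_coverage: float = 30.0 / 36.0  # fraction of species with ≥1 roadkill record
    wvc_mean_records: float = 4.0
    wvc_missing_rate: float = 0.15
    seed: int = 0

    def __post_init__(self):
        for name, frac in (("pa_coverage", self.pa_coverage), ("wvc_coverage", self.wvc_coverage),
                           ("wvc_missing_rate", self.wvc_missing_rate)):
            if not (0.0 <= frac <= 1.0):
                raise WorldParamError(f"{name} must be in [0, 1], got {frac}")
        if self.n_species < 1:
            raise WorldParamError("n_species must be ≥ 1")
        if self.range_mode not in ("rectangles", "blobs"):
            raise WorldParamError(f"unknown range_mode {self.range_mode!r}")
        if self.road_mode not in ("lattice", "walks"):
            raise WorldParamError(f"unknown road_mode {self.road_mode!r}")
        if len(self.roads_per_type) != len(ROAD_TYPES):
            raise WorldParamError("roads_per_type must give a count for each of the 5 road types")


@dataclass
class GroundTruth:
    """Independent direct evaluation of everything the pipeline should measure."""

    grid: GridSpec
    cell_area_km2: np.ndarray                  # closed-form spherical areas
    road_length_km: dict[int, np.ndarray]      # per road type, per cell
    range_masks: dict[str, np.ndarray]         # exact rasterized ranges
    pa_mask: np.ndarray
    species: pd.DataFrame                      # per-species expected scores
    wvc: dict = field(default_factory=dict)
    files: dict[str, str] = field(default_factory=dict)

    @property
    def aggregate_length_km(self) -> np.ndarray:
        """Analysed road length per cell (types 1–4; type 5 excluded)."""
        return sum(self.road_length_km[t] for t in (1, 2, 3, 4))


# ---------------------------------------------------------------------------
# closed-form helpers (deliberately local: the ground truth must not lean on
# the pipeline's grid/geodesy code paths)
# ---------------------------------------------------------------------------


def _areas_km2(grid: GridSpec) -> np.ndarray:
    res = grid.resolution_deg
    rows = np.empty(grid.n_rows)
    for r in range(grid.n_rows):
        top = math.radians(grid.north - r * res)
        bot = math.radians(grid.north - (r + 1) * res)
        rows[r] = EARTH_RADIUS_KM ** 2 * math.radians(res) * (math.sin(top) - math.sin(bot))
    return np.repeat(rows[:, None], grid.n_cols, axis=1)


def _meridian_lengths(grid: GridSpec, lon: float, lat_a: float, lat_b: float) -> np.ndarray:
    """Per-cell closed-form arc length (km) of a meridian segment."""
    out = np.zeros(grid.shape)
    res = grid.resolution_deg
    col = min(int((lon - grid.west) // res), grid.n_cols - 1)
    lo, hi = min(lat_a, lat_b), max(lat_a, lat_b)
    for r in range(grid.n_rows):
        top = grid.north - r * res
        bot = top - res
        ov = min(hi, top) - max(lo, bot)
        if ov > 1e-9:  # degrees; guards float noise at snapped endpoints
            out[r, col] = EARTH_RADIUS_KM * math.radians(ov)
    return out


def _parallel_lengths(grid: GridSpec, lat: float, lon_a: float, lon_b: float) -> np.ndarray:
    """Per-cell closed-form arc length (km) of a parallel segment."""
    out = np.zeros(grid.shape)
    res = grid.resolution_deg
    row = min(int((grid.north - lat) // res), grid.n_rows - 1)
    lo, hi = min(lon_a, lon_b), max(lon_a, lon_b)
    for c in range(grid.n_cols):
        left = grid.west + c * res
        right = left + res
        ov = min(hi, right) - max(lo, left)
        if ov > 1e-9:
            out[row, c] = EARTH_RADIUS_KM * math.cos(math.radians(lat)) * math.radians(ov)
    return out


def _walk_lengths(grid: GridSpec, coords: np.ndarray, step_deg: float = 0.002) -> np.ndarray:
    """Densify-and-bin oracle for irregular polylines (length km per cell)."""
    out = np.zeros(grid.shape)
    res = grid.resolution_deg
    for (x0, y0), (x1, y1) in zip(coords[:-1], coords[1:]):
        n = max(1, int(math.ceil(max(abs(x1 - x0), abs(y1 - y0)) / step_deg)))
        t = np.linspace(0.0, 1.0, n + 1)
        xs, ys = x0 + t * (x1 - x0), y0 + t * (y1 - y0)
        mx, my = (xs[:-1] + xs[1:]) / 2.0, (ys[:-1] + ys[1:]) / 2.0
        lam1, phi1, lam2, phi2 = map(np.radians, (xs[:-1], ys[:-1], xs[1:], ys[1:]))
        a = np.sin((phi2 - phi1) / 2) ** 2 + np.cos(phi1) * np.cos(phi2) * np.sin((lam2 - lam1) / 2) ** 2
        d = 2 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(a))
        cols = np.clip(((mx - grid.west) // res).astype(int), 0, grid.n_cols - 1)
        rows = np.clip(((grid.north - my) // res).astype(int), 0, grid.n_rows - 1)
        np.add.at(out, (rows, cols), d)
    return out


def _snapped_rect(grid: GridSpec, r0: int, r1: int, c0: int, c1: int) -> Polygon:
    """Polygon of the cell block rows r0..r1, cols c0..c1 (inclusive)."""
    res = grid.resolution_deg
    return box(
        grid.west + c0 * res,
        grid.north - (r1 + 1) * res,
        grid.west + (c1 + 1) * res,
        grid.north - r0 * res,
    )


def _rect_mask(grid: GridSpec, r0: int, r1: int, c0: int, c1: int) -> np.ndarray:
    m = np.zeros(grid.shape, dtype=bool)
    m[r0 : r1 + 1, c0 : c1 + 1] = True
    return m


# ---------------------------------------------------------------------------
# independent score evaluation
# ---------------------------------------------------------------------------


def direct_scores(
    density: dict[str, float],
    npa: dict[str, float],
    iucn_codes: dict[str, str],
    threats: dict[str, int],
    bm_class: dict[str, int],
) -> pd.DataFrame:
    """Plain-loop evaluation of the exposure/vulnerability/risk equations.

    Shares no code with the scoring engine; used as the oracle the pipeline
    is compared against.
    """
    iucn_map = {"LC": 1, "NT": 2, "VU": 3, "EN": 4, "CR": 5}
    sp = sorted(density)
    expo = {s: math.sqrt(density[s]) for s in sp}
    max_npa = max(npa[s] for s in sp)
    max_iucn = max(iucn_map[iucn_codes[s]] for s in sp)
    max_th = max(threats[s] for s in sp)
    max_bm = max(bm_class[s] for s in sp)
    for name, m in (("nPA", max_npa), ("IUCN", max_iucn), ("TH", max_th), ("BM", max_bm)):
        if m <= 0:
            raise WorldParamError(f"degenerate world: maximum {name} over species is zero")
    vuln = {
        s: npa[s] / max_npa
        + iucn_map[iucn_codes[s]] / max_iucn
        + 0.5 * threats[s] / max_th
        + 0.5 * bm_class[s] / max_bm
        for s in sp
    }
    max_expo = max(expo.values())
    max_vuln = max(vuln.values())
    if max_expo <= 0:
        raise WorldParamError("degenerate world: no species has any road in its range")
    rows = []
    for s in sp:
        rows.append(
            {
                "species": s,
                "road_density": density[s],
                "exposure_raw": expo[s],
                "nPA": npa[s],
                "vulnerability_raw": vuln[s],
                "exposure_star": expo[s] / max_expo,
                "vulnerability_star": vuln[s] / max_vuln,
                "risk": (expo[s] / max_expo) * (vuln[s] / max_vuln),
            }
        )
    return pd.DataFrame(rows).set_index("species")


def _bm_class_of(mass: float) -> int:
    if mass > 100:
        return 4
    if mass >= 25:
        return 3
    if mass >= 15:
        return 2
    return 1


# ---------------------------------------------------------------------------
# the generator
# ---------------------------------------------------------------------------


def simulate_world(params: WorldParams, outdir) -> GroundTruth:
    """Write a complete synthetic input set under ``outdir``; return its ground truth.

    Same ``params`` (including seed) ⇒ byte-identical files.
    """
    rng = np.random.default_rng(params.seed)
    grid = make_grid(params.resolution_arcmin, params.extent)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    res = grid.resolution_deg
    areas = _areas_km2(grid)

    # --- species ranges -------------------------------------------------
    species_names = [f"Synthetus predator{i:02d}" for i in range(params.n_species)]
    range_masks: dict[str, np.ndarray] = {}
    range_feats = []
    min_cells = max(4, grid.n_rows // 6)
    for name in species_names:
        if params.range_mode == "rectangles":
            h = int(rng.integers(min_cells, max(min_cells + 1, grid.n_rows // 2)))
            w = int(rng.integers(min_cells, max(min_cells + 1, grid.n_cols // 2)))
            r0 = int(rng.integers(0, grid.n_rows - h))
            c0 = int(rng.integers(0, grid.n_cols - w))
            poly = _snapped_rect(grid, r0, r0 + h - 1, c0, c0 + w - 1)
            mask = _rect_mask(grid, r0, r0 + h - 1, c0, c0 + w - 1)
        else:  # blobs: buffered random point, oracle = per-center containment
            cx = rng.uniform(grid.west + 1.0, grid.east - 1.0)
            cy = rng.uniform(grid.south + 1.0, grid.north - 1.0)
            poly = Polygon(
                [
                    (
                        cx + r_ * math.cos(a),
                        cy + 0.8 * r_ * math.sin(a),
                    )
                    for a, r_ in zip(
                        np.linspace(0, 2 * math.pi, 12, endpoint=False),
                        rng.uniform(0.6, 1.8, size=12),
                    )
                ]
            ).buffer(0)
            mask = np.zeros(grid.shape, dtype=bool)
            shapely.prepare(poly)
            for r in range(grid.n_rows):
                lat = grid.north - (r + 0.5) * res
                for c in range(grid.n_cols):
                    lon = grid.west + (c + 0.5) * res
                    mask[r, c] = poly.covers(Point(lon, lat))
        if not mask.any():
            raise WorldParamError(f"range of {name} rasterizes to zero cells; adjust params")
        range_masks[name] = mask
        range_feats.append((poly, {"species": name}))
    write_features(outdir / "ranges.geojson", range_feats)

    # --- roads by type ---------------------------------------------------
    road_length: dict[int, np.ndarray] = {t: np.zeros(grid.shape) for t in ROAD_TYPES}
    road_feats: dict[int, list] = {t: [] for t in ROAD_TYPES}
    for t, n_roads in zip(ROAD_TYPES, params.roads_per_type):
        for _ in range(n_roads):
            if params.road_mode == "lattice":
                if rng.random() < 0.5:  # meridian at a cell-center longitude
                    col = int(rng.integers(0, grid.n_cols))
                    lon = grid.west + (col + 0.5) * res
                    r0 = int(rng.integers(0, grid.n_rows - 1))
                    r1 = int(rng.integers(r0 + 1, grid.n_rows))
                    lat_a, lat_b = grid.north - r1 * res, grid.north - r0 * res
                    coords = [(lon, lat_a), (lon, lat_b)]
                    road_length[t] += _meridian_lengths(grid, lon, lat_a, lat_b)
                else:  # parallel at a cell-center latitude
                    row = int(rng.integers(0, grid.n_rows))
                    lat = grid.north - (row + 0.5) * res
                    c0 = int(rng.integers(0, grid.n_cols - 1))
                    c1 = int(rng.integers(c0 + 1, grid.n_cols))
                    lon_a, lon_b = grid.west + c0 * res, grid.west + c1 * res
                    coords = [(lon_a, lat), (lon_b, lat)]
                    road_length[t] += _parallel_lengths(grid, lat, lon_a, lon_b)
            else:  # random walk
                n_steps = int(rng.integers(4, 10))
                x = rng.uniform(grid.west + 0.5, grid.east - 0.5)
                y = rng.uniform(grid.south + 0.5, grid.north - 0.5)
                pts = [(x, y)]
                for _ in range(n_steps):
                    x = float(np.clip(x + rng.uniform(-1.0, 1.0), grid.west, grid.east))
                    y = float(np.clip(y + rng.uniform(-1.0, 1.0), grid.south, grid.north))
                    pts.append((x, y))
                coords = pts
                road_length[t] += _walk_lengths(grid, np.asarray(coords))
            road_feats[t].append((LineString(coords), {"road_type": t}))
    for t in ROAD_TYPES:
        write_features(outdir / f"roads_type{t}.geojson", road_feats[t])

    # --- protected areas --------------------------------------------------
    pa_mask = np.zeros(grid.shape, dtype=bool)
    pa_feats = []
    target = params.pa_coverage * grid.n_rows * grid.n_cols
    pid = 0
    while pa_mask.sum() < target and pid < 200:
        h = int(rng.integers(3, max(4, grid.n_rows // 4)))
        w = int(rng.integers(3, max(4, grid.n_cols // 4)))
        r0 = int(rng.integers(0, grid.n_rows - h))
        c0 = int(rng.integers(0, grid.n_cols - w))
        pa_feats.append(
            (_snapped_rect(grid, r0, r0 + h - 1, c0, c0 + w - 1), {"pa_id": pid, "name": f"PA-{pid:03d}"})
        )
        pa_mask |= _rect_mask(grid, r0, r0 + h - 1, c0, c0 + w - 1)
        pid += 1
    write_features(outdir / "protected_areas.geojson", pa_feats)

    # --- proposed roads ---------------------------------------------------
    future_feats = []
    for i in range(params.n_future_roads):
        n_pts = int(rng.integers(3, 7))
        xs = np.sort(rng.uniform(grid.west + 0.3, grid.east - 0.3, size=n_pts))
        ys = rng.uniform(grid.south + 0.3, grid.north - 0.3, size=n_pts)
        future_feats.append(
            (LineString(list(zip(xs, ys))), {"id": f"future-{i:02d}", "status": "proposed"})
        )
    write_features(outdir / "future_roads.geojson", future_feats)

    # --- traits -----------------------------------------------------------
    lo, hi = params.mass_range_kg
    masses = np.exp(rng.uniform(math.log(lo), math.log(hi), size=params.n_species))
    statuses = [
        _STATUSES[int(rng.integers(0, len(_STATUSES)))] for _ in range(params.n_species)
    ]
    threats = rng.integers(params.threats_range[0], params.threats_range[1] + 1, size=params.n_species)
    if threats.max() == 0:
        threats[0] = 1  # avoid a degenerate TH normalization
    traits = pd.DataFrame(
        {
            "species": species_names,
            "abm_kg": np.round(masses, 2),
            "iucn_status": statuses,
            "n_threats": threats.astype(int),
        }
    )
    traits.to_csv(outdir / "traits.csv", index=False)

    # --- WVC records ------------------------------------------------------
    n_covered = int(round(params.wvc_coverage * params.n_species))
    covered = list(rng.choice(params.n_species, size=n_covered, replace=False))
    wvc_rows = []
    for idx in sorted(covered):
        for _ in range(1 + rng.poisson(params.wvc_mean_records)):
            individuals = int(rng.integers(1, 50))
            years = int(rng.integers(1, 30))
            miss_ind = rng.random() < params.wvc_missing_rate
            miss_yr = rng.random() < params.wvc_missing_rate
            y0 = int(rng.integers(1963, 2021 - years + 1))
            wvc_rows.append(
                {
                    "species": species_names[idx],
                    "country": _COUNTRIES[int(rng.integers(0, len(_COUNTRIES)))],
                    "individuals": "" if miss_ind else individuals,
                    "study_years": "" if miss_yr else years,
                    "year_start": y0,
                    "year_end": y0 + years - 1,
                    "source_kind": "article",
                }
            )
    pd.DataFrame(
        wvc_rows,
        columns=["species", "country", "individuals", "study_years", "year_start", "year_end", "source_kind"],
    ).to_csv(outdir / "wvc_records.csv", index=False)

    # ground truth of the WVC conventions (missing → 1), by direct arithmetic
    eff: dict[str, float] = {}
    tot: dict[str, float] = {}
    for row in wvc_rows:
        ind = 1 if row["individuals"] == "" else row["individuals"]
        yrs = 1 if row["study_years"] == "" else row["study_years"]
        eff[row["country"]] = eff.get(row["country"], 0) + yrs
        tot[row["country"]] = tot.get(row["country"], 0) + ind / yrs
    wvc_truth = {
        "coverage": n_covered,
        "n_records": len(wvc_rows),
        "effort_years": eff,
        "single_year_wvc": tot,
    }

    # --- per-species expected scores -------------------------------------
    agg = sum(road_length[t] for t in (1, 2, 3, 4))
    density, npa, cov = {}, {}, {}
    iucn_codes, th_counts, bm_classes, range_area = {}, {}, {}, {}
    for i, name in enumerate(species_names):
        m = range_masks[name]
        a = float(areas[m].sum())
        density[name] = float(agg[m].sum()) * 1000.0 / a
        npa[name] = float(areas[m & ~pa_mask].sum()) / a
        cov[name] = float(np.count_nonzero(agg[m] > 0)) / float(np.count_nonzero(m))
        iucn_codes[name] = statuses[i]
        th_counts[name] = int(threats[i])
        bm_classes[name] = _bm_class_of(float(masses[i]))
        range_area[name] = a
    species_df = direct_scores(density, npa, iucn_codes, th_counts, bm_classes)
    species_df["road_coverage"] = pd.Series(cov)
    species_df["range_area_km2"] = pd.Series(range_area)

    files = {
        "ranges": str(outdir / "ranges.geojson"),
        "protected_areas": str(outdir / "protected_areas.geojson"),
        "future_roads": str(outdir / "future_roads.geojson"),
        "traits": str(outdir / "traits.csv"),
        "wvc": str(outdir / "wvc_records.csv"),
        **{f"roads_type{t}": str(outdir / f"roads_type{t}.geojson") for t in ROAD_TYPES},
    }
    truth = GroundTruth(
        grid=grid,
        cell_area_km2=areas,
        road_length_km=road_length,
        range_masks=range_masks,
        pa_mask=pa_mask,
        species=species_df,
        wvc=wvc_truth,
        files=files,
    )
    _write_sidecar(outdir / "ground_truth.json", params, truth)
    return truth


def _write_sidecar(path, params: WorldParams, truth: GroundTruth) -> None:
    payload = {
        "params": {
            k: (list(v) if isinstance(v, tuple) else v)
            for k, v in params.__dict__.items()
        },
        "species": truth.species.reset_index().to_dict("records"),
        "wvc": truth.wvc,
        "total_road_length_km": {
            str(t): float(truth.road_length_km[t].sum()) for t in ROAD_TYPES
        },
        "pa_cell_count": int(truth.pa_mask.sum()),
    }
    Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))


# ---------------------------------------------------------------------------
# deterministic benchmark fixture with a known ranking structure
# ---------------------------------------------------------------------------


def make_benchmark_fixture(outdir) -> GroundTruth:
    """A deterministic 36-species world whose risk ranking is known by construction.

    Species ranges tile 1°-wide bands of a 36°×3° window; the road lattice
    thins from west to east so constructed road densities are strictly
    ordered: the top species' band is densest (meridians spanning ~97% of
    the band, so ~97% of its range cells carry road), the runner-up sits near
    2/3 of its density, and the last band has no roads at all (a
    boreal-like, low-exposure species).  The top species also carries the
    maximal vulnerability components, so it ranks first by construction.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    n_species = 36
    grid = make_grid(5.0, (0.0, 0.0, float(n_species), 3.0))
    res = grid.resolution_deg
    areas = _areas_km2(grid)
    cols_per_band = int(round(1.0 / res))
    species_names = [f"Synthetus predator{i:02d}" for i in range(n_species)]

    range_masks, range_feats = {}, []
    for i, name in enumerate(species_names):
        c0 = i * cols_per_band
        poly = _snapped_rect(grid, 0, grid.n_rows - 1, c0, c0 + cols_per_band - 1)
        range_masks[name] = _rect_mask(grid, 0, grid.n_rows - 1, c0, c0 + cols_per_band - 1)
        range_feats.append((poly, {"species": name}))
    write_features(outdir / "ranges.geojson", range_feats)

    # meridian counts per band: 34, then ~2/3 of that, tapering to 0 in the
    # last band (the boreal-like, road-free range)
    meridians = [34, 22] + [1 + ((34 - i) * 19) // 32 for i in range(2, n_species - 1)] + [0]
    # roads span rows 0..34 of 36 → 35/36 ≈ 97% of each band's cells see road
    lat_a, lat_b = grid.south + res, grid.north
    road_length: dict[int, np.ndarray] = {t: np.zeros(grid.shape) for t in ROAD_TYPES}
    road_feats: dict[int, list] = {t: [] for t in ROAD_TYPES}
    for i, k in enumerate(meridians):
        if k == 0:
            continue
        band_w0 = grid.west + i * 1.0
        lons = band_w0 + (np.arange(k) + 0.5) * (1.0 / k)
        # keep off cell edges: nudge any edge-coincident lon by a hair
        frac = (lons - grid.west) / res
        lons = np.where(np.isclose(frac, np.round(frac)), lons + res * 1e-3, lons)
        for j, lon in enumerate(lons):
            t = (j % 4) + 1  # spread across road types 1–4
            road_feats[t].append((LineString([(lon, lat_a), (lon, lat_b)]), {"road_type": t}))
            road_length[t] += _meridian_lengths(grid, float(lon), lat_a, lat_b)
    for t in ROAD_TYPES:
        write_features(outdir / f"roads_type{t}.geojson", road_feats[t])

    # protected areas: southern third of every even band except the top species' band
    pa_mask = np.zeros(grid.shape, dtype=bool)
    pa_feats = []
    pid = 0
    r0 = 2 * grid.n_rows // 3
    for i in range(2, n_species, 2):
        c0 = i * cols_per_band
        pa_feats.append(
            (_snapped_rect(grid, r0, grid.n_rows - 1, c0, c0 + cols_per_band - 1),
             {"pa_id": pid, "name": f"PA-{pid:03d}"})
        )
        pa_mask |= _rect_mask(grid, r0, grid.n_rows - 1, c0, c0 + cols_per_band - 1)
        pid += 1
    write_features(outdir / "protected_areas.geojson", pa_feats)

    # proposed roads: a western transect crossing the PA belt directly, and a
    # full transect ~5.6 km north of the PA edge (inside a 10-km buffer only)
    lat_in_pa = grid.south + 0.5 + res / 2
    lat_near_pa = grid.south + 1.0 + 0.05
    future_feats = [
        (LineString([(grid.west + 0.1, lat_in_pa), (grid.west + 18.0, lat_in_pa)]),
         {"id": "future-00", "status": "proposed"}),
        (LineString([(grid.west + 0.1, lat_near_pa), (grid.east - 0.1, lat_near_pa)]),
         {"id": "future-01", "status": "proposed"}),
    ]
    write_features(outdir / "future_roads.geojson", future_feats)

    # traits: top species maximal on every vulnerability component
    rows = []
    statuses_cycle = ("LC", "NT", "VU", "EN", "CR")
    for i, name in enumerate(species_names):
        if i == 0:
            rows.append({"species": name, "abm_kg": 140.0, "iucn_status": "CR", "n_threats": 12})
        else:
            rows.append(
                {
                    "species": name,
                    "abm_kg": float(8 + (i * 7) % 120),
                    "iucn_status": statuses_cycle[i % 5],
                    "n_threats": int(1 + (i * 3) % 11),
                }
            )
    traits = pd.DataFrame(rows)
    traits.to_csv(outdir / "traits.csv", index=False)

    # WVC: 30 of the 36 species documented; the top species gets a 15-individual,
    # 6-year record (a sloth-bear-like entry)
    wvc_rows = [
        {
            "species": species_names[0],
            "country": _COUNTRIES[0],
            "individuals": 15,
            "study_years": 6,
            "year_start": 2012,
            "year_end": 2017,
            "source_kind": "article",
        }
    ]
    for i in range(1, 30):
        wvc_rows.append(
            {
                "species": species_names[i],
                "country": _COUNTRIES[i % len(_COUNTRIES)],
                "individuals": 1 + (i * 5) % 40,
                "study_years": 1 + i % 10,
                "year_start": 1990 + i,
                "year_end": 1990 + i + i % 10,
                "source_kind": "article",
            }
        )
    pd.DataFrame(wvc_rows).to_csv(outdir / "wvc_records.csv", index=False)
    eff: dict[str, float] = {}
    tot: dict[str, float] = {}
    for row in wvc_rows:
        eff[row["country"]] = eff.get(row["country"], 0) + row["study_years"]
        tot[row["country"]] = tot.get(row["country"], 0) + row["individuals"] / row["study_years"]
    wvc_truth = {
        "coverage": 30,
        "n_records": len(wvc_rows),
        "effort_years": eff,
        "single_year_wvc": tot,
    }

    agg = sum(road_length[t] for t in (1, 2, 3, 4))
    density, npa, cov = {}, {}, {}
    iucn_codes, th_counts, bm_classes, range_area = {}, {}, {}, {}
    for i, name in enumerate(species_names):
        m = range_masks[name]
        a = float(areas[m].sum())
        density[name] = float(agg[m].sum()) * 1000.0 / a
        npa[name] = float(areas[m & ~pa_mask].sum()) / a
        cov[name] = float(np.count_nonzero(agg[m] > 0)) / float(np.count_nonzero(m))
        iucn_codes[name] = str(traits.iloc[i]["iucn_status"])
        th_counts[name] = int(traits.iloc[i]["n_threats"])
        bm_classes[name] = _bm_class_of(float(traits.iloc[i]["abm_kg"]))
        range_area[name] = a
    species_df = direct_scores(density, npa, iucn_codes, th_counts, bm_classes)
    species_df["road_coverage"] = pd.Series(cov)
    species_df["range_area_km2"] = pd.Series(range_area)

    files = {
        "ranges": str(outdir / "ranges.geojson"),
        "protected_areas": str(outdir / "protected_areas.geojson"),
        "future_roads": str(outdir / "future_roads.geojson"),
        "traits": str(outdir / "traits.csv"),
        "wvc": str(outdir / "wvc_records.csv"),
        **{f"roads_type{t}": str(outdir / f"roads_type{t}.geojson") for t in ROAD_TYPES},
    }
    truth = GroundTruth(
        grid=grid,
        cell_area_km2=areas,
        road_length_km=road_length,
        range_masks=range_masks,
        pa_mask=pa_mask,
        species=species_df,
        wvc=wvc_truth,
        files=files,
    )
    _write_sidecar(outdir / "ground_truth.json", WorldParams(n_species=36, extent=(0.0, 0.0, 36.0, 3.0)), truth)
    return truth
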