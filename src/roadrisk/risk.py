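"""Species road-risk scoring: exposure × vulnerability.

The risk of species *i* from the current road network is the product of a
likelihood term (exposure to roads) and a severity term (intrinsic
vulnerability), each max-normalised over the analysed species set:

    risk_i = exposure*_i · vulnerability*_i                       (risk)
    exposure_i = sqrt(road_density_i)                             (likelihood)
    vulnerability_i = nPA*_i + IUCN*_i + 0.5·TH*_i + 0.5·BM*_i    (severity)

where road_density_i is the mean road density over the species range (total
road length in metres / range area in km²), nPA the unprotected fraction of
the range, IUCN the ordinal Red List status (LC=1 … CR=5), TH the number of
IUCN-listed threats and BM a 4-level body-mass class (a home-range-size
proxy).  Starred quantities are divided by their maximum across the analysed
set, so the species set itself is an explicit input: changing it rescales
every score.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, asdict
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .grid import AreaLayer, BinaryLayer, DensityLayer, _check_same_grid

IUCN_VALUES = {"LC": 1, "NT": 2, "VU": 3, "EN": 4, "CR": 5}

#: Eq. weights on the threat-count and body-mass vulnerability components.
SECONDARY_WEIGHT = 0.5


class RiskInputError(ValueError):
    pass


class DegenerateNormalizationError(RiskInputError):
    """A normalization maximum is zero, so starred values are undefined."""


@dataclass(frozen=True)
class SpeciesTraits:
    species: str
    abm_kg: float
    iucn_status: str
    n_threats: int
    bm_category: int | None = None  # explicit override of the mass-derived class

    def __post_init__(self):
        if self.abm_kg <= 0:
            raise RiskInputError(f"{self.species}: body mass must be positive")
        if self.iucn_status not in IUCN_VALUES:
            raise RiskInputError(
                f"{self.species}: unknown IUCN status {self.iucn_status!r} (expected LC/NT/VU/EN/CR)"
            )
        if self.n_threats < 0:
            raise RiskInputError(f"{self.species}: threat count must be nonnegative")


@dataclass
class SpeciesRiskRecord:
    """All per-species quantities of the scoring equations (starred = max-normalised)."""

    species: str
    road_density: float
    exposure_raw: float
    nPA: float
    iucn_value: int
    th_count: int
    bm_category: int
    nPA_star: float = math.nan
    iucn_star: float = math.nan
    th_star: float = math.nan
    bm_star: float = math.nan
    vulnerability_raw: float = math.nan
    exposure_star: float = math.nan
    vulnerability_star: float = math.nan
    risk: float = math.nan
    road_coverage: float = math.nan
    range_area_km2: float = math.nan


def body_mass_category(abm_kg: float) -> int:
    """4-level body-mass class: >100 kg → 4, [25,100] → 3, [15,25) → 2, [8,15) → 1.

    Masses below 8 kg (species included as the main predator of their
    ecosystem despite small size) fall in class 1 with a warning.
    """
    if abm_kg <= 0:
        raise RiskInputError("body mass must be positive")
    if abm_kg > 100:
        return 4
    if abm_kg >= 25:
        return 3
    if abm_kg >= 15:
        return 2
    if abm_kg < 8:
        warnings.warn(
            f"body mass {abm_kg} kg below the smallest class (8-15 kg); assigning class 1",
            stacklevel=2,
        )
    return 1


def iucn_value(status: str) -> int:
    """Ordinal Red List status: LC=1, NT=2, VU=3, EN=4, CR=5."""
    try:
        return IUCN_VALUES[status]
    except KeyError:
        raise RiskInputError(f"unknown IUCN status {status!r}") from None


def mean_road_density(
    range_layer: BinaryLayer, density_layer: DensityLayer, areas: AreaLayer, *, species: str = "?"
) -> float:
    """Area-weighted mean road density (m/km²) over a species range.

    Equals total road length within the range divided by the range area.
    Nodata density counts as 0 road.
    """
    _check_same_grid(range_layer.grid, density_layer.grid)
    _check_same_grid(range_layer.grid, areas.grid)
    mask = range_layer.values.astype(bool)
    if not mask.any():
        raise RiskInputError(f"species {species!r} has an empty rasterized range")
    dens = np.nan_to_num(density_layer.values, nan=0.0)
    area = areas.values
    return float(np.sum(dens[mask] * area[mask]) / np.sum(area[mask]))


def exposure(road_density: float) -> float:
    """Road exposure: square root of the mean road density."""
    if road_density < 0:
        raise RiskInputError("road density cannot be negative")
    return math.sqrt(road_density)


def unprotected_fraction(
    range_layer: BinaryLayer, pa_layer: BinaryLayer, areas: AreaLayer, *, species: str = "?"
) -> float:
    """nPA: fraction of range area falling on cells with no protected-area cover."""
    _check_same_grid(range_layer.grid, pa_layer.grid)
    _check_same_grid(range_layer.grid, areas.grid)
    mask = range_layer.values.astype(bool)
    if not mask.any():
        raise RiskInputError(f"species {species!r} has an empty rasterized range")
    area = areas.values
    unprot = (pa_layer.values == 0) & mask
    return float(np.sum(area[unprot]) / np.sum(area[mask]))


def road_coverage(
    range_layer: BinaryLayer, density_layer: DensityLayer, *, species: str = "?"
) -> float:
    """Fraction of range cells with any road (density strictly > 0; nodata = roadless)."""
    _check_same_grid(range_layer.grid, density_layer.grid)
    mask = range_layer.values.astype(bool)
    if not mask.any():
        raise RiskInputError(f"species {species!r} has an empty rasterized range")
    dens = np.nan_to_num(density_layer.values, nan=0.0)
    return float(np.count_nonzero(dens[mask] > 0) / np.count_nonzero(mask))


def vulnerability(nPA_star: float, iucn_star: float, th_star: float, bm_star: float) -> float:
    """Weighted vulnerability sum; all inputs must already be max-normalised to [0,1]."""
    for name, v in (("nPA*", nPA_star), ("IUCN*", iucn_star), ("TH*", th_star), ("BM*", bm_star)):
        if not (0.0 <= v <= 1.0):
            raise RiskInputError(f"{name}={v} outside [0, 1]")
    return nPA_star + iucn_star + SECONDARY_WEIGHT * th_star + SECONDARY_WEIGHT * bm_star


def _normalize(values: np.ndarray, name: str) -> np.ndarray:
    m = float(np.max(values))
    if m <= 0:
        raise DegenerateNormalizationError(
            f"maximum of {name} over the species set is zero; starred values undefined"
        )
    return values / m


def risk_table(
    traits: Sequence[SpeciesTraits],
    range_layers: Mapping[str, BinaryLayer],
    density_layer: DensityLayer,
    pa_layer: BinaryLayer,
    areas: AreaLayer,
) -> list[SpeciesRiskRecord]:
    """Score every species of the analysed set (Eqs. of the module docstring).

    Deterministic and order-invariant: records are returned sorted by risk
    descending, ties broken alphabetically.
    """
    if not traits:
        raise RiskInputError("empty species set")
    missing = [t.species for t in traits if t.species not in range_layers]
    if missing:
        raise RiskInputError(f"no range layer for species: {missing}")
    records = []
    for t in sorted(traits, key=lambda t: t.species):
        rng = range_layers[t.species]
        dens = mean_road_density(rng, density_layer, areas, species=t.species)
        bm = t.bm_category if t.bm_category is not None else body_mass_category(t.abm_kg)
        records.append(
            SpeciesRiskRecord(
                species=t.species,
                road_density=dens,
                exposure_raw=exposure(dens),
                nPA=unprotected_fraction(rng, pa_layer, areas, species=t.species),
                iucn_value=iucn_value(t.iucn_status),
                th_count=t.n_threats,
                bm_category=bm,
                road_coverage=road_coverage(rng, density_layer, species=t.species),
                range_area_km2=float(
                    np.sum(areas.values[rng.values.astype(bool)])
                ),
            )
        )
    npa = _normalize(np.array([r.nPA for r in records]), "nPA")
    iucn = _normalize(np.array([r.iucn_value for r in records], dtype=float), "IUCN value")
    th = _normalize(np.array([r.th_count for r in records], dtype=float), "threat count")
    bm = _normalize(np.array([r.bm_category for r in records], dtype=float), "body-mass class")
    for r, a, b, c, d in zip(records, npa, iucn, th, bm):
        r.nPA_star, r.iucn_star, r.th_star, r.bm_star = float(a), float(b), float(c), float(d)
        r.vulnerability_raw = vulnerability(r.nPA_star, r.iucn_star, r.th_star, r.bm_star)
    expo = _normalize(np.array([r.exposure_raw for r in records]), "exposure")
    vuln = _normalize(np.array([r.vulnerability_raw for r in records]), "vulnerability")
    for r, e, v in zip(records, expo, vuln):
        r.exposure_star, r.vulnerability_star = float(e), float(v)
        r.risk = r.exposure_star * r.vulnerability_star
    records.sort(key=lambda r: (-r.risk, r.species))
    return records


def risk_table_to_frame(records: Sequence[SpeciesRiskRecord]) -> pd.DataFrame:
    """Risk table as a DataFrame (row order preserved: risk descending)."""
    return pd.DataFrame([asdict(r) for r in records]).set_index("species")


def read_traits(path) -> list[SpeciesTraits]:
    """Read the traits CSV: species, abm_kg, iucn_status, n_threats[, bm_category]."""
    df = pd.read_csv(path)
    out = []
    for rec in df.to_dict("records"):
        bm = rec.get("bm_category")
        if bm is None or (isinstance(bm, float) and np.isnan(bm)):
            bm = None
        else:
            bm = int(bm)
        out.append(
            SpeciesTraits(
                species=str(rec["species"]).strip(),
                abm_kg=float(rec["abm_kg"]),
                iucn_status=str(rec["iucn_status"]).strip(),
                n_threats=int(rec["n_threats"]),
                bm_category=bm,
            )
        )
    return out
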