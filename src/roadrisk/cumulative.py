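"""Cumulative road-risk surface and its discretization into impact levels.

Per pixel the cumulative risk is

    value = SSR + β · PA

where SSR is the sum of the risk scores of all species whose range covers the
pixel, β the mean risk of those species (0 where no species is present), and
PA the binary protected-area flag — protected pixels are up-weighted by one
average species risk.  The continuous surface is discretized into 1..n
impact levels (default 10) for reporting; level 0 marks pixels with no
species present.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .grid import BinaryLayer, GridSpec, _check_same_grid
from .risk import SpeciesRiskRecord


class CumulativeError(ValueError):
    pass


@dataclass
class CumulativeRiskLayer:
    grid: GridSpec
    ssr: np.ndarray       # sum of risks of species present
    beta: np.ndarray      # mean risk of species present, 0 where none
    n_species: np.ndarray  # per-cell count of species present
    pa: np.ndarray        # protected-area flag 0/1
    value: np.ndarray     # ssr + beta * pa


@dataclass
class ImpactLevelLayer:
    grid: GridSpec
    level: np.ndarray     # int 0..n_levels; 0 = no species present
    n_levels: int
    max_value: float      # normalizing maximum of the continuous surface
    mode: str             # binning mode used


def cumulative_risk(
    risk_records: Sequence[SpeciesRiskRecord],
    range_layers: Mapping[str, BinaryLayer],
    pa_layer: BinaryLayer,
) -> CumulativeRiskLayer:
    """Overlay species risks into the per-pixel cumulative surface.

    Every species appearing in ``range_layers`` must have a risk record.
    """
    risk_by_species = {r.species: r.risk for r in risk_records}
    missing = sorted(set(range_layers) - set(risk_by_species))
    if missing:
        raise CumulativeError(f"species missing from the risk table: {missing}")
    grid = pa_layer.grid
    ssr = np.zeros(grid.shape)
    n = np.zeros(grid.shape, dtype=np.int32)
    for species, layer in range_layers.items():
        _check_same_grid(grid, layer.grid)
        present = layer.values.astype(bool)
        ssr[present] += risk_by_species[species]
        n[present] += 1
    beta = np.where(n > 0, ssr / np.maximum(n, 1), 0.0)
    pa = pa_layer.values.astype(np.uint8)
    value = ssr + beta * pa
    return CumulativeRiskLayer(grid=grid, ssr=ssr, beta=beta, n_species=n, pa=pa, value=value)


def impact_levels(
    cumulative: CumulativeRiskLayer,
    n_levels: int = 10,
    *,
    mode: str = "equal_width",
    max_value: float | None = None,
) -> ImpactLevelLayer:
    """Discretize the cumulative surface into integer impact levels.

    ``equal_width`` (default): level = ceil(n · value / max) over (0, max],
    clipped to [1, n]; 0 where value = 0.  ``quantile``: equal-count bins of
    the positive values.  ``max_value`` lets a wider analysis extent supply
    the normalizing maximum so levels stay comparable across regional
    windows; by default the layer's own positive maximum is used.
    """
    v = cumulative.value
    pos = v[v > 0]
    if pos.size == 0:
        raise CumulativeError("cumulative surface is identically zero; levels undefined")
    vmax = float(max_value) if max_value is not None else float(pos.max())
    if vmax <= 0:
        raise CumulativeError("normalizing maximum must be positive")
    level = np.zeros(cumulative.grid.shape, dtype=np.int32)
    mask = v > 0
    if mode == "equal_width":
        level[mask] = np.clip(np.ceil(n_levels * v[mask] / vmax), 1, n_levels).astype(np.int32)
    elif mode == "quantile":
        edges = np.quantile(pos, np.linspace(0, 1, n_levels + 1)[1:-1])
        level[mask] = (np.searchsorted(edges, v[mask], side="left") + 1).astype(np.int32)
    else:
        raise ValueError(f"unknown binning mode {mode!r}")
    return ImpactLevelLayer(
        grid=cumulative.grid, level=level, n_levels=n_levels, max_value=vmax, mode=mode
    )


def level_of_value(value: float, levels: ImpactLevelLayer) -> int:
    """Impact level of a single cumulative-risk value under a layer's binning."""
    if value <= 0:
        return 0
    if levels.mode != "equal_width":
        raise ValueError("scalar lookup only defined for equal-width binning")
    return int(np.clip(np.ceil(levels.n_levels * value / levels.max_value), 1, levels.n_levels))
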