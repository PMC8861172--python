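import math

import numpy as np
import pytest
from shapely.geometry import LineString, Point, box

from roadrisk.cumulative import cumulative_risk, impact_levels
from roadrisk.future import (
    FutureRoadNetwork,
    NetworkError,
    assign_impact,
    geodesic_line_length_km,
    level_length_distribution,
    pa_intersections,
    segment_by_cell,
    species_crossing,
)
from roadrisk.geodesy import EARTH_RADIUS_KM, haversine_km
from roadrisk.grid import BinaryLayer, make_grid
from roadrisk.risk import SpeciesRiskRecord

KM_PER_DEG = EARTH_RADIUS_KM * math.pi / 180.0


def _net(lines):
    return FutureRoadNetwork([(f"r{i}", ls, {}) for i, ls in enumerate(lines)])


def _surface_on(grid_vals, pa=None):
    vals = np.asarray(grid_vals, dtype=float)
    g = make_grid(60, (0, 0, vals.shape[1], vals.shape[0]))
    rec = SpeciesRiskRecord(
        species="Sp", road_density=0, exposure_raw=0, nPA=0, iucn_value=1, th_count=0,
        bm_category=1, risk=1.0,
    )
    layers = {"Sp": BinaryLayer(g, (vals > 0).astype(int))}
    pa_layer = BinaryLayer(g, np.zeros(vals.shape, dtype=int) if pa is None else pa)
    surf = cumulative_risk([rec], layers, pa_layer)
    surf.value = vals
    return g, surf


# --- segmentation ------------------------------------------------------


def test_single_cell_road_one_segment():
    g = make_grid(60, (0, 0, 4, 4))
    road = LineString([(0.2, 0.3), (0.8, 0.6)])
    segs = segment_by_cell(_net([road]), g)
    assert len(segs) == 1
    assert segs[0].length_km == pytest.approx(geodesic_line_length_km(road), rel=1e-9)


def test_two_cell_road_partitions_length():
    g = make_grid(60, (0, 0, 4, 4))
    road = LineString([(0.5, 0.5), (1.5, 0.5)])
    segs = segment_by_cell(_net([road]), g)
    assert len(segs) == 2
    total = sum(s.length_km for s in segs)
    assert total == pytest.approx(geodesic_line_length_km(road), rel=1e-3)


def test_zigzag_against_densify_oracle(rng):
    g = make_grid(60, (0, 0, 4, 4))
    pts = [(0.3, 0.4), (1.6, 1.2), (2.1, 0.5), (3.4, 2.8), (0.9, 3.5)]
    segs = segment_by_cell(_net([LineString(pts)]), g)
    got = np.zeros(g.shape)
    for s in segs:
        got[s.row, s.col] += s.length_km
    oracle = np.zeros(g.shape)
    coords = np.asarray(pts)
    for (x0, y0), (x1, y1) in zip(coords[:-1], coords[1:]):
        t = np.linspace(0, 1, 8001)
        xs, ys = x0 + t * (x1 - x0), y0 + t * (y1 - y0)
        d = haversine_km(xs[:-1], ys[:-1], xs[1:], ys[1:])
        mx, my = (xs[:-1] + xs[1:]) / 2, (ys[:-1] + ys[1:]) / 2
        rows = np.clip(((g.north - my) / g.resolution_deg).astype(int), 0, 3)
        cols = np.clip(((mx - g.west) / g.resolution_deg).astype(int), 0, 3)
        np.add.at(oracle, (rows, cols), d)
    mask = oracle > 1e-9
    assert np.allclose(got[mask], oracle[mask], rtol=5e-3)
    assert got[~mask].sum() < 1e-6


def test_partition_invariant_total_length(rng):
    g = make_grid(60, (0, 0, 6, 6))
    lines = [
        LineString(np.column_stack([rng.uniform(0.2, 5.8, 5), rng.uniform(0.2, 5.8, 5)]))
        for _ in range(3)
    ]
    net = _net(lines)
    segs = segment_by_cell(net, g)
    assert sum(s.length_km for s in segs) == pytest.approx(net.total_length_km, rel=1e-3)


def test_feature_outside_extent_listed():
    g = make_grid(60, (0, 0, 2, 2))
    with pytest.raises(NetworkError, match="r0"):
        segment_by_cell(_net([LineString([(1, 1), (5, 1)])]), g)


def test_duplicate_ids_rejected():
    ls = LineString([(0, 0), (1, 1)])
    with pytest.raises(NetworkError):
        FutureRoadNetwork([("a", ls, {}), ("a", ls, {})])


# --- impact assignment and level distribution -------------------------


def test_assign_impact_values_and_levels():
    vals = [[1.0, 0.31], [0.0, 0.5]]
    g, surf = _surface_on(vals)
    levels = impact_levels(surf, 10)
    net = _net([LineString([(0.5, 1.5), (1.5, 1.5)]), LineString([(0.2, 0.5), (0.8, 0.5)])])
    segs = assign_impact(segment_by_cell(net, g), surf, levels)
    by_cell = {(s.row, s.col): s for s in segs}
    assert by_cell[(0, 0)].level == 10 and by_cell[(0, 0)].cum_risk == 1.0
    assert by_cell[(0, 1)].level == 4   # 0.31·max → ceil(3.1)
    assert by_cell[(1, 0)].level == 0   # value 0 stays level 0


def test_uniform_layer_single_level():
    g, surf = _surface_on([[0.7, 0.7], [0.7, 0.7]])
    levels = impact_levels(surf, 10)
    net = _net([LineString([(0.2, 0.4), (1.8, 1.6)])])
    segs = assign_impact(segment_by_cell(net, g), surf, levels)
    assert {s.level for s in segs} == {10}
    table = level_length_distribution(segs, 10)
    assert table.loc[10, "pct_of_total"] == pytest.approx(100.0)


def test_level_distribution_percentages_sum_to_100():
    g, surf = _surface_on([[0.2, 0.5, 1.0]])
    levels = impact_levels(surf, 10)
    net = _net([LineString([(0.0, 0.5), (3.0, 0.5)])])
    segs = assign_impact(segment_by_cell(net, g), surf, levels)
    table = level_length_distribution(segs, 10)
    assert table["pct_of_total"].sum() == pytest.approx(100.0, abs=0.1)
    # three equal-length cells at three distinct levels → 33.33% each
    occupied = table[table["pct_of_total"] > 0]
    assert len(occupied) == 3
    assert np.allclose(occupied["pct_of_total"], 100 / 3, rtol=1e-3)


def test_empty_segments_rejected():
    with pytest.raises(NetworkError):
        level_length_distribution([])


# --- species crossings -------------------------------------------------


def test_network_fully_inside_range_is_100_percent():
    net = _net([LineString([(0.5, 0.5), (1.5, 0.8)])])
    ranges = {"Cuon alpinus": box(0, 0, 2, 1)}
    out = species_crossing(net, ranges, {"Cuon alpinus": 1000.0})
    assert out.loc["Cuon alpinus", "pct_of_network"] == pytest.approx(100.0, abs=1e-6)


def test_disjoint_network_and_range_zero():
    net = _net([LineString([(5.0, 5.0), (6.0, 5.0)])])
    out = species_crossing(net, {"Sp": box(0, 0, 1, 1)}, {"Sp": 10.0})
    assert out.loc["Sp", "crossing_length_km"] == 0.0
    assert out.loc["Sp", "pct_of_network"] == 0.0


def test_raster_route_agrees_with_vector_route_on_snapped_range():
    from roadrisk.future import species_crossing_raster

    g = make_grid(60, (0, 0, 4, 2))
    net = _net([LineString([(0.1, 0.7), (3.9, 0.7)])])
    # range snapped to cell columns 0-1: both routes see the same geometry
    rng_mask = np.zeros(g.shape, dtype=int)
    rng_mask[:, :2] = 1
    segs = segment_by_cell(net, g)
    raster = species_crossing_raster(segs, {"Sp": BinaryLayer(g, rng_mask)}, net.total_length_km, {"Sp": 1.0})
    vector = species_crossing(net, {"Sp": box(0, 0, 2, 2)}, {"Sp": 1.0})
    assert raster.loc["Sp", "crossing_length_km"] == pytest.approx(
        vector.loc["Sp", "crossing_length_km"], rel=5e-3
    )


def test_half_length_inside_range():
    # a parallel-arc road whose midpoint sits on the range boundary
    net = _net([LineString([(0.0, 0.2), (2.0, 0.2)])])
    out = species_crossing(net, {"Sp": box(0, 0, 1, 1)}, {"Sp": 10.0})
    assert out.loc["Sp", "pct_of_network"] == pytest.approx(50.0, rel=5e-3)
    # range-relative metric: crossing km per km² of range
    assert out.loc["Sp", "length_per_range_area"] == pytest.approx(
        out.loc["Sp", "crossing_length_km"] / 10.0
    )


# --- protected areas ---------------------------------------------------


def test_pa_containing_network_direct_full_length():
    net = _net([LineString([(0.5, 0.5), (1.5, 0.5)])])
    pa = [(box(0, 0, 2, 1), {"pa_id": 7})]
    out = pa_intersections(net, pa, buffer_km=10)
    assert bool(out.loc["7", "direct"]) and bool(out.loc["7", "buffered"])
    assert out.loc["7", "intersected_length_km"] == pytest.approx(net.total_length_km, rel=1e-6)


def test_pa_9km_away_buffered_not_direct():
    # road along the meridian lon=0; PA centroid 9 km east, radius 0.5 km
    road = LineString([(0.0, -0.5), (0.0, 0.5)])
    cx = 9.0 / KM_PER_DEG
    r = 0.5 / KM_PER_DEG
    pa = [(Point(cx, 0.0).buffer(r, quad_segs=16), {"pa_id": 1})]
    out = pa_intersections(_net([road]), pa, buffer_km=10)
    assert not bool(out.loc["1", "direct"])
    assert bool(out.loc["1", "buffered"])


def test_pa_50km_away_untouched():
    road = LineString([(0.0, -0.5), (0.0, 0.5)])
    cx = 50.0 / KM_PER_DEG
    pa = [(Point(cx, 0.0).buffer(0.5 / KM_PER_DEG, quad_segs=16), {"pa_id": 1})]
    out = pa_intersections(_net([road]), pa, buffer_km=10)
    assert not bool(out.loc["1", "direct"]) and not bool(out.loc["1", "buffered"])


def test_direct_subset_of_buffered_and_buffer_monotonicity():
    road = LineString([(0.0, -0.5), (0.0, 0.5)])
    pas = [
        (box(-0.01, -0.1, 0.01, 0.1), {"pa_id": "hit"}),
        (Point(9.0 / KM_PER_DEG, 0.0).buffer(0.002), {"pa_id": "near"}),
        (Point(50.0 / KM_PER_DEG, 0.0).buffer(0.002), {"pa_id": "far"}),
    ]
    net = _net([road])
    wide = pa_intersections(net, pas, buffer_km=10)
    assert set(wide[wide["direct"]].index) <= set(wide[wide["buffered"]].index)
    narrow = pa_intersections(net, pas, buffer_km=2)
    assert set(narrow[narrow["buffered"]].index) <= set(wide[wide["buffered"]].index)


def test_pa_duplicate_ids_merged():
    net = _net([LineString([(0.0, 0.0), (2.0, 0.0)])])
    pas = [
        (box(0.2, -0.1, 0.6, 0.1), {"pa_id": 1}),
        (box(1.2, -0.1, 1.6, 0.1), {"pa_id": 1}),
    ]
    out = pa_intersections(net, pas)
    assert len(out) == 1
    # merged designation accumulates both crossing lengths (~0.8° of arc)
    assert out.loc["1", "intersected_length_km"] == pytest.approx(0.8 * KM_PER_DEG, rel=1e-3)
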