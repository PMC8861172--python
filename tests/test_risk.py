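import math

import numpy as np
import pytest

from roadrisk.geodesy import EARTH_RADIUS_KM
from roadrisk.grid import BinaryLayer, DensityLayer, cell_areas, make_grid
from roadrisk.risk import (
    DegenerateNormalizationError,
    RiskInputError,
    SpeciesTraits,
    body_mass_category,
    exposure,
    iucn_value,
    mean_road_density,
    risk_table,
    road_coverage,
    unprotected_fraction,
    vulnerability,
)


# --- categorical maps --------------------------------------------------


@pytest.mark.parametrize(
    "mass, cat",
    [(150, 4), (101, 4), (100, 3), (50, 3), (25, 3), (24.9, 2), (15, 2), (14.9, 1), (10, 1), (8, 1)],
)
def test_body_mass_categories(mass, cat):
    assert body_mass_category(mass) == cat


def test_body_mass_below_smallest_class_warns():
    with pytest.warns(UserWarning):
        assert body_mass_category(5.5) == 1


def test_body_mass_nonpositive_rejected():
    with pytest.raises(RiskInputError):
        body_mass_category(0)


@pytest.mark.parametrize("status, value", [("LC", 1), ("NT", 2), ("VU", 3), ("EN", 4), ("CR", 5)])
def test_iucn_ordinal_scale(status, value):
    assert iucn_value(status) == value


def test_iucn_unknown_code_rejected():
    with pytest.raises(RiskInputError):
        iucn_value("EX")


# --- exposure ----------------------------------------------------------


@pytest.mark.parametrize("dens, expo", [(0, 0), (100, 10), (303, 17.407)])
def test_exposure_is_sqrt_density(dens, expo):
    assert exposure(dens) == pytest.approx(expo, abs=5e-4)


def test_exposure_negative_rejected():
    with pytest.raises(RiskInputError):
        exposure(-1)


# --- zonal statistics --------------------------------------------------


def _world(extent=(0, 0, 2, 2), res=30):
    g = make_grid(res, extent)
    return g, cell_areas(g)


def test_mean_density_uniform():
    g, areas = _world()
    rng_layer = BinaryLayer(g, np.ones(g.shape, dtype=int))
    dens = DensityLayer(g, np.full(g.shape, 42.0))
    assert mean_road_density(rng_layer, dens, areas) == pytest.approx(42.0, rel=1e-12)


def test_mean_density_two_equal_area_cells():
    # two cells in the same row have identical spherical area
    g, areas = _world()
    mask = np.zeros(g.shape, dtype=int)
    mask[1, 0] = mask[1, 1] = 1
    vals = np.zeros(g.shape)
    vals[1, 0], vals[1, 1] = 100.0, 300.0
    out = mean_road_density(BinaryLayer(g, mask), DensityLayer(g, vals), areas)
    assert out == pytest.approx(200.0, rel=1e-12)


def test_mean_density_known_road_length():
    """Range with one meridian road: density equals closed-form L/A."""
    from roadrisk.grid import line_density

    g, areas = _world(extent=(0, 0, 3, 3), res=30)
    road = [np.array([(1.25, 0.0), (1.25, 3.0)])]  # meridian through column 2
    dens = line_density(road, g, areas)
    rng_layer = BinaryLayer(g, np.ones(g.shape, dtype=int))
    got = mean_road_density(rng_layer, dens, areas)
    L_m = EARTH_RADIUS_KM * math.radians(3.0) * 1000.0
    A = areas.values.sum()
    assert got == pytest.approx(L_m / A, rel=5e-3)


def test_mean_density_empty_range_names_species():
    g, areas = _world()
    empty = BinaryLayer(g, np.zeros(g.shape, dtype=int))
    with pytest.raises(RiskInputError, match="Gulo gulo"):
        mean_road_density(empty, DensityLayer(g, np.zeros(g.shape)), areas, species="Gulo gulo")


def test_unprotected_fraction_extremes():
    g, areas = _world()
    rng_layer = BinaryLayer(g, np.ones(g.shape, dtype=int))
    all_pa = BinaryLayer(g, np.ones(g.shape, dtype=int))
    no_pa = BinaryLayer(g, np.zeros(g.shape, dtype=int))
    assert unprotected_fraction(rng_layer, all_pa, areas) == 0.0
    assert unprotected_fraction(rng_layer, no_pa, areas) == 1.0


def test_unprotected_fraction_fosa_like_87_percent():
    # 100 equal-area range cells in one latitude row, 13 of them protected
    g = make_grid(6, (0, 0, 10, 0.1))
    areas = cell_areas(g)
    mask = np.ones(g.shape, dtype=int)
    pa = np.zeros(g.shape, dtype=int)
    pa[0, :13] = 1
    out = unprotected_fraction(BinaryLayer(g, mask), BinaryLayer(g, pa), areas)
    assert out == pytest.approx(0.87, abs=1e-9)


def test_road_coverage_fractions():
    g, _ = _world(extent=(0, 0, 10, 0.5), res=30)  # 1×20 cells
    mask = np.ones(g.shape, dtype=int)
    vals = np.zeros(g.shape)
    assert road_coverage(BinaryLayer(g, mask), DensityLayer(g, vals)) == 0.0
    vals[:] = 5.0
    assert road_coverage(BinaryLayer(g, mask), DensityLayer(g, vals)) == 1.0
    vals[0, :1] = 0.0
    vals[0, 1] = np.nan  # nodata counts as roadless
    assert road_coverage(BinaryLayer(g, mask), DensityLayer(g, vals)) == pytest.approx(18 / 20)


# --- vulnerability -----------------------------------------------------


@pytest.mark.parametrize(
    "inputs, expect", [((1, 1, 1, 1), 3.0), ((0, 0, 0, 0), 0.0), ((0.5, 1, 0, 0), 1.5)]
)
def test_vulnerability_weighted_sum(inputs, expect):
    assert vulnerability(*inputs) == pytest.approx(expect)


def test_vulnerability_rejects_out_of_range():
    with pytest.raises(RiskInputError):
        vulnerability(1.2, 0, 0, 0)


# --- the full scoring table -------------------------------------------


def _score_world(densities, traits=None, pa_rows=0):
    """n species on disjoint single-row ranges with prescribed densities."""
    n = len(densities)
    g = make_grid(60, (0, 0, n, 1))
    areas = cell_areas(g)
    vals = np.zeros(g.shape)
    ranges = {}
    for i, d in enumerate(densities):
        vals[0, i] = d
        m = np.zeros(g.shape, dtype=int)
        m[0, i] = 1
        ranges[f"Sp {i}"] = BinaryLayer(g, m)
    pa = np.zeros(g.shape, dtype=int)
    pa[:pa_rows] = 1
    if traits is None:
        traits = [SpeciesTraits(f"Sp {i}", 50.0, "VU", 5) for i in range(n)]
    return traits, ranges, DensityLayer(g, vals), BinaryLayer(g, pa), areas


def test_single_species_self_normalizes():
    records = risk_table(*_score_world([100.0]))
    r = records[0]
    assert r.exposure_star == 1.0 and r.vulnerability_star == 1.0 and r.risk == 1.0


def test_density_ratio_four_gives_risk_ratio_half():
    records = risk_table(*_score_world([100.0, 400.0]))
    by = {r.species: r for r in records}
    assert by["Sp 0"].risk / by["Sp 1"].risk == pytest.approx(0.5, rel=1e-12)


def test_three_species_match_spreadsheet_recomputation():
    """Hand-set components reproduced by an independent direct recomputation."""
    traits = [
        SpeciesTraits("Sp 0", 140.0, "CR", 12),
        SpeciesTraits("Sp 1", 30.0, "VU", 6),
        SpeciesTraits("Sp 2", 9.0, "LC", 1),
    ]
    densities = [300.0, 150.0, 10.0]
    records = risk_table(*_score_world(densities, traits))
    by = {r.species: r for r in records}

    # independent evaluation, plain arithmetic
    expo = [math.sqrt(d) for d in densities]
    iucn = [5, 3, 1]
    th = [12, 6, 1]
    bm = [4, 3, 1]
    npa = [1.0, 1.0, 1.0]
    vuln = [
        npa[i] / 1.0 + iucn[i] / 5 + 0.5 * th[i] / 12 + 0.5 * bm[i] / 4 for i in range(3)
    ]
    risk = [(expo[i] / max(expo)) * (vuln[i] / max(vuln)) for i in range(3)]
    for i in range(3):
        assert by[f"Sp {i}"].risk == pytest.approx(risk[i], rel=1e-12)
        assert by[f"Sp {i}"].vulnerability_raw == pytest.approx(vuln[i], rel=1e-12)


def test_starred_maxima_reach_one():
    records = risk_table(*_score_world([10.0, 200.0, 40.0]))
    assert max(r.exposure_star for r in records) == 1.0
    assert max(r.vulnerability_star for r in records) == 1.0


def test_scale_invariance_doubling_densities():
    a = risk_table(*_score_world([10.0, 200.0, 40.0]))
    b = risk_table(*_score_world([20.0, 400.0, 80.0]))
    for ra, rb in zip(a, b):
        assert ra.species == rb.species
        assert ra.risk == pytest.approx(rb.risk, rel=1e-12)


def test_risk_monotone_in_density():
    lo = {r.species: r for r in risk_table(*_score_world([50.0, 100.0]))}
    hi = {r.species: r for r in risk_table(*_score_world([80.0, 100.0]))}
    assert hi["Sp 0"].risk >= lo["Sp 0"].risk


def test_all_zero_densities_degenerate():
    with pytest.raises(DegenerateNormalizationError):
        risk_table(*_score_world([0.0, 0.0]))


def test_sqrt_k_exposure_ratio_recovered():
    """Constructed density ratio k yields a measured exposure ratio √k (≤1%)."""
    from roadrisk.grid import line_density

    k = 9
    g = make_grid(30, (0, 0, 4, 2))
    areas = cell_areas(g)
    # species A: k meridians in lon [0,2); species B: one meridian in [2,4)
    roads = [np.array([((0.25 + 1.5 * j / k), 0.0), ((0.25 + 1.5 * j / k), 2.0)]) for j in range(k)]
    roads.append(np.array([(3.25, 0.0), (3.25, 2.0)]))
    dens = line_density(roads, g, areas)
    ranges = {}
    for name, c0 in (("A", 0), ("B", 4)):
        m = np.zeros(g.shape, dtype=int)
        m[:, c0 : c0 + 4] = 1
        ranges[name] = BinaryLayer(g, m)
    traits = [SpeciesTraits(s, 50.0, "VU", 5) for s in ("A", "B")]
    pa = BinaryLayer(g, np.zeros(g.shape, dtype=int))
    records = {r.species: r for r in risk_table(traits, ranges, dens, pa, areas)}
    ratio = records["A"].exposure_raw / records["B"].exposure_raw
    assert ratio == pytest.approx(math.sqrt(k), rel=1e-2)


def test_missing_range_layer_is_named():
    traits, ranges, dens, pa, areas = _score_world([10.0, 20.0])
    del ranges["Sp 1"]
    with pytest.raises(RiskInputError, match="Sp 1"):
        risk_table(traits, ranges, dens, pa, areas)
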