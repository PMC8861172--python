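# roadrisk

Road networks are among the strongest pressures on terrestrial apex
predators: collisions with vehicles, habitat fragmentation, genetic
isolation, and poaching access all scale with how much road a species'
range contains.  `roadrisk` is a geospatial analysis package for
conservation scientists and road-ecology practitioners that scores each
species' risk from the existing road network, builds a per-pixel cumulative
risk surface, and screens *proposed* road alignments against it — flagging
high-impact segments, species-range crossings, and protected areas hit
directly or within a 10-km buffer.

## The model

All layers live on a north-up geographic grid (5-arcmin cells by default,
the resolution of the global gridded road-density data the method was
designed around).  For each species *i* of the analysed set:

```
Risk_i        = Exposure*_i × Vulnerability*_i
Exposure_i    = √(RoadDensity_i)          RoadDensity_i in m of road / km² of range
Vulnerability_i = nPA*_i + IUCN*_i + 0.5·TH*_i + 0.5·BM*_i
```

where `nPA` is the fraction of the range outside protected areas, `IUCN`
the ordinal Red List status (LC = 1 … CR = 5), `TH` the number of
IUCN-listed threats, and `BM` a four-level body-mass class (>100 kg = 4,
25–100 = 3, 15–25 = 2, 8–15 = 1), a proxy for home-range size.  A star
means division by the maximum over the analysed species set, so the species
list itself is part of the model input.  Road densities aggregate road
types 1–4 (highways through tertiary); type-5 local roads are excluded for
their spatial reporting bias and require explicit forcing.

Per pixel, species risks combine into the cumulative surface

```
CumulativeRisk_px = SSR_px + β·PA_px
```

with `SSR` the sum of risks of species present, `β` their mean, and `PA`
the binary protected-area flag — protected pixels gain one average species
risk.  The surface is discretized into impact levels 1–10 (equal-width bins
over the positive values; level 0 marks pixels with no species), and
proposed-road polylines are split at cell boundaries so every segment
inherits its pixel's level.

A companion data model summarises wildlife-vehicle-collision (WVC)
literature records: missing individual counts or study durations default to
one, a record's annual rate is individuals per study-year, and country
tables report the sum of annual rates ("WVC in a single year") and total
study-years (sampling effort).

All distances and areas are spherical (authalic radius 6371.0072 km);
vectors are GeoJSON, rasters plain-text ESRI ASCII grids; metric buffering
runs in a local azimuthal equidistant projection.

## Worked example

The package ships a seeded synthetic-world generator so the whole pipeline
runs without any data downloads.  The deterministic 36-species fixture
mirrors the qualitative structure of a global assessment — a densely roaded
top species, a runner-up at two-thirds of its road density, and a road-free
boreal-like range:

```python
import pathlib, tempfile
from roadrisk.synth import make_benchmark_fixture
from roadrisk.pipeline import config_for_world, run_pipeline

tmp = pathlib.Path(tempfile.mkdtemp())
make_benchmark_fixture(tmp / "world")
results = run_pipeline(config_for_world(tmp / "world", tmp / "run"))

rt = results["risk_table"]
print(rt[["road_density", "exposure_star", "vulnerability_star", "risk"]].head(5).round(3))
```

```
                      road_density  exposure_star  vulnerability_star   risk
species
Synthetus predator00       297.411          1.000               1.000  1.000
Synthetus predator03       166.200          0.748               0.864  0.646
Synthetus predator09       131.211          0.664               0.875  0.581
Synthetus predator07       148.706          0.707               0.811  0.574
Synthetus predator04       157.453          0.728               0.708  0.515
```

The top species carries 297 m/km² of road over its range and maximal
vulnerability components, so both starred factors are 1 and its risk is 1
by self-normalization; 97.2% of its range cells contain road.  Screening
the fixture's proposed roads against the cumulative surface:

```python
report = results["impact_report"]
pa = report["protected_areas"]
print(f"PAs crossed directly: {int(pa['direct'].sum())}, within 10 km: {int(pa['buffered'].sum())}")
print(f"WVC-documented species: {results['wvc']['coverage']} of {len(rt)}")
```

```
PAs crossed directly: 9, within 10 km: 17
WVC-documented species: 30 of 36
```

Nine protected areas are bisected by the proposed alignments and eight more
fall inside the 10-km buffer; roadkill records exist for 30 of the 36
analysed species.  Impact-level shares of proposed-road length (from
`report["levels"]`) sum to 100%.

The same stages are exposed on the command line:

```
roadrisk simulate --seed 1 --outdir world
roadrisk run --config config.yaml
roadrisk wvc-summary --records world/wvc_records.csv --traits world/traits.csv
```

Every run writes its artifacts (risk table CSV, cumulative-risk and
impact-level rasters, screening tables, segments GeoJSON) plus a manifest
with input checksums and all discretionary modes under the run directory.

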