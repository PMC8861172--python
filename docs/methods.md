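# Methods

This note records the modelling conventions, numerical choices, and known
limitations of `roadrisk`, in the spirit of a model-description appendix.

## Grid and geodesy

The analysis lattice is a north-up geographic grid of square-in-degrees
cells; row 0 touches the northern edge, indices are 0-based, and each cell
owns the half-open box `[west, east) × (south, north]`, with points on the
grid's outer south/east edge clamped into the boundary cells so the extent
partitions exactly.  The default resolution is 5 arc-minutes, matching the
gridded road-density products the method consumes; the extent must snap to
whole cells or construction fails with an alignment error.

All metric quantities are measured on the sphere of authalic radius
R = 6371.0072 km (the sphere with the WGS84 ellipsoid's surface area).
Cell areas use the exact spherical-quadrangle formula
`R²·Δλ·(sin φ_n − sin φ_s)`; the global 5-arcmin grid's areas sum to 4πR²
to machine precision, and an equatorial cell is ≈ 9.27 km on a side and
≈ 86 km² — the scale usually quoted as "roughly 8 km in the tropics".
Polylines are interpreted as straight lines in lon/lat (the convention of
the vector data ingested); their length is the great-circle length of a
finely densified version of that path (default step 0.01°).  Choosing the
sphere over the ellipsoid keeps lengths, areas and densities mutually
consistent; the ellipsoidal correction is sub-percent, far below the 0.5%
tolerance used for all geometric comparisons.  Geometries crossing the
antimeridian are rejected explicitly rather than silently wrapped; none of
the intended use regions need them.

## Rasterization and road density

Presence rasterization uses the cell-center rule: a cell is 1 iff its
center lies inside or on the boundary of the polygon union.  This is
deterministic, matches an exhaustive point-in-polygon oracle, and is the
default; a coverage-fraction mode (cell = 1 iff covered fraction ≥
threshold) exists for sensitivity checks but is not used in the reference
configuration.

Road density is metres of road per km² of cell.  Lines are split exactly at
cell boundaries by linear interpolation in lon/lat, each piece assigned to
the cell containing its midpoint (the half-open rule breaks boundary ties
deterministically), and measured geodesically.  Road types 1–4 are summed
cellwise with nodata treated as 0 wherever any sibling type has data; a
cell is nodata only if all types are.  Type 5 (local roads) is excluded by
default for its strong reporting bias toward developed regions, and
including it requires an explicit override that logs a warning.

## Species scoring

Mean road density over a range is the area-weighted mean of cell densities,
identical to total road length over total range area.  Exposure is its
square root.  Vulnerability sums the unprotected range fraction and the
ordinal Red List status at full weight, and the IUCN-threat count and
body-mass class at half weight, each first divided by its maximum over the
analysed species set.  Exposure and vulnerability are likewise
max-normalised before multiplying into the risk score, so every score is
relative to the species set analysed: adding or removing a species rescales
all risks.  This is deliberate and surfaced prominently — the species list
is a model input, not metadata.

Body-mass classes follow printed ranges that share endpoints; intervals are
taken lower-inclusive ([8,15) = 1, [15,25) = 2, [25,100] = 3, >100 = 4),
masses under 8 kg fall into class 1 with a warning (small species included
as their ecosystems' main predators), and an explicit `bm_category` column
in the traits CSV overrides the mass-derived class.  The threat count is
used raw (no cap).  "Covered by roads" means cell density strictly
positive, with nodata counting as roadless.  Any normalization maximum of
zero (e.g. a world with no roads at all, or all ranges fully protected)
raises a degenerate-normalization error instead of producing NaNs.

## Cumulative surface and impact levels

The cumulative surface is strictly cellwise: the sum of the risks of
species present plus, on protected cells, their mean (defined as 0 where no
species occurs, so empty protected cells score 0 — the one case the
formula leaves open).  No smoothing or distance decay is applied.  The
continuous surface is discretized into levels 1–10 by equal-width bins over
(0, max] with ceiling assignment; level 0 is reserved for cells with no
species.  The binning rule is a reporting convention, not part of the
model, so it is configurable (quantile bins as the alternative) and the
mode plus normalizing maximum are recorded in every layer and manifest.
When screening a regional window the maximum from the widest available
extent should be supplied so levels stay comparable across regions.

## Proposed-road screening

Proposed polylines are split at cell boundaries; segments inherit their
cell's cumulative value and level, and the per-level table reports km and
percentage of total network length (percentages sum to 100 within 0.1).
Species crossings are computed vector-on-vector (network ∩ range polygon),
avoiding a second discretization; the rasterized route exists behind a flag
for strict grid-consistency comparisons.  Crossing lengths are reported in
km, as a share of network length, and per km² of range area (the
range-relative impact metric).

Buffering in geographic coordinates is meaningless, so protected-area
proximity is evaluated in a local spherical azimuthal equidistant
projection centered on each protected area; distances from the center are
exact and the distortion at screening scales is far below the 0.5 km that
would matter for a 10-km threshold.  A protected area is "direct" on any
nonempty intersection with the network — a tangent touch counts, with
length 0 — and "buffered" if within the buffer distance; direct implies
buffered by construction.  Features sharing an id are merged before
counting, since protected-area databases contain multi-part and overlapping
designations; counts are therefore per designation id, not per database
row, which should be kept in mind when comparing against row-counted
figures.

## WVC record conventions

One record is one study × species × country entry.  Missing individual
counts or study durations are set to one (the compilation convention for
incomplete reports), so each record contributes at least one individual and
one study-year; the annual rate is individuals per study-year.  The
per-country "single-year" total is the sum of its records' annual rates —
the reading consistent with the rate definition — with a per-year-max
alternative available but flagged experimental.  Sampling effort is the sum
of study-years.  Species names match case-insensitively on canonical
binomials; an (empty) synonym-table hook exists.  Calendar years outside
1963–2021, the span of the collated literature, are flagged, not rejected.

## Synthetic worlds and what passing tests show

The generator emulates all six inputs on a small window (default 10°×10°
at 5 arc-minutes, 36 species, 15% protected-area coverage, roadkill records
for 30 of 36 species — the conditions of the reference analysis, at desk
scale).  Rectangle ranges and lattice roads are snapped so ground truth is
closed-form: range and PA cell sets exact, per-cell road lengths from
analytic meridian/parallel arc lengths, and expected scores from a
plain-loop evaluation sharing no code with the engine.  Blob ranges and
random-walk roads provide irregular-geometry fuzzing, checked against
densify-and-bin oracles instead of closed forms.  All randomness flows from
one explicit seed; identical parameters give byte-identical files.

A deterministic 36-species fixture reproduces the qualitative structure of
a global assessment (a top species with ~97% of its range roaded, a
runner-up near two-thirds of its density, a road-free boreal-like range)
and is used for ordering and report-consistency tests.

These fixtures establish correctness of the computations, not realism:
they contain no spatial autocorrelation, no coastline clipping, no
multi-polygon ranges spanning hemispheres, and no nodata structure like
real road products.  Passing tests show the equations, geometry kernels and
conventions are implemented exactly; they say nothing about the ecological
validity of the scores on real data.

## Problem sizes and numerical tolerances

Tests and the acceptance script run on grids up to ~100×100 cells
(fixture: 36×432) with up to 36 species — sizes chosen so closed-form
oracles stay exact and the full suite completes in seconds.  Geometric
comparisons use 0.5% relative tolerance (densification and sphere/path
conventions), score comparisons 1e-9 relative against direct evaluation on
identical inputs, and the cumulative-surface identities are exact.  Risk
ties in output tables break alphabetically; all stages are deterministic
for fixed inputs, and manifests record checksums to make reruns provably
identical.

## Known limitations

Global scoring underestimates local road impacts on wide-ranging species —
a low global score does not mean low risk for a particular population.
Only geographic (lon/lat) inputs are supported; there is no reprojection
machinery beyond the internal buffering projection.  Vector I/O is GeoJSON
and raster I/O plain-text ASCII grids; heavier binary formats are out of
scope.  The screening stage models exposure only: deforestation, land-use
change and poaching-pressure dynamics that roads trigger are not computed.
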