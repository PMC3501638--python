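# Methods

## Problem and scope

Digitized natural-history collections are the main source of occurrence
data for southern African rodents, and rodent assemblages are in turn a
standard proxy in Plio-Pleistocene palaeoenvironmental reconstruction:
under the actualistic assumption, the habitats and climates occupied by an
extant genus bound what its fossil look-alikes tolerated. Turning raw
museum tables into defensible occupancy and climate-envelope statistics
requires a chain of unglamorous but consequential steps — record QC,
coordinate standardization, boundary-aware validation, overlay on a nested
vegetation classification, raster extraction — each with choices that
change the numbers. This package implements that chain as a tested
library, and pairs it with a synthetic generator so every step can be
scored against known truth.

Analyses are run at genus level throughout: genus is generally the lowest
taxonomic level to which fragmentary micromammal skeletal material can be
identified without molecular data, so genus-level envelopes are the
quantities a palaeontologist can actually apply.

## Record quality control (`records_qc`)

Raw tables are parsed without silently dropping rows; unparseable
coordinate strings demote a record to "no coordinates" with a logged
warning. A user-supplied synonym table updates taxonomy before filtering
(mechanism only — no taxonomic authority is bundled).

Exclusion rules run in a fixed order:

1. records without coordinates;
2. exact duplicates (all fields equal; the first occurrence is kept);
3. accession collisions — every record in a group that shares one
   (accession number, source museum) pair across more than one taxon is
   removed, because the source of the conflict cannot be identified from
   the database alone. Collisions are scoped per museum: DM and NMNH
   number independently, so equal numbers across museums are not
   conflicts;
4. coordinates reported in the quarter-degree-square (QDS) system — a
   15′ × 15′ cell centre is ~±9 km of positional slack, too coarse for
   point overlays. Detection uses the reporting-format column when the
   table has one, plus a fallback that flags decimal pairs whose
   fractional parts are QDS cell centres ({.125, .375, .625, .875} within
   1e-9);
5. introduced/commensal taxa, from a user list with genus wildcards;
6. genus-only records in genera containing both introduced and natural
   species (e.g. *Mus* spp.), which cannot be classified either way.

The relative order of rules 2 and 3 is a design choice (duplicates first),
not something the record semantics force; the audit trail makes either
order reconstructible. All rules are applied uniformly to every source
collection. Conservation (|in| = |out| + removals) and idempotence are
property-tested.

## Georeferencing (`georef`)

Coordinates are standardized to decimal degrees (DMS parsed exactly,
southern/western hemispheres negative) and rounded to six decimals
(≈0.11 m), which also defines locality identity. No geodetic datum
transformation is applied: the residual offset between the Cape Datum and
Hartebeesthoek94/WGS84 frames seen in these collections (tens of metres in
longitude, up to ~300 m in latitude) is accepted, and the datum tag is
carried through for transparency. Consequently all metric geometry uses a
local equirectangular frame plus the haversine (sphere R = 6 371 km);
at snap scales (≤200 m) the approximation error is far below the accepted
datum error.

Validation runs in a fixed order, mirroring how a curator would work:

1. **Study-area boundary.** Points inside pass; points outside but within
   `max_snap_m` (default 200 m, configurable — the threshold describes
   "on or slightly over the boundary" cases) are snapped to the nearest
   boundary point and nudged 1e-6° into the interior, with an escalation
   fallback guaranteeing the corrected point tests inside under any
   covering convention; points farther out are removed as irreconcilable.
2. **Aquatic features.** The same contract inverted: points inside a
   river/lake/dam polygon are displaced to the nearest shore point (and
   re-checked against all aquatic polygons); mid-water points beyond the
   threshold are removed.
3. **Administrative claims.** A record claiming a province or state is
   checked against the admin polygons; a mismatch within the snap distance
   of the claimed unit is corrected into it, otherwise the record is
   removed. Unknown claimed names degrade to "no claim" with a warning
   (many historical records predate provincial re-designation).

Surviving records collapse into localities by exact rounded-coordinate
equality; locality ids are assigned in sorted (lat, lon) order so the
result is independent of row order.

## Vegetation overlay (`habitat`)

The vegetation model is a three-level nested hierarchy (vegetation unit →
bioregion → biome) with an azonal override: units whose hydrogeology and
pedology override the surrounding zonal vegetation report the separate
"Azonal" biome, giving nine zonal biomes plus Azonal. Point-in-polygon
assignment is boundary-inclusive with a lexicographic-smallest-unit-id
tie-break, making edge cases deterministic regardless of polygon order;
assignment is cross-checked against an independent ray-casting oracle in
the tests.

Occupancy tables count either unique localities (each site once) or
specimens (sites weighted by collection size). The dual weighting is a
collector-bias diagnostic: uneven collecting inflates specimen counts
without implying habitat preference, while complete collections make
specimen counts informative about abundance — since the historical
collection strategies are unknowable, both are reported and their
congruence summarized. Congruence is the mean and median of absolute
percent differences over the union of nonzero cells per taxon (an absent
cell counts as zero); taxa with any single cell differing by more than 10
percentage points are flagged. Zero cells are omitted from tables (wide
output prints dashes); per-taxon percents sum to 100 up to rounding.

Coarse-scale cartographic layers dissolve biome polygons under 2000 ha and
bioregion polygons under 600 ha into neighbours. `dissolve_small_polygons`
reproduces this: connected same-class polygons strictly below the
threshold merge into the same-level neighbour sharing the longest
boundary, iterating smallest-first for determinism; a polygon of exactly
the threshold area is retained; total area is conserved to 1e-6 relative.
`compare_query_levels` then measures the fraction of localities whose
biome differs between the full-resolution rollup and the dissolved layer —
the scale artifact that querying at unit level avoids.

Hectares on geographic coordinates use cosine-of-latitude scaling of the
planar degree² area; the same approximation is used by the generator so
threshold logic is self-consistent. Exactness is irrelevant at the
landscape scales where the 600/2000 ha thresholds bite.

## Climate envelopes (`climate`)

Six bioclim-style variables are used: MAT, MxTWM, MnTCM (°C) and MAP, PWM,
PDM (mm) — gross plus extreme means of temperature and precipitation.
Grids are read from ESRI ASCII with a nodata sentinel; a `scale_factor`
(default 1.0) divides raw values for layers shipped as integer tenths of a
degree.

Cell membership is half-open — a point on a shared vertical edge belongs
to the eastern cell, on a horizontal edge to the southern cell — so
lookup is deterministic; grid edge semantics are otherwise unspecified by
the data formats. Rasters can also be converted to discrete-valued
searchable polygons (`polygonize`, value-preserving optional merging);
direct lookup and polygon query are equivalent by construction and this
dual path is asserted exactly in the tests. Nodata extractions are
excluded from statistics with a log entry, never imputed — the visible
consequence is that localities snapped to the coast or border can lose a
cell whose centre falls outside the mapped area.

Per taxon × variable, eight statistics are computed (n, mean, sd, min,
Q1, median, Q3, max) under both weightings; the specimen weighting
replicates each locality's value by the taxon's specimen count there, so
the two weightings coincide exactly when every count is 1. The median of
an even count is the mean of the central pair; quartiles use the inclusive
(Tukey hinge) method; sd is the n−1 sample deviation, defined as 0 for a
single value. Cross-taxon summaries take the median, minimum and maximum
across taxa of the per-taxon means, carrying the extreme taxa
(alphabetically first on exact ties).

The bundled 35-genus table of published climate means supports a worked
example: cross-taxon medians and extremes recomputed from its locality
columns reproduce the reported values (median MAT 18.0 °C, median MAP
616 mm, etc.). Specimen-weighted cross-taxon *medians* reported alongside
the source table appear to have been computed over raw specimen values
rather than the printed per-taxon means, so only locality-weighted medians
and the printed specimen-weighted extremes are asserted.

## Reporting (`reporting`)

Two wide tables mirror the publication shapes: per-genus climate means
(temperatures to one decimal, precipitation to whole millimetres) and
percent biome occupation (dashes for zeros, an exact 100 printed without
decimals). Rounding is round-half-even everywhere; dashes appear only in
the wide human-readable tables, never in tidy CSVs. Identical inputs
produce byte-identical files. Locality sets export as RFC 7946 GeoJSON
FeatureCollections, one per taxon.

## Synthetic generator (`synthgen`)

The real inputs (museum databases; the licensed national vegetation map;
WORLDCLIM rasters) cannot be redistributed, so the generator emulates
their structure and failure modes:

* **Landscape** — a convex study area (~1.8° radius) partitioned by
  nested seeded Voronoi tessellation into biomes → bioregions → units:
  irregular, realistic adjacency with exactly non-overlapping nesting.
  Options plant azonal units and sub-2000-ha alien-biome inclusions
  (default 1500 ha, provoking the dissolution artifact), small lakes
  (150 m radius, so a mid-lake point is always within snapping range of
  shore), and a two-province admin split.
* **Climate** — each variable is a linear lat/lon gradient plus optional
  Gaussian noise at cell centres (0.05° cells), nodata outside the area,
  precipitation clipped at zero and PDM ≤ PWM enforced cellwise; the
  closed-form parameters are stored so envelope recovery can be checked
  analytically.
* **Collections** — localities drawn per taxon from a biome-occupancy
  probability vector (uniform within the class polygons, never in water),
  specimen counts fixed or 1+Poisson, one record per specimen, a mix of
  decimal and DMS coordinate notations. Defects are injected into
  disjoint record subsets at configured rates: blanked coordinates, exact
  duplicate rows, cross-taxon accession collisions (pairs within one
  museum), QDS-centre snapping of the reported coordinate, displacement
  20–200 m outside the boundary, placement into a lake, and extra
  introduced-taxon rows. Every injection is labelled in the truth bundle,
  keyed by (accession, museum).

Defaults are the study conditions used throughout the tests: three biomes
(2 bioregions × 2 units each), QC defect rates of 5% missing, 5%
duplicate, 2% collision and 5% quarter-degree — the magnitudes a curator
would recognize from real digitized collections — and georeferencing
defects off unless a test turns them on. Test problem sizes (500
localities per taxon for recovery, 1000-point oracle comparisons, 50-unit
mosaics) are chosen so that binomial envelopes are tight and runs stay in
seconds. One global seed fans out via `SeedSequence` to per-stage child
seeds, so stages re-run independently and byte-identically.

What the generator does *not* emulate — and hence what passing tests do
not show about real data: real vegetation geometry (Voronoi cells are
convex-ish and lack the sliver/archipelago structure of mapped
vegetation), spatially autocorrelated collecting effort (localities are
independent draws, real collections cluster along roads and rivers),
gazetteer-style textual localities, datum mixtures with systematic offsets,
and non-linear climate fields. The pipeline's correctness claims are
therefore about the operations, not about any real fauna.

## Numerical conventions and degenerate inputs

* Haversine on a 6 371 000 m sphere; local equirectangular frames for
  nearest-point and area computations.
* Snap nudge: 1e-6°, escalated ×10 up to 1e-3° with a fallback direction
  toward the polygon's representative point; failure to place the point
  raises rather than silently passing.
* Empty QC output is legal; an all-nodata raster polygonizes to an empty
  list with a warning; a taxon with no usable extractions is omitted with
  a warning; an isolated sub-threshold polygon with no neighbour is left
  in place with a warning.
* Dissolution ties (equal shared boundary length) resolve to the first
  candidate in the stable polygon order; assignment ties on shared edges
  resolve to the smallest unit id; polygonized-layer query ties resolve
  to the smallest value.

## Known limitations

* No gazetteer or imagery-based vetting: points the rules cannot reconcile
  are removed, which understates recoverable records relative to a manual
  workflow.
* Quarter-degree detection by fractional parts can in principle flag a
  genuine high-precision coordinate that happens to sit on a QDS centre;
  with six-decimal continuous coordinates this has measure zero, but
  tables pre-rounded to three decimals would need the explicit
  reporting-format column.
* The congruence statistic's averaging set (union of nonzero cells per
  taxon) is one of several defensible definitions; alternatives (all
  cells, per-taxon means first) give different numbers and the choice is
  documented rather than asserted against any external value.
* Area computation is an equal-area approximation; for polygons spanning
  many degrees of latitude the hectare error grows, which matters only if
  dissolution thresholds are applied to continent-scale polygons.
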