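# museoclim

Turn digitized natural-history museum records into quantitative
biogeography: habitat occupancy across a nested vegetation hierarchy and
climate-envelope statistics per taxon, with the record-level quality
control and georeferencing that make those numbers defensible.

The package is aimed at mammalogists and palaeoecologists working with
southern-African-style inputs — specimen tables from museum databases, a
biome/bioregion/vegetation-unit polygon hierarchy with azonal overrides,
and WORLDCLIM-style bioclimatic rasters — but every stage is generic. A
core use case is actualistic palaeoenvironmental reconstruction: the
habitats and climates occupied by extant rodent genera bound what their
fossil counterparts tolerated, so genus-level envelopes computed from
modern collections are the calibration data.

## What it computes

For each taxon *t* with localities *L(t)* (unique coordinate pairs) and
specimen counts *s(ℓ, t)* per locality:

* **Percent occupancy** of habitat class *c* at hierarchy level
  biome/bioregion/vegetation-unit, under two weightings:
  locality-weighted `100·|{ℓ ∈ L(t): class(ℓ)=c}|/|L(t)|` and
  specimen-weighted `100·Σ_{class(ℓ)=c} s(ℓ,t)/Σ s(ℓ,t)`. The divergence
  between the two is a collector-bias diagnostic: their mean/median
  absolute cell difference is reported and taxa with any cell differing
  by >10 percentage points are flagged.
* **Climate envelopes**: n, mean, sd, min, Q1, median, Q3, max of six
  bioclim variables (MAT, MxTWM, MnTCM in °C; MAP, PWM, PDM in mm)
  extracted at localities, under both weightings, plus cross-taxon
  medians and extremes of the per-taxon means.
* **The dissolution artifact**: the fraction of localities whose biome
  changes when queried against a coarse-scale layer in which biome
  polygons <2000 ha (bioregion <600 ha) have been dissolved into
  neighbours, versus rolling up from the full-resolution units.

Upstream of that: ordered exclusion rules (missing coordinates, exact
duplicates, cross-taxon accession collisions within a museum,
quarter-degree-precision records, introduced taxa, ambiguous genus-only
records), DMS/decimal standardization, ≤200 m boundary snapping, aquatic
displacement, and administrative-claim checking — every removal and
correction logged so record counts always reconcile.

A synthetic generator (`museoclim.synthgen`) builds Voronoi-nested
vegetation mosaics, gradient climate surfaces and error-injected museum
tables with truth labels, so the whole chain is testable without any
proprietary download.

## Worked example

The package bundles a published table of per-genus climate means for the
35 rodent genera of South Africa, Lesotho and Swaziland (19,471 records,
1,527 unique localities; locality- and specimen-weighted means for all
six variables). Recomputing the cross-taxon summaries:

```python
from museoclim import (load_genus_climate_means, genus_means_to_stats,
                       cross_taxon_summary)

wide = load_genus_climate_means()
print(wide["localities"].median(), wide["specimens"].median())
summary = cross_taxon_summary(genus_means_to_stats(wide))
print(summary.set_index(["variable", "weighting"]).loc[("MAT", "LOCALITY")])
```

prints median counts of `62.0` localities and `185.0` specimens per
genus, and for locality-weighted MAT a cross-taxon median of `18.0` °C.
The full summary reproduces the reported extremes: specimen-weighted MAP
ranges from 120 mm (*Petromyscus*) to 961 mm (*Grammomys*), and
specimen-weighted MAT from 15.6 °C (*Myomyscus*) to 21.2 °C
(*Paraxerus*); the largest collection is *Mastomys* with 478 localities.

## The analysis pipeline

Numbered drivers under `analysis/` chain the stages on a generated
scenario and write their tables under `results/`:

```
python analysis/01_generate_scenario.py   # records + layers + grids + truth
python analysis/02_qc_records.py          # exclusion rules, audit log
python analysis/03_georeference.py        # snap/displace/check, localities
python analysis/04_habitat_occupancy.py   # occupancy, congruence, artifact
python analysis/05_climate_envelopes.py   # envelopes, cross-taxon summary
```

A typical run of step 2 prints

```
4929 raw records -> 4055 clean; removals: {'MISSING_COORDS': 230,
'DUPLICATE': 230, 'ACCESSION_COLLISION': 92, 'QUARTER_DEGREE': 230,
'INTRODUCED': 92}
```

and the truth bundle confirms those removals match the injected defects
one for one. The same stages are available as a CLI (`museoclim qc`,
`museoclim georef`, `museoclim occupancy`, `museoclim climstats`,
`museoclim scenario`, `museoclim export`); see `museoclim --help`.

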