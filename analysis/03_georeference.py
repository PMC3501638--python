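#!/usr/bin/env python
"""Validate cleaned records against the polygon layers and build localities.

Chains study-area validation (with <=200 m boundary snapping), aquatic
displacement and administrative-claim checking, then collapses the
surviving records into unique localities and exports per-taxon GeoJSON
distributions.
"""

import argparse
import csv
from pathlib import Path

from museoclim import build_localities, georeference, read_records
from museoclim.georef import Locality, load_study_area
from museoclim.reporting import export_distribution_geojson

RESULTS = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--snap-m", type=float, default=200.0)
    args = ap.parse_args()

    scen = RESULTS / "scenario"
    records, _ = read_records(RESULTS / "clean_records.csv")
    area = load_study_area(scen / "boundary.geojson", scen / "water.geojson",
                           scen / "admin.geojson")
    placed, audit = georeference(records, area, max_snap_m=args.snap_m)
    audit.to_csv(RESULTS / "georef_audit.csv")
    locs = build_localities(placed)
    loc_by_point = {loc.point: loc.locality_id for loc in locs}

    with open(RESULTS / "placements.csv", "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(["accession_id", "source", "genus", "species", "lat", "lon",
                    "locality_id"])
        for rec, pt in placed:
            w.writerow([rec.accession_id, rec.source.value, rec.genus, rec.species,
                        f"{pt.lat:.6f}", f"{pt.lon:.6f}", loc_by_point[pt]])
    with open(RESULTS / "localities.csv", "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(["locality_id", "lat", "lon", "n_records"])
        for loc in locs:
            w.writerow([loc.locality_id, f"{loc.point.lat:.6f}",
                        f"{loc.point.lon:.6f}", loc.specimen_count])

    # regroup localities per taxon for the distribution export
    taxon_locs: dict[str, dict[int, list]] = {}
    for rec, pt in placed:
        taxon_locs.setdefault(rec.genus, {}).setdefault(
            loc_by_point[pt], []).append((rec.accession_id, rec.source.value))
    loc_points = {loc.locality_id: loc.point for loc in locs}
    by_taxon = {
        taxon: [Locality(lid, loc_points[lid], tuple(refs))
                for lid, refs in sorted(groups.items())]
        for taxon, groups in taxon_locs.items()
    }
    export_distribution_geojson(by_taxon, RESULTS / "distributions")

    corr = {k.value: v for k, v in audit.counts_by_rule.items()}
    print(f"{len(records)} records -> {len(placed)} retained as {len(locs)} unique "
          f"localities; corrections/removals: {corr}")


if __name__ == "__main__":
    main()
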