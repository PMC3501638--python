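#!/usr/bin/env python
"""Generate the synthetic study system used by the downstream analyses.

Writes a museum record table with realistic database defects, the nested
vegetation mosaic, study-area/water/admin layers, six climate grids, and
the truth bundle to results/scenario/.
"""

import argparse
from pathlib import Path

from museoclim import write_ascii_grid
from museoclim.georef import save_study_area
from museoclim.records_qc import write_records
from museoclim.synthgen import ScenarioConfig, generate_scenario


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--outdir", type=Path,
                    default=Path(__file__).resolve().parents[1] / "results" / "scenario")
    args = ap.parse_args()

    cfg = ScenarioConfig(seed=args.seed, error_rates={
        "missing_coords": 0.05, "duplicate": 0.05, "accession_collision": 0.02,
        "quarter_degree": 0.05, "boundary_overshoot": 0.02, "water_point": 0.01,
        "introduced": 0.02,
    })
    area, hmap, surfaces, records, truth = generate_scenario(cfg)

    out = args.outdir
    out.mkdir(parents=True, exist_ok=True)
    save_study_area(area, out / "boundary.geojson", out / "water.geojson",
                    out / "admin.geojson")
    hmap.to_geojson(out / "vegetation.geojson")
    for var, surf in surfaces.items():
        write_ascii_grid(surf, out / f"{var.value}.asc")
    write_records(records, out / "records.csv")
    truth.to_json(out / "truth.json")

    n_err = sum(1 for r in truth.records if r.error)
    print(f"scenario seed={args.seed}: {len(records)} records "
          f"({n_err} with injected defects), {len(hmap.units)} vegetation units, "
          f"{len(hmap.bioregions)} bioregions, "
          f"{len(hmap.biomes) - 1} zonal biomes + Azonal -> {out}")


if __name__ == "__main__":
    main()
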