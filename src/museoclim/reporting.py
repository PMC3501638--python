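"""Rendering of the analysis outputs in their publication table shapes.

Two wide human-readable tables are produced: the climate-means table (one
row per genus, paired locality/specimen columns per variable; temperature
to one decimal, precipitation to integer millimetres) and the percent
biome-occupation table (paired L/S percent columns per class, dashes for
zero cells, an exact 100 printed without decimals). Rounding is
round-half-even throughout; dashes appear only in the wide tables, never
in tidy CSVs. Per-taxon locality sets are exported as RFC 7946 GeoJSON
FeatureCollections.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import geomutil
from .climate import VARIABLES, Variable
from .georef import Locality
from .habitat import OccupancyTable

DASH = "-"


@dataclass
class RunManifest:
    """Provenance of one pipeline run: inputs, config, seeds, stage counts."""

    input_paths: dict[str, str] = field(default_factory=dict)
    config_hash: str = ""
    seeds: dict[str, int] = field(default_factory=dict)
    stage_counts: dict[str, int] = field(default_factory=dict)
    timestamp: str = ""

    def validate(self) -> None:
        c = self.stage_counts
        chain = [c.get(k) for k in ("raw", "post_qc", "georeferenced")]
        known = [v for v in chain if v is not None]
        if any(a < b for a, b in zip(known, known[1:])):
            raise ValueError(f"stage counts must be non-increasing: {c}")
        if ("localities" in c and "georeferenced" in c
                and c["localities"] > c["georeferenced"]):
            raise ValueError("more localities than georeferenced records")

    @staticmethod
    def hash_config(config: dict) -> str:
        return hashlib.sha256(
            json.dumps(config, sort_keys=True, default=str).encode()).hexdigest()[:16]

    def to_json(self, path) -> None:
        self.validate()
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(self.__dict__, fh, indent=2, sort_keys=True)
            fh.write("\n")


def _fmt_value(value: float, variable: Variable) -> str:
    if variable.units == "degC":
        return f"{round(float(value), 1):.1f}"
    return str(round(float(value)))


def write_table1(stats: pd.DataFrame, counts: pd.DataFrame, path=None) -> pd.DataFrame:
    """Wide per-genus climate-means table with paired L/S columns.

    ``stats`` is tidy envelope output covering both weightings (columns
    taxon, variable, weighting, mean); ``counts`` has columns taxon,
    localities, specimens. Temperatures are printed to one decimal,
    precipitation to whole millimetres, both round-half-even; parsing a
    written table back recovers the rounded values exactly.
    """
    means = stats.set_index(["taxon", "variable", "weighting"])["mean"]
    counts = counts.set_index("taxon")
    rows = []
    for taxon in sorted(counts.index):
        row: dict[str, object] = {
            "taxon": taxon,
            "localities": int(counts.loc[taxon, "localities"]),
            "specimens": int(counts.loc[taxon, "specimens"]),
        }
        for var in VARIABLES:
            for wt, suffix in (("LOCALITY", "L"), ("SPECIMEN", "S")):
                row[f"{var.value}_{suffix}"] = _fmt_value(
                    means[(taxon, var.value, wt)], var)
        rows.append(row)
    out = pd.DataFrame(rows)
    if path is not None:
        out.to_csv(path, index=False, lineterminator="\n")
    return out


def parse_table1(path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_table2(table_locality: OccupancyTable, table_specimen: OccupancyTable,
                 path=None) -> pd.DataFrame:
    """Wide percent-occupation table with paired L/S columns per class.

    Zero cells print as dashes; percents to one decimal except an exact
    100, which prints as "100".
    """
    if table_locality.level is not table_specimen.level:
        raise ValueError("occupancy tables are at different hierarchy levels")

    def fmt(p: float) -> str:
        if p == 0.0:
            return DASH
        if p == 100.0:
            return "100"
        return f"{round(p, 1):.1f}"

    classes = sorted(set(table_locality.classes()) | set(table_specimen.classes()))
    taxa = sorted(set(table_locality.totals) | set(table_specimen.totals))
    rows = []
    for taxon in taxa:
        row: dict[str, object] = {"taxon": taxon}
        for cls in classes:
            row[f"{cls}_L"] = fmt(table_locality.percent(taxon, cls))
            row[f"{cls}_S"] = fmt(table_specimen.percent(taxon, cls))
        rows.append(row)
    out = pd.DataFrame(rows)
    if path is not None:
        out.to_csv(path, index=False, lineterminator="\n")
    return out


def export_distribution_geojson(localities_by_taxon: dict[str, list[Locality]],
                                outdir) -> list[Path]:
    """One GeoJSON FeatureCollection of locality points per taxon.

    Coordinates are [lon, lat] per RFC 7946; properties carry taxon,
    locality_id and n_specimens.
    """
    from shapely.geometry import Point

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written = []
    for taxon in sorted(localities_by_taxon):
        feats = [
            (Point(loc.point.lon, loc.point.lat),
             {"taxon": taxon, "locality_id": loc.locality_id,
              "n_specimens": loc.specimen_count})
            for loc in localities_by_taxon[taxon]
        ]
        path = outdir / f"{taxon}.geojson"
        geomutil.write_geojson(path, feats)
        written.append(path)
    return written
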