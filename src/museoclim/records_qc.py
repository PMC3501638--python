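"""Museum record parsing and exclusion rules.

Digitized museum databases carry systematic defects: rows without
coordinates, exact duplicate rows, the same accession number assigned to
specimens of different taxa, coordinates reported only to quarter-degree
grid precision, and records of commensal/introduced taxa. This module
parses raw delimited tables into :class:`SpecimenRecord` objects and
applies a fixed, ordered sequence of exclusion rules, logging every
removal so that input and output record counts always reconcile.
"""

from __future__ import annotations

import csv
from collections import Counter
from dataclasses import dataclass, field, replace
from enum import Enum
from pathlib import Path

from .coords import detect_format, is_quarter_degree_value, parse_angle


class CoordFormat(str, Enum):
    DECIMAL = "DECIMAL"
    DMS = "DMS"
    QUARTER_DEGREE = "QUARTER_DEGREE"
    ABSENT = "ABSENT"


class Source(str, Enum):
    DM = "DM"
    NMNH = "NMNH"
    OTHER = "OTHER"


class DatumTag(str, Enum):
    WGS84 = "WGS84"
    HARTEBEESTHOEK94 = "HARTEBEESTHOEK94"
    CAPE = "CAPE"
    UNKNOWN = "UNKNOWN"


class RuleCode(str, Enum):
    MISSING_COORDS = "MISSING_COORDS"
    DUPLICATE = "DUPLICATE"
    ACCESSION_COLLISION = "ACCESSION_COLLISION"
    QUARTER_DEGREE = "QUARTER_DEGREE"
    INTRODUCED = "INTRODUCED"
    AMBIGUOUS_GENUS = "AMBIGUOUS_GENUS"
    OUTSIDE_AREA_UNRESOLVED = "OUTSIDE_AREA_UNRESOLVED"
    ADMIN_UNRESOLVED = "ADMIN_UNRESOLVED"
    SNAPPED = "SNAPPED"
    WATER_DISPLACED = "WATER_DISPLACED"
    COORD_CORRECTED = "COORD_CORRECTED"
    TAXONOMY_UPDATED = "TAXONOMY_UPDATED"
    PARSE_WARNING = "PARSE_WARNING"


@dataclass(frozen=True)
class SpecimenRecord:
    """One raw museum database row."""

    accession_id: str
    source: Source
    genus: str
    species: str = ""
    lat_raw: str = ""
    lon_raw: str = ""
    coord_format: CoordFormat = CoordFormat.ABSENT
    datum_tag: DatumTag = DatumTag.UNKNOWN
    province_claim: str = ""
    state_claim: str = ""
    locality_text: str = ""
    introduced: bool = False

    @property
    def taxon(self) -> tuple[str, str]:
        return (self.genus, self.species)


@dataclass(frozen=True)
class AuditEvent:
    accession_id: str
    source: str
    rule_code: RuleCode
    detail: str = ""


@dataclass
class FilterAudit:
    """Removal/correction log for one pipeline stage."""

    events: list[AuditEvent] = field(default_factory=list)

    def log(self, rec: SpecimenRecord, rule: RuleCode, detail: str = "") -> None:
        self.events.append(AuditEvent(rec.accession_id, str(rec.source.value), rule, detail))

    @property
    def counts_by_rule(self) -> dict[RuleCode, int]:
        return dict(Counter(e.rule_code for e in self.events))

    def count(self, rule: RuleCode) -> int:
        return sum(1 for e in self.events if e.rule_code == rule)

    def to_csv(self, path) -> None:
        with open(path, "w", newline="", encoding="utf-8") as fh:
            w = csv.writer(fh)
            w.writerow(["accession_id", "source", "rule_code", "detail"])
            for e in self.events:
                w.writerow([e.accession_id, e.source, e.rule_code.value, e.detail])


#: our field name -> default input column name
DEFAULT_DIALECT: dict[str, str] = {
    "accession_id": "accession_id",
    "source": "source",
    "genus": "genus",
    "species": "species",
    "lat_raw": "lat",
    "lon_raw": "lon",
    "coord_format": "coord_format",
    "datum_tag": "datum",
    "province_claim": "province",
    "state_claim": "state",
    "locality_text": "locality",
    "introduced": "introduced",
}

_MANDATORY = ("accession_id", "source", "genus", "species", "lat_raw", "lon_raw")


class ColumnMappingError(KeyError):
    """A mandatory input column is missing from the table or the mapping."""


def _classify_coords(lat_raw: str, lon_raw: str) -> tuple[CoordFormat, str]:
    """Infer the reporting format of a coordinate pair.

    Returns (format, warning_detail); the detail is empty unless a non-empty
    string failed to parse, in which case the pair is demoted to ABSENT.
    """
    if not lat_raw and not lon_raw:
        return CoordFormat.ABSENT, ""
    if not lat_raw or not lon_raw:
        return CoordFormat.ABSENT, f"one coordinate empty: lat={lat_raw!r} lon={lon_raw!r}"
    try:
        fmts = {detect_format(lat_raw), detect_format(lon_raw)}
        lat, lon = parse_angle(lat_raw), parse_angle(lon_raw)
    except ValueError as err:
        return CoordFormat.ABSENT, str(err)
    if fmts == {"DECIMAL"} and is_quarter_degree_value(lat) and is_quarter_degree_value(lon):
        return CoordFormat.QUARTER_DEGREE, ""
    return (CoordFormat.DMS if "DMS" in fmts else CoordFormat.DECIMAL), ""


def read_records(path, dialect: dict[str, str] | None = None,
                 delimiter: str | None = None) -> tuple[list[SpecimenRecord], FilterAudit]:
    """Read a delimited museum table into records; no row is silently dropped.

    ``dialect`` maps record field names to input column names (defaults in
    :data:`DEFAULT_DIALECT`); optional fields whose column is absent default
    cleanly. Unparseable coordinate strings give ``coord_format=ABSENT`` with
    a PARSE_WARNING audit event. The delimiter is sniffed (comma vs tab)
    unless given.
    """
    mapping = dict(DEFAULT_DIALECT)
    if dialect:
        mapping.update(dialect)
    text = Path(path).read_text(encoding="utf-8")
    if delimiter is None:
        header = text.splitlines()[0] if text else ""
        delimiter = "\t" if "\t" in header else ","
    reader = csv.DictReader(text.splitlines(), delimiter=delimiter)
    cols = reader.fieldnames or []
    for fld in _MANDATORY:
        if mapping[fld] not in cols:
            raise ColumnMappingError(
                f"mandatory column {mapping[fld]!r} (field {fld}) not in {cols}")

    audit = FilterAudit()
    records: list[SpecimenRecord] = []
    for row in reader:
        get = lambda fld: (row.get(mapping[fld]) or "").strip()
        lat_raw, lon_raw = get("lat_raw"), get("lon_raw")
        fmt_col = get("coord_format").upper()
        if fmt_col in CoordFormat.__members__:
            fmt, warn = CoordFormat[fmt_col], ""
        else:
            fmt, warn = _classify_coords(lat_raw, lon_raw)
        datum = get("datum_tag").upper()
        rec = SpecimenRecord(
            accession_id=get("accession_id"),
            source=Source(get("source")) if get("source") in Source.__members__
            else Source.OTHER,
            genus=get("genus"),
            species=get("species"),
            lat_raw=lat_raw,
            lon_raw=lon_raw,
            coord_format=fmt,
            datum_tag=DatumTag[datum] if datum in DatumTag.__members__ else DatumTag.UNKNOWN,
            province_claim=get("province_claim"),
            state_claim=get("state_claim"),
            locality_text=get("locality_text"),
            introduced=get("introduced").lower() in ("1", "true", "yes", "y"),
        )
        if warn:
            audit.log(rec, RuleCode.PARSE_WARNING, warn)
        records.append(rec)
    return records, audit


def write_records(records: list[SpecimenRecord], path) -> None:
    """Write records back out as UTF-8 CSV with the default column names."""
    with open(path, "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(list(DEFAULT_DIALECT.values()))
        for r in records:
            w.writerow([
                r.accession_id, r.source.value, r.genus, r.species, r.lat_raw,
                r.lon_raw, r.coord_format.value, r.datum_tag.value,
                r.province_claim, r.state_claim, r.locality_text,
                "true" if r.introduced else "false",
            ])


def harmonize_taxonomy(records: list[SpecimenRecord],
                       synonym_table: dict[tuple[str, str], tuple[str, str]],
                       ) -> tuple[list[SpecimenRecord], FilterAudit]:
    """Replace each record's (genus, species) by its synonym-table image.

    Unmapped taxa pass through unchanged; every change is logged. The table
    content is user-supplied — this is the mechanism only, not a taxonomy.
    """
    audit = FilterAudit()
    out = []
    for rec in records:
        target = synonym_table.get(rec.taxon)
        if target is not None and target != rec.taxon:
            audit.log(rec, RuleCode.TAXONOMY_UPDATED,
                      f"{rec.genus} {rec.species} -> {target[0]} {target[1]}")
            rec = replace(rec, genus=target[0], species=target[1])
        out.append(rec)
    return out, audit


def _matches_introduced(rec: SpecimenRecord,
                        introduced_list: set[tuple[str, str]]) -> bool:
    return (rec.genus, rec.species) in introduced_list or (rec.genus, "*") in introduced_list


def apply_exclusion_rules(records: list[SpecimenRecord],
                          introduced_list: set[tuple[str, str]] | None = None,
                          ambiguous_genera: set[str] | None = None,
                          ) -> tuple[list[SpecimenRecord], FilterAudit]:
    """Apply the exclusion rules in their fixed order and log every removal.

    Order: (1) missing coordinates; (2) identical duplicates, first kept;
    (3) whole groups sharing an (accession, source) pair across more than
    one taxon; (4) quarter-degree-precision coordinates; (5) matches of the
    introduced/commensal list (genus wildcard ``(genus, "*")`` supported)
    or rows flagged introduced in the source table; (6) records lacking a
    species designation in a genus containing both introduced and natural
    species. Output may be empty; |input| = |output| + removals always.
    """
    introduced_list = introduced_list or set()
    ambiguous_genera = ambiguous_genera or set()
    audit = FilterAudit()

    # (1) missing coordinates
    kept = []
    for rec in records:
        if rec.coord_format is CoordFormat.ABSENT:
            audit.log(rec, RuleCode.MISSING_COORDS)
        else:
            kept.append(rec)

    # (2) identical duplicates: all fields equal, first occurrence kept
    seen: set[SpecimenRecord] = set()
    uniq = []
    for rec in kept:
        if rec in seen:
            audit.log(rec, RuleCode.DUPLICATE, "identical duplicate record")
        else:
            seen.add(rec)
            uniq.append(rec)

    # (3) accession collisions: >1 taxon under one (accession, source);
    # the whole group goes — the discrepancy's source cannot be identified
    taxa_by_key: dict[tuple[str, Source], set[tuple[str, str]]] = {}
    for rec in uniq:
        taxa_by_key.setdefault((rec.accession_id, rec.source), set()).add(rec.taxon)
    kept = []
    for rec in uniq:
        taxa = taxa_by_key[(rec.accession_id, rec.source)]
        if len(taxa) > 1:
            audit.log(rec, RuleCode.ACCESSION_COLLISION,
                      f"{len(taxa)} taxa share accession {rec.accession_id}")
        else:
            kept.append(rec)

    # (4) quarter-degree precision is too coarse for point analyses
    uniq = []
    for rec in kept:
        if rec.coord_format is CoordFormat.QUARTER_DEGREE:
            audit.log(rec, RuleCode.QUARTER_DEGREE)
        else:
            uniq.append(rec)

    # (5) commensal / introduced taxa
    kept = []
    for rec in uniq:
        if rec.introduced or _matches_introduced(rec, introduced_list):
            audit.log(rec, RuleCode.INTRODUCED, f"{rec.genus} {rec.species}".strip())
        else:
            kept.append(rec)

    # (6) genus-only records in genera with both introduced and natural species
    out = []
    for rec in kept:
        if not rec.species and rec.genus in ambiguous_genera:
            audit.log(rec, RuleCode.AMBIGUOUS_GENUS, f"{rec.genus} spp.")
        else:
            out.append(rec)

    return out, audit
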