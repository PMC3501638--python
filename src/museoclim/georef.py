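"""Coordinate standardization, spatial validation and locality building.

Raw museum coordinates are standardized to decimal degrees, then validated
against three polygon layers in a fixed order: the study-area boundary
(points slightly outside are snapped back in, far-outside points are
removed), aquatic features (points falling in rivers/lakes/dams are
displaced to the nearest shore), and administrative units (a record whose
claimed province or state disagrees with its coordinates is snapped into
the claimed unit when close, removed when irreconcilable). Surviving
records are collapsed into unique localities by exact coordinate equality
at six decimal places.

No geodetic datum transformation is performed: the residual offset between
the datums seen in these collections (tens of metres in longitude, up to
~300 m in latitude) is accepted and the datum tag is carried through for
transparency.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import NamedTuple, Sequence

from shapely.geometry import Point
from shapely.geometry.base import BaseGeometry

from . import geomutil
from .coords import parse_angle
from .records_qc import AuditEvent, CoordFormat, FilterAudit, RuleCode, SpecimenRecord

DEFAULT_SNAP_M = 200.0


class GeoPoint(NamedTuple):
    """A standardized position in decimal degrees (southern latitudes negative)."""

    lat: float
    lon: float


class PlacementStatus(str, Enum):
    INSIDE = "INSIDE"
    SNAPPED = "SNAPPED"
    REMOVED = "REMOVED"


class AdminStatus(str, Enum):
    CONSISTENT = "CONSISTENT"
    CORRECTED = "CORRECTED"
    UNRESOLVED = "UNRESOLVED"
    NO_CLAIM = "NO_CLAIM"


class AdminLevel(str, Enum):
    STATE = "STATE"
    PROVINCE = "PROVINCE"


@dataclass(frozen=True)
class AdminUnit:
    name: str
    level: AdminLevel
    polygon: BaseGeometry


@dataclass
class StudyArea:
    """Study-area boundary plus aquatic-feature and administrative layers."""

    boundary: BaseGeometry
    aquatic: list[BaseGeometry] = field(default_factory=list)
    admin_units: list[AdminUnit] = field(default_factory=list)

    def admin_by_name(self, name: str) -> AdminUnit | None:
        low = name.strip().lower()
        for unit in self.admin_units:
            if unit.name.lower() == low:
                return unit
        return None


@dataclass(frozen=True)
class Locality:
    """A unique standardized coordinate pair aggregating one or more records."""

    locality_id: int
    point: GeoPoint
    record_refs: tuple[tuple[str, str], ...]

    @property
    def specimen_count(self) -> int:
        return len(self.record_refs)


class CoordinateError(ValueError):
    """A record's coordinate strings could not be standardized."""


def standardize_coordinates(record: SpecimenRecord) -> GeoPoint:
    """Convert a record's raw coordinate strings to decimal degrees.

    Accepts DECIMAL and DMS reporting formats; values are rounded to six
    decimal places (≈0.11 m), which also defines locality identity.
    """
    if record.coord_format not in (CoordFormat.DECIMAL, CoordFormat.DMS):
        raise CoordinateError(
            f"record {record.accession_id}/{record.source.value}: "
            f"coord_format {record.coord_format.value} cannot be standardized")
    try:
        lat = parse_angle(record.lat_raw)
        lon = parse_angle(record.lon_raw)
    except ValueError as err:
        raise CoordinateError(
            f"record {record.accession_id}/{record.source.value}: {err}") from err
    if not (-90.0 <= lat <= 90.0 and -180.0 <= lon <= 180.0):
        raise CoordinateError(
            f"record {record.accession_id}/{record.source.value}: "
            f"({lat}, {lon}) out of range")
    return GeoPoint(round(lat, 6), round(lon, 6))


def distance_m(a: GeoPoint, b: GeoPoint) -> float:
    """Great-circle distance in metres (haversine, R = 6 371 000 m)."""
    return geomutil.haversine_m(a.lat, a.lon, b.lat, b.lon)


def validate_against_area(point: GeoPoint, area: StudyArea,
                          max_snap_m: float = DEFAULT_SNAP_M,
                          ) -> tuple[PlacementStatus, GeoPoint | None]:
    """Check a point against the study-area boundary.

    Inside → INSIDE; outside but within ``max_snap_m`` of the boundary →
    SNAPPED to the nearest boundary point, nudged 1e-6° into the interior
    (the corrected point is guaranteed to test inside); farther out →
    REMOVED (irreconcilable provenance).
    """
    if area.boundary is None or area.boundary.is_empty:
        raise ValueError("study area boundary is empty")
    pt = Point(point.lon, point.lat)
    if area.boundary.covers(pt):
        return PlacementStatus.INSIDE, point
    slon, slat, dist = geomutil.nearest_point_on(area.boundary, point.lon, point.lat)
    if dist > max_snap_m:
        return PlacementStatus.REMOVED, None
    clon, clat = geomutil.nudge_inside(point.lon, point.lat, slon, slat, area.boundary)
    return PlacementStatus.SNAPPED, GeoPoint(round(clat, 6), round(clon, 6))


def displace_from_water(point: GeoPoint, aquatic: Sequence[BaseGeometry],
                        max_snap_m: float = DEFAULT_SNAP_M,
                        ) -> tuple[PlacementStatus, GeoPoint | None]:
    """Move a point out of any aquatic polygon it falls in.

    Same contract as :func:`validate_against_area` but inverted: points on
    land pass unchanged (INSIDE); points in water within ``max_snap_m`` of
    the shore are displaced to the nearest exterior point (SNAPPED); points
    farther from shore are REMOVED.
    """
    cur = point
    for _ in range(len(aquatic) + 1):
        wet = [g for g in aquatic if g.covers(Point(cur.lon, cur.lat))]
        if not wet:
            return (PlacementStatus.INSIDE, point) if cur == point \
                else (PlacementStatus.SNAPPED, cur)
        poly = wet[0]
        slon, slat, dist = geomutil.nearest_point_on(poly.boundary, cur.lon, cur.lat)
        if dist > max_snap_m:
            return PlacementStatus.REMOVED, None
        clon, clat = geomutil.nudge_outside(cur.lon, cur.lat, slon, slat, poly)
        cur = GeoPoint(round(clat, 6), round(clon, 6))
    return PlacementStatus.REMOVED, None


def check_admin_consistency(point: GeoPoint, record: SpecimenRecord,
                            area: StudyArea,
                            max_snap_m: float = DEFAULT_SNAP_M,
                            ) -> tuple[AdminStatus, GeoPoint | None]:
    """Compare a record's claimed province/state with the point's position.

    A provincial claim takes precedence over a state claim when both are
    present. An unknown claimed name is a configuration warning treated as
    NO_CLAIM. A mismatched claim within ``max_snap_m`` of the claimed unit
    is CORRECTED (snapped inside it); farther away it is UNRESOLVED and the
    caller removes the record.
    """
    claim = record.province_claim or record.state_claim
    if not claim:
        return AdminStatus.NO_CLAIM, point
    unit = area.admin_by_name(claim)
    if unit is None:
        return AdminStatus.NO_CLAIM, point
    pt = Point(point.lon, point.lat)
    if unit.polygon.covers(pt):
        return AdminStatus.CONSISTENT, point
    slon, slat, dist = geomutil.nearest_point_on(unit.polygon, point.lon, point.lat)
    if dist > max_snap_m:
        return AdminStatus.UNRESOLVED, None
    clon, clat = geomutil.nudge_inside(point.lon, point.lat, slon, slat, unit.polygon)
    return AdminStatus.CORRECTED, GeoPoint(round(clat, 6), round(clon, 6))


def georeference(records: Sequence[SpecimenRecord], area: StudyArea,
                 max_snap_m: float = DEFAULT_SNAP_M,
                 ) -> tuple[list[tuple[SpecimenRecord, GeoPoint]], FilterAudit]:
    """Run the full validation chain over standardized records.

    Order: study-area validation → aquatic displacement → administrative
    consistency. Every record ends up exactly once in either the retained
    list (with its final point) or the audit's removal events.
    """
    audit = FilterAudit()
    retained: list[tuple[SpecimenRecord, GeoPoint]] = []
    for rec in records:
        point = standardize_coordinates(rec)
        status, corrected = validate_against_area(point, area, max_snap_m)
        if status is PlacementStatus.REMOVED:
            audit.log(rec, RuleCode.OUTSIDE_AREA_UNRESOLVED,
                      f"({point.lat}, {point.lon}) beyond {max_snap_m} m of boundary")
            continue
        if status is PlacementStatus.SNAPPED:
            audit.log(rec, RuleCode.SNAPPED,
                      f"({point.lat}, {point.lon}) -> ({corrected.lat}, {corrected.lon})")
        point = corrected
        status, corrected = displace_from_water(point, area.aquatic, max_snap_m)
        if status is PlacementStatus.REMOVED:
            audit.log(rec, RuleCode.OUTSIDE_AREA_UNRESOLVED,
                      "mid-water beyond displacement range")
            continue
        if status is PlacementStatus.SNAPPED:
            audit.log(rec, RuleCode.WATER_DISPLACED,
                      f"({point.lat}, {point.lon}) -> ({corrected.lat}, {corrected.lon})")
        point = corrected
        astatus, corrected = check_admin_consistency(point, rec, area, max_snap_m)
        if astatus is AdminStatus.UNRESOLVED:
            audit.log(rec, RuleCode.ADMIN_UNRESOLVED,
                      f"claim {rec.province_claim or rec.state_claim!r} irreconcilable")
            continue
        if astatus is AdminStatus.CORRECTED:
            audit.log(rec, RuleCode.COORD_CORRECTED,
                      f"({point.lat}, {point.lon}) -> ({corrected.lat}, {corrected.lon})")
            point = corrected
        retained.append((rec, point))
    return retained, audit


def build_localities(placed: Sequence[tuple[SpecimenRecord, GeoPoint]]) -> list[Locality]:
    """Collapse placed records into unique localities.

    Identity is exact (lat, lon) equality at 6-decimal rounding; ids are
    assigned in sorted (lat, lon) order, so the result is invariant to
    input row order.
    """
    groups: dict[GeoPoint, list[tuple[str, str]]] = {}
    for rec, pt in placed:
        key = GeoPoint(round(pt.lat, 6), round(pt.lon, 6))
        groups.setdefault(key, []).append((rec.accession_id, rec.source.value))
    return [
        Locality(i + 1, pt, tuple(sorted(groups[pt])))
        for i, pt in enumerate(sorted(groups, key=lambda p: (p.lat, p.lon)))
    ]


def taxon_locality_table(placed: Sequence[tuple[SpecimenRecord, GeoPoint]],
                         localities: Sequence[Locality],
                         ) -> list[tuple[str, int, GeoPoint, int]]:
    """Group placed records into (taxon, locality_id, point, specimen_count) rows.

    A locality hosting several genera yields one row per genus; specimen
    counts are per genus at that locality. Taxon identity is the genus, the
    lowest level reliably identifiable from skeletal material.
    """
    loc_by_point = {loc.point: loc for loc in localities}
    counts: dict[tuple[str, int], int] = {}
    points: dict[int, GeoPoint] = {}
    for rec, pt in placed:
        key = GeoPoint(round(pt.lat, 6), round(pt.lon, 6))
        loc = loc_by_point[key]
        counts[(rec.genus, loc.locality_id)] = counts.get((rec.genus, loc.locality_id), 0) + 1
        points[loc.locality_id] = loc.point
    return [(taxon, loc_id, points[loc_id], n)
            for (taxon, loc_id), n in sorted(counts.items())]


# ---------------------------------------------------------------------------
# study-area GeoJSON plumbing

def save_study_area(area: StudyArea, boundary_path, water_path, admin_path) -> None:
    geomutil.write_geojson(boundary_path, [(area.boundary, {"role": "study_area"})])
    geomutil.write_geojson(water_path,
                           [(g, {"role": "aquatic"}) for g in area.aquatic])
    geomutil.write_geojson(admin_path, [
        (u.polygon, {"name": u.name, "level": u.level.value}) for u in area.admin_units
    ])


def load_study_area(boundary_path, water_path=None, admin_path=None) -> StudyArea:
    """Assemble a StudyArea from GeoJSON layers (water/admin optional)."""
    from shapely.ops import unary_union

    boundary = unary_union([g for g, _ in geomutil.read_geojson(boundary_path)])
    aquatic = ([g for g, _ in geomutil.read_geojson(water_path)]
               if water_path else [])
    admin = []
    if admin_path:
        for g, props in geomutil.read_geojson(admin_path):
            admin.append(AdminUnit(str(props.get("name", "")),
                                   AdminLevel(props.get("level", "PROVINCE")), g))
    return StudyArea(boundary=boundary, aquatic=aquatic, admin_units=admin)
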