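"""Nested vegetation overlay and occupancy quantification.

The vegetation model is a three-level nested hierarchy — landscape-scale
vegetation units nest in bioregions, bioregions in biomes — with one
twist: azonal units (riparian, wetland and similar azonal vegetation
whose hydrogeology overrides the surrounding climate-zonal vegetation)
roll up to a separate "Azonal" biome regardless of where they are
embedded, giving nine zonal biomes plus Azonal.

Occupancy of each class by each taxon is quantified two ways: by number
of unique localities (each collecting site counts once) and by number of
specimens (sites weighted by how many specimens were taken there). The
two weightings disagree when collecting effort was uneven — the
collector-bias diagnostic — and their congruence is summarized here.

Coarse-scale cartographic products dissolve small polygons into their
neighbours (biome polygons under 2000 ha, bioregion polygons under
600 ha). Querying occupancy against such a dissolved layer instead of the
full-resolution units mislabels any locality inside a dissolved
inclusion; :func:`dissolve_small_polygons` reproduces the dissolution and
:func:`compare_query_levels` measures the resulting discordance.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Iterable, NamedTuple, Sequence

import pandas as pd
from shapely import STRtree
from shapely.geometry import Point
from shapely.geometry.base import BaseGeometry
from shapely.ops import unary_union

from . import geomutil
from .georef import GeoPoint

AZONAL_BIOME_ID = "Azonal"

BIOME_MIN_HA = 2000.0
BIOREGION_MIN_HA = 600.0


class Level(str, Enum):
    BIOME = "BIOME"
    BIOREGION = "BIOREGION"
    VEG_UNIT = "VEG_UNIT"


class Weighting(str, Enum):
    LOCALITY = "LOCALITY"
    SPECIMEN = "SPECIMEN"


class UncoveredPointError(ValueError):
    """A point lies in no vegetation unit polygon."""

    def __init__(self, point: GeoPoint):
        self.point = point
        super().__init__(f"point ({point.lat}, {point.lon}) is outside all vegetation units")


class MapIntegrityError(ValueError):
    """A unit or bioregion references a parent that does not exist."""


@dataclass(frozen=True)
class VegUnit:
    unit_id: str
    name: str
    polygon: BaseGeometry
    area_ha: float
    bioregion_id: str
    azonal: bool = False


@dataclass
class HabitatMap:
    """Three-level nested vegetation hierarchy with an azonal override.

    ``biome_layer`` / ``bioregion_layer`` hold dissolved coarse-scale
    polygon layers — lists of (class_id, polygon) — once
    :func:`dissolve_small_polygons` has been run.
    """

    units: list[VegUnit]
    bioregions: dict[str, tuple[str, str]]  # bioregion_id -> (name, biome_id)
    biomes: dict[str, str]                  # biome_id -> name
    biome_layer: list[tuple[str, BaseGeometry]] | None = None
    bioregion_layer: list[tuple[str, BaseGeometry]] | None = None
    _tree: STRtree | None = field(default=None, repr=False, compare=False)

    def unit(self, unit_id: str) -> VegUnit:
        for u in self.units:
            if u.unit_id == unit_id:
                return u
        raise KeyError(unit_id)

    def tree(self) -> STRtree:
        if self._tree is None:
            object.__setattr__(self, "_tree", STRtree([u.polygon for u in self.units]))
        return self._tree

    def validate(self, overlap_tol_deg2: float = 1e-9) -> None:
        """Check referential integrity, positive areas and unit disjointness."""
        for u in self.units:
            if u.bioregion_id not in self.bioregions:
                raise MapIntegrityError(f"unit {u.unit_id}: unknown bioregion {u.bioregion_id}")
            if not u.area_ha > 0:
                raise MapIntegrityError(f"unit {u.unit_id}: non-positive area")
        for brid, (_, biome_id) in self.bioregions.items():
            if biome_id not in self.biomes:
                raise MapIntegrityError(f"bioregion {brid}: unknown biome {biome_id}")
        tree = STRtree([u.polygon for u in self.units])
        for i, u in enumerate(self.units):
            for j in tree.query(u.polygon, predicate="intersects"):
                if j <= i:
                    continue
                inter = u.polygon.intersection(self.units[j].polygon)
                if inter.area > overlap_tol_deg2:
                    raise MapIntegrityError(
                        f"units {u.unit_id} and {self.units[j].unit_id} overlap "
                        f"by {inter.area:.3g} deg^2")

    # ----- GeoJSON round trip ------------------------------------------
    def to_geojson(self, path) -> None:
        feats = []
        for u in self.units:
            br_name, biome_id = self.bioregions[u.bioregion_id]
            feats.append((u.polygon, {
                "unit_id": u.unit_id, "name": u.name, "area_ha": u.area_ha,
                "bioregion": u.bioregion_id, "bioregion_name": br_name,
                "biome": biome_id, "biome_name": self.biomes[biome_id],
                "azonal": u.azonal,
            }))
        geomutil.write_geojson(path, feats)

    @classmethod
    def from_geojson(cls, path) -> "HabitatMap":
        units, bioregions, biomes = [], {}, {}
        for geom, props in geomutil.read_geojson(path):
            area = props.get("area_ha") or geomutil.polygon_area_ha(geom)
            units.append(VegUnit(
                unit_id=str(props["unit_id"]), name=str(props.get("name", props["unit_id"])),
                polygon=geom, area_ha=float(area),
                bioregion_id=str(props["bioregion"]), azonal=bool(props.get("azonal", False))))
            bioregions[str(props["bioregion"])] = (
                str(props.get("bioregion_name", props["bioregion"])), str(props["biome"]))
            biomes[str(props["biome"])] = str(props.get("biome_name", props["biome"]))
        biomes.setdefault(AZONAL_BIOME_ID, AZONAL_BIOME_ID)
        return cls(units=units, bioregions=bioregions, biomes=biomes)


class Assignment(NamedTuple):
    """One locality of one taxon placed in a vegetation unit."""

    taxon: str
    locality_id: int
    specimen_count: int
    unit_id: str


@dataclass
class OccupancyTable:
    """Per-taxon percent occupation of habitat classes at one level.

    ``cells`` holds only nonzero classes (rendered as dashes in the wide
    tables); per taxon the percents sum to 100 up to rounding.
    """

    level: Level
    weighting: Weighting
    cells: dict[tuple[str, str], tuple[int, float]]
    totals: dict[str, int]

    def percent(self, taxon: str, class_id: str) -> float:
        return self.cells.get((taxon, class_id), (0, 0.0))[1]

    def taxa(self) -> list[str]:
        return sorted(self.totals)

    def classes(self) -> list[str]:
        return sorted({c for (_, c) in self.cells})

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"taxon": t, "class_id": c, "level": self.level.value,
             "weighting": self.weighting.value, "count": n, "percent": p}
            for (t, c), (n, p) in sorted(self.cells.items())
        ]
        return pd.DataFrame(rows, columns=["taxon", "class_id", "level",
                                           "weighting", "count", "percent"])


def assign_vegetation_unit(point: GeoPoint, habitat_map: HabitatMap) -> str:
    """Return the unit containing the point (boundary-inclusive).

    A point exactly on a shared edge is assigned to the covering candidate
    with the lexicographically smallest unit_id — a documented tie-break
    that makes assignment independent of polygon ordering.
    """
    pt = Point(point.lon, point.lat)
    idx = habitat_map.tree().query(pt, predicate="covered_by")
    if len(idx) == 0:
        raise UncoveredPointError(point)
    return min(habitat_map.units[i].unit_id for i in idx)


def rollup(unit_id: str, habitat_map: HabitatMap) -> tuple[str, str]:
    """Map a vegetation unit to its (bioregion_id, biome_id).

    An azonal unit keeps its bioregion but reports the "Azonal" biome,
    overriding the zonal biome it is embedded in.
    """
    unit = habitat_map.unit(unit_id)
    if unit.bioregion_id not in habitat_map.bioregions:
        raise MapIntegrityError(f"unit {unit_id}: unknown bioregion {unit.bioregion_id}")
    _, biome_id = habitat_map.bioregions[unit.bioregion_id]
    if biome_id not in habitat_map.biomes:
        raise MapIntegrityError(f"bioregion {unit.bioregion_id}: unknown biome {biome_id}")
    if unit.azonal:
        return unit.bioregion_id, AZONAL_BIOME_ID
    return unit.bioregion_id, biome_id


def _class_of(unit_id: str, habitat_map: HabitatMap, level: Level) -> str:
    if level is Level.VEG_UNIT:
        return unit_id
    bioregion_id, biome_id = rollup(unit_id, habitat_map)
    return bioregion_id if level is Level.BIOREGION else biome_id


def occupancy_table(assignments: Sequence[Assignment], habitat_map: HabitatMap,
                    level: Level, weighting: Weighting) -> OccupancyTable:
    """Tabulate percent occupation per taxon at one hierarchy level.

    LOCALITY weighting counts each locality once; SPECIMEN weighting counts
    each locality's specimen total. Classes with zero count are omitted.
    """
    if not isinstance(level, Level):
        raise ValueError(f"unknown level: {level}")
    if not assignments:
        raise ValueError("assignments must be nonempty")
    df = pd.DataFrame(assignments, columns=["taxon", "locality_id",
                                            "specimen_count", "unit_id"])
    df["class_id"] = [_class_of(u, habitat_map, level) for u in df["unit_id"]]
    df["w"] = 1 if weighting is Weighting.LOCALITY else df["specimen_count"]
    counts = df.groupby(["taxon", "class_id"], sort=True)["w"].sum()
    totals = counts.groupby("taxon").sum()
    cells = {
        (taxon, cls): (int(n), 100.0 * n / totals[taxon])
        for (taxon, cls), n in counts.items() if n > 0
    }
    return OccupancyTable(level, weighting, cells, {t: int(n) for t, n in totals.items()})


def congruence(table_locality: OccupancyTable, table_specimen: OccupancyTable,
               flag_threshold: float = 10.0,
               ) -> tuple[float, float, list[str]]:
    """Locality- vs specimen-weighted agreement (collector-bias diagnostic).

    Absolute percent differences are taken over the union of nonzero cells
    per taxon (a cell absent from one table contributes its full percent);
    returns their mean and median, plus the taxa with any single-cell
    difference above ``flag_threshold`` percentage points.
    """
    if table_locality.level is not table_specimen.level:
        raise ValueError("occupancy tables are at different hierarchy levels")
    diffs: list[float] = []
    flagged: set[str] = set()
    taxa = sorted(set(table_locality.totals) | set(table_specimen.totals))
    for taxon in taxa:
        classes = {c for (t, c) in table_locality.cells if t == taxon}
        classes |= {c for (t, c) in table_specimen.cells if t == taxon}
        for cls in sorted(classes):
            d = abs(table_locality.percent(taxon, cls) - table_specimen.percent(taxon, cls))
            diffs.append(d)
            if d > flag_threshold:
                flagged.add(taxon)
    if not diffs:
        return 0.0, 0.0, []
    s = pd.Series(diffs)
    return float(s.mean()), float(s.median()), sorted(flagged)


# ---------------------------------------------------------------------------
# Dissolution of small polygons (coarse-scale cartography artifact)

def _connected_polygons(geom: BaseGeometry) -> list[BaseGeometry]:
    if geom.is_empty:
        return []
    if geom.geom_type == "Polygon":
        return [geom]
    return [g for g in geom.geoms if g.geom_type == "Polygon" and not g.is_empty]


def _build_layer(habitat_map: HabitatMap, level: Level) -> list[tuple[str, BaseGeometry]]:
    by_class: dict[str, list[BaseGeometry]] = {}
    for u in habitat_map.units:
        by_class.setdefault(_class_of(u.unit_id, habitat_map, level), []).append(u.polygon)
    layer = []
    for cls in sorted(by_class):
        for poly in _connected_polygons(unary_union(by_class[cls])):
            layer.append((cls, poly))
    return layer


def _dissolve_layer(layer: list[tuple[str, BaseGeometry]], min_ha: float,
                    ) -> list[tuple[str, BaseGeometry]]:
    polys = [{"cls": c, "geom": g, "ha": geomutil.polygon_area_ha(g)} for c, g in layer]
    while True:
        small = [p for p in polys if p["ha"] < min_ha]
        if not small:
            break
        small.sort(key=lambda p: p["ha"])  # smallest-first for determinism
        victim = small[0]
        best, best_len = None, 0.0
        for cand in polys:
            if cand is victim:
                continue
            shared = victim["geom"].intersection(cand["geom"])
            if shared.length > best_len:
                best, best_len = cand, shared.length
        if best is None:
            warnings.warn(
                f"sub-threshold polygon ({victim['ha']:.0f} ha, class {victim['cls']}) "
                "has no neighbour; left as-is")
            victim["ha"] = min_ha  # stop revisiting
            continue
        best["geom"] = unary_union([best["geom"], victim["geom"]])
        best["ha"] = geomutil.polygon_area_ha(best["geom"])
        polys.remove(victim)
    return [(p["cls"], p["geom"]) for p in polys]


def dissolve_small_polygons(habitat_map: HabitatMap,
                            biome_min_ha: float = BIOME_MIN_HA,
                            bioregion_min_ha: float = BIOREGION_MIN_HA) -> HabitatMap:
    """Produce coarse-scale biome and bioregion layers with small polygons merged.

    Each connected polygon strictly below its level's threshold is merged
    into the same-level neighbour sharing the longest boundary, iterating
    smallest-first until none remain. Total area is conserved. A polygon of
    exactly the threshold area is retained. The returned map carries the
    dissolved layers alongside the untouched unit hierarchy.
    """
    biome_layer = _dissolve_layer(_build_layer(habitat_map, Level.BIOME), biome_min_ha)
    bioregion_layer = _dissolve_layer(_build_layer(habitat_map, Level.BIOREGION),
                                      bioregion_min_ha)
    return replace(habitat_map, biome_layer=biome_layer,
                   bioregion_layer=bioregion_layer, _tree=None)


def lookup_layer(point: GeoPoint, layer: Iterable[tuple[str, BaseGeometry]]) -> str | None:
    """Class of the layer polygon covering the point (smallest class id on ties)."""
    pt = Point(point.lon, point.lat)
    hits = sorted(cls for cls, geom in layer if geom.covers(pt))
    return hits[0] if hits else None


def compare_query_levels(localities: Sequence[GeoPoint],
                         habitat_map: HabitatMap) -> float:
    """Fraction of localities whose biome differs between query routes.

    Route one rolls up from the full-resolution vegetation unit; route two
    reads the dissolved biome layer directly. Any locality inside a
    dissolved sub-threshold inclusion is discordant.
    """
    if habitat_map.biome_layer is None:
        raise ValueError("run dissolve_small_polygons first: no dissolved biome layer")
    if not localities:
        return 0.0
    discordant = 0
    for pt in localities:
        _, biome_fine = rollup(assign_vegetation_unit(pt, habitat_map), habitat_map)
        biome_coarse = lookup_layer(pt, habitat_map.biome_layer)
        if biome_coarse != biome_fine:
            discordant += 1
    return discordant / len(localities)
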