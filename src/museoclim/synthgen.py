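"""Synthetic study areas, vegetation mosaics, climate gradients and
error-injected museum collections.

Real inputs to this pipeline — museum databases and a licensed national
vegetation map — cannot be bundled, so every pipeline stage is exercised
against generated stand-ins with a full truth bundle:

* a convex study area partitioned by nested Voronoi tessellation into
  biomes → bioregions → vegetation units, optionally with azonal units
  and with sub-2000-ha alien-biome inclusions (to provoke the
  dissolution artifact), plus small lakes and a two-province admin layer;
* six climate surfaces, each a linear lat/lon gradient plus optional
  Gaussian noise, with the driest month never wetter than the wettest;
* museum record tables drawn per taxon from a biome-occupancy
  probability vector, with the classic database defects injected at
  configurable rates: blanked coordinates, exact duplicate rows,
  cross-taxon accession collisions, quarter-degree-precision
  coordinates, points displaced just over the study-area boundary,
  points dropped into water, and introduced-taxon rows.

Every injection is recorded in the :class:`TruthBundle`, so QC and
georeferencing can be scored with exact precision/recall, and occupancy
and climate-envelope recovery can be checked against the generating
parameters. One global seed fans out to per-stage child seeds, so stages
are independently reproducible.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
from shapely import STRtree
from shapely.geometry import MultiPoint, Point, Polygon, box
from shapely.geometry.base import BaseGeometry
from shapely.ops import unary_union, voronoi_diagram

from . import geomutil
from .climate import ClimateSurface, Variable, VARIABLES
from .georef import AdminLevel, AdminUnit, GeoPoint, StudyArea
from .habitat import AZONAL_BIOME_ID, HabitatMap, VegUnit
from .records_qc import CoordFormat, DatumTag, Source, SpecimenRecord
from .coords import format_dms

#: thematic biome names for synthetic maps, coarsest first
BIOME_NAMES = ("Savanna", "Grassland", "Fynbos", "Nama-Karoo", "Succulent Karoo",
               "Albany Thicket", "Forests", "IOCB", "Desert")

INTRODUCED_TAXA = (("Rattus", "rattus"), ("Rattus", "norvegicus"), ("Mus", "musculus"))


@dataclass
class TaxonSpec:
    """Generating parameters for one synthetic taxon."""

    name: str
    n_localities: int
    specimens: dict = field(default_factory=lambda: {"kind": "poisson", "mean": 3.0})
    class_probs: dict[str, float] = field(default_factory=dict)  # class -> probability

    def check(self) -> None:
        total = sum(self.class_probs.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"taxon {self.name}: class probabilities sum to {total}")


@dataclass
class ScenarioConfig:
    """Study conditions for one synthetic scenario.

    Defaults give a modest three-biome landscape with the defect rates a
    curator would recognize from real digitized collections; set the
    relevant rate to zero to isolate a stage.
    """

    seed: int = 0
    n_biomes: int = 3
    n_bioregions_per_biome: int = 2
    n_units_per_bioregion: int = 2
    azonal_fraction: float = 0.0
    small_polygon_fraction: float = 0.0
    inclusion_ha: float = 1500.0         # area of planted biome inclusions (< 2000)
    center_lon: float = 26.0
    center_lat: float = -28.0
    radius_deg: float = 1.8
    n_lakes: int = 2
    lake_radius_m: float = 150.0
    taxa: list[TaxonSpec] = field(default_factory=list)
    error_rates: dict[str, float] = field(default_factory=lambda: {
        "missing_coords": 0.05, "duplicate": 0.05, "accession_collision": 0.02,
        "quarter_degree": 0.05, "boundary_overshoot": 0.0, "water_point": 0.0,
        "introduced": 0.0,
    })
    boundary_overshoot_m: float = 200.0  # max planted overshoot distance
    dms_fraction: float = 0.3            # share of records reported in DMS notation
    cellsize: float = 0.05
    climate: dict[str, dict[str, float]] = field(default_factory=lambda: {
        "MAT":   {"base": 18.0, "slope_lat": 0.7, "slope_lon": 0.2, "noise_sd": 0.3},
        "MxTWM": {"base": 29.0, "slope_lat": 0.5, "slope_lon": 0.3, "noise_sd": 0.3},
        "MnTCM": {"base": 4.0,  "slope_lat": 0.8, "slope_lon": 0.1, "noise_sd": 0.3},
        "MAP":   {"base": 600.0, "slope_lat": 40.0, "slope_lon": 60.0, "noise_sd": 20.0},
        "PWM":   {"base": 110.0, "slope_lat": 8.0, "slope_lon": 12.0, "noise_sd": 5.0},
        "PDM":   {"base": 10.0,  "slope_lat": 1.0, "slope_lon": 2.0, "noise_sd": 1.0},
    })

    def check(self) -> None:
        for k, v in self.error_rates.items():
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"error rate {k}={v} outside [0, 1]")
        if not 0.0 <= self.azonal_fraction <= 1.0:
            raise ValueError("azonal_fraction outside [0, 1]")
        if not 0.0 <= self.small_polygon_fraction <= 1.0:
            raise ValueError("small_polygon_fraction outside [0, 1]")
        for t in self.taxa:
            t.check()

    def child_seeds(self) -> dict[str, int]:
        """Stage seeds fanned out from the global seed."""
        ss = np.random.SeedSequence(self.seed)
        kids = ss.spawn(3)
        return {name: int(k.generate_state(1)[0] % (2**31))
                for name, k in zip(("landscape", "climate", "collections"), kids)}


def default_taxa(biomes: Sequence[str]) -> list[TaxonSpec]:
    """Three taxa with contrasting occupancy over the first three biomes."""
    b = list(biomes)[:3]
    return [
        TaxonSpec("Synthomys", 500, class_probs={b[0]: 0.6, b[1]: 0.3, b[2]: 0.1}),
        TaxonSpec("Fictomys", 500, class_probs={b[0]: 0.1, b[1]: 0.6, b[2]: 0.3}),
        TaxonSpec("Pseudotomys", 500, class_probs={b[0]: 0.3, b[1]: 0.1, b[2]: 0.6}),
    ]


@dataclass
class TruthRecord:
    accession_id: str
    source: str
    taxon: str
    true_lat: float
    true_lon: float
    unit_id: str
    bioregion_id: str
    biome_id: str
    locality_key: int
    error: str = ""       # one of the injection kinds, or "" for clean
    detail: str = ""


@dataclass
class TruthBundle:
    """Everything a test needs to score the pipeline against the generator."""

    records: list[TruthRecord] = field(default_factory=list)
    occupancy: dict[str, dict[str, float]] = field(default_factory=dict)
    climate_params: dict[str, dict[str, float]] = field(default_factory=dict)
    seeds: dict[str, int] = field(default_factory=dict)

    def labelled(self, kind: str) -> list[tuple[str, str]]:
        """(accession_id, source) pairs carrying one injected error kind."""
        return [(r.accession_id, r.source) for r in self.records if r.error == kind]

    def to_json(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump({
                "records": [asdict(r) for r in self.records],
                "occupancy": self.occupancy,
                "climate_params": self.climate_params,
                "seeds": self.seeds,
            }, fh, indent=1, sort_keys=True)
            fh.write("\n")


class GenerationError(RuntimeError):
    """The requested scenario is geometrically infeasible."""


# ---------------------------------------------------------------------------
# landscape

def _sample_point_in(rng: np.random.Generator, geom: BaseGeometry,
                     max_tries: int = 10_000) -> Point:
    minx, miny, maxx, maxy = geom.bounds
    for _ in range(max_tries):
        p = Point(rng.uniform(minx, maxx), rng.uniform(miny, maxy))
        if geom.covers(p):
            return p
    raise GenerationError(f"could not sample a point inside geometry {geom.bounds}")


def _voronoi_partition(rng: np.random.Generator, parent: BaseGeometry,
                       n: int) -> list[BaseGeometry]:
    """Partition *parent* into n cells by nearest-site Voronoi tessellation."""
    if n <= 1:
        return [parent]
    sites = [_sample_point_in(rng, parent) for _ in range(n)]
    cells = voronoi_diagram(MultiPoint(sites), envelope=parent.buffer(1.0))
    out: list[BaseGeometry] = [None] * n
    for cell in cells.geoms:
        for i, site in enumerate(sites):
            if cell.covers(site):
                piece = cell.intersection(parent)
                out[i] = piece if out[i] is None else unary_union([out[i], piece])
                break
    pieces = []
    for i, g in enumerate(out):
        if g is None or g.is_empty:
            raise GenerationError("degenerate Voronoi cell; change the seed")
        # keep only polygonal parts
        if g.geom_type == "GeometryCollection":
            g = unary_union([p for p in g.geoms if p.geom_type.endswith("Polygon")])
        pieces.append(g)
    return pieces


def _metric_disc(lon: float, lat: float, radius_m: float, quad_segs: int = 16) -> Polygon:
    """A circle of metric radius about (lon, lat), built in a local frame."""
    to_xy, to_lonlat = geomutil.local_projector(lat, lon)
    x, y = to_xy(lon, lat)
    disc = Point(x, y).buffer(radius_m, quad_segs=quad_segs)
    from shapely.ops import transform
    return transform(to_lonlat, disc)


def generate_landscape(config: ScenarioConfig) -> tuple[StudyArea, HabitatMap]:
    """Generate the study area and its nested vegetation mosaic.

    The study area is a convex 24-gon; biome, bioregion and unit polygons
    come from nested seeded Voronoi tessellation, giving irregular but
    exactly non-overlapping nesting. Requested fractions of units are
    flagged azonal and of sub-threshold alien-biome inclusions planted.
    """
    config.check()
    rng = np.random.default_rng(config.child_seeds()["landscape"])

    # convex study area: a regular 24-gon, slightly irregularized
    angles = np.linspace(0.0, 2.0 * math.pi, 25)[:-1]
    radii = config.radius_deg * (1.0 + 0.1 * rng.uniform(-1, 1, size=angles.size))
    # convexity: use the convex hull of the jittered ring
    ring = [(config.center_lon + r * math.cos(a),
             config.center_lat + r * math.sin(a)) for a, r in zip(angles, radii)]
    boundary = Polygon(ring).convex_hull

    n_b = config.n_biomes
    if n_b > len(BIOME_NAMES):
        raise GenerationError(f"at most {len(BIOME_NAMES)} biomes supported")
    biome_polys = _voronoi_partition(rng, boundary, n_b)
    biomes = {BIOME_NAMES[i]: BIOME_NAMES[i] for i in range(n_b)}
    biomes[AZONAL_BIOME_ID] = AZONAL_BIOME_ID

    units: list[VegUnit] = []
    bioregions: dict[str, tuple[str, str]] = {}
    uid = 0
    for bi, bpoly in enumerate(biome_polys):
        biome_id = BIOME_NAMES[bi]
        br_polys = _voronoi_partition(rng, bpoly, config.n_bioregions_per_biome)
        for ri, rpoly in enumerate(br_polys):
            br_id = f"{biome_id[:3].upper()}-BR{ri + 1}"
            bioregions[br_id] = (f"{biome_id} bioregion {ri + 1}", biome_id)
            for upoly in _voronoi_partition(rng, rpoly, config.n_units_per_bioregion):
                uid += 1
                units.append(VegUnit(
                    unit_id=f"U{uid:03d}", name=f"Unit {uid}", polygon=upoly,
                    area_ha=geomutil.polygon_area_ha(upoly), bioregion_id=br_id))

    # azonal flags
    n_azonal = int(round(config.azonal_fraction * len(units)))
    if n_azonal:
        for i in rng.choice(len(units), size=n_azonal, replace=False):
            u = units[i]
            units[i] = VegUnit(u.unit_id, u.name, u.polygon, u.area_ha,
                               u.bioregion_id, azonal=True)

    # sub-threshold alien-biome inclusions
    n_inc = int(round(config.small_polygon_fraction * len(units)))
    if n_inc:
        radius_m = math.sqrt(config.inclusion_ha * 1.0e4 / math.pi)
        hosts = sorted(range(len(units)), key=lambda i: -units[i].area_ha)[:n_inc]
        for k, i in enumerate(hosts):
            host = units[i]
            # a disc fully interior to the host
            shrunk = host.polygon.buffer(-3.0 * radius_m / geomutil.M_PER_DEG)
            if shrunk.is_empty:
                raise GenerationError(
                    f"host unit {host.unit_id} too small for a {config.inclusion_ha} ha "
                    "inclusion")
            c = _sample_point_in(rng, shrunk)
            disc = _metric_disc(c.x, c.y, radius_m)
            # the inclusion belongs to a different biome than its surroundings
            host_biome = bioregions[host.bioregion_id][1]
            alien_biome = next(b for b in list(biomes) if b not in
                               (host_biome, AZONAL_BIOME_ID))
            inc_br = f"{alien_biome[:3].upper()}-INC"
            bioregions.setdefault(inc_br, (f"{alien_biome} inclusions", alien_biome))
            carved = host.polygon.difference(disc)
            units[i] = VegUnit(host.unit_id, host.name, carved,
                               geomutil.polygon_area_ha(carved), host.bioregion_id,
                               host.azonal)
            uid += 1
            units.append(VegUnit(f"U{uid:03d}", f"Inclusion {k + 1}", disc,
                                 geomutil.polygon_area_ha(disc), inc_br))

    # aquatic features: small lakes well inside the area
    aquatic = []
    core = boundary.buffer(-0.1)
    for _ in range(config.n_lakes):
        c = _sample_point_in(rng, core)
        aquatic.append(_metric_disc(c.x, c.y, config.lake_radius_m))

    # two provinces split by a meridian through the centroid
    cx = boundary.centroid.x
    minx, miny, maxx, maxy = boundary.bounds
    west = boundary.intersection(box(minx - 1, miny - 1, cx, maxy + 1))
    east = boundary.intersection(box(cx, miny - 1, maxx + 1, maxy + 1))
    admin = [AdminUnit("West Province", AdminLevel.PROVINCE, west),
             AdminUnit("East Province", AdminLevel.PROVINCE, east)]

    area = StudyArea(boundary=boundary, aquatic=aquatic, admin_units=admin)
    hmap = HabitatMap(units=units, bioregions=bioregions, biomes=biomes)
    hmap.validate()
    return area, hmap


# ---------------------------------------------------------------------------
# climate

def generate_climate(config: ScenarioConfig, area: StudyArea,
                     ) -> tuple[dict[Variable, ClimateSurface], dict[str, dict[str, float]]]:
    """Generate the six gridded surfaces over the study area.

    Each variable is base + slope_lat·(lat−lat0) + slope_lon·(lon−lon0)
    plus optional Gaussian noise, evaluated at cell centres; cells outside
    the study area are nodata, precipitation is clipped at zero, and
    PDM ≤ PWM holds cellwise by construction. Returns the surfaces and the
    closed-form truth parameters.
    """
    rng = np.random.default_rng(config.child_seeds()["climate"])
    cs = config.cellsize
    minx, miny, maxx, maxy = area.boundary.bounds
    xll = math.floor(minx / cs) * cs
    yll = math.floor(miny / cs) * cs
    ncols = int(math.ceil((maxx - xll) / cs))
    nrows = int(math.ceil((maxy - yll) / cs))
    lat0, lon0 = area.boundary.centroid.y, area.boundary.centroid.x

    lon_c = xll + (np.arange(ncols) + 0.5) * cs
    lat_c = (yll + nrows * cs) - (np.arange(nrows) + 0.5) * cs  # row 0 = north
    lon_g, lat_g = np.meshgrid(lon_c, lat_c)
    pts = [Point(x, y) for x, y in zip(lon_g.ravel(), lat_g.ravel())]
    inside = np.array([area.boundary.covers(p) for p in pts]).reshape(nrows, ncols)

    surfaces: dict[Variable, ClimateSurface] = {}
    params: dict[str, dict[str, float]] = {}
    fields = {}
    for var in VARIABLES:
        p = config.climate[var.value]
        vals = (p["base"] + p["slope_lat"] * (lat_g - lat0)
                + p["slope_lon"] * (lon_g - lon0))
        if p.get("noise_sd", 0.0) > 0:
            vals = vals + rng.normal(0.0, p["noise_sd"], size=vals.shape)
        if var.units == "mm":
            vals = np.clip(vals, 0.0, None)
        fields[var] = vals
        params[var.value] = {**p, "lat0": lat0, "lon0": lon0, "cellsize": cs}
    # driest month can never be wetter than the wettest month
    fields[Variable.PDM] = np.minimum(fields[Variable.PDM], fields[Variable.PWM])
    for var in VARIABLES:
        vals = np.where(inside, fields[var], np.nan)
        surfaces[var] = ClimateSurface(var, xll, yll, cs, vals)
    return surfaces, params


def closed_form_value(params: dict[str, float], point: GeoPoint,
                      surface: ClimateSurface) -> float:
    """Noiseless expectation of a generated surface at a point's cell centre."""
    row, col = surface.cell_of(point)
    c = surface.cell_center(row, col)
    return (params["base"] + params["slope_lat"] * (c.lat - params["lat0"])
            + params["slope_lon"] * (c.lon - params["lon0"]))


# ---------------------------------------------------------------------------
# collections

def _class_regions(hmap: HabitatMap) -> dict[str, BaseGeometry]:
    """Union of unit polygons per rollup biome class (azonal → 'Azonal')."""
    from .habitat import rollup

    groups: dict[str, list[BaseGeometry]] = {}
    for u in hmap.units:
        _, biome = rollup(u.unit_id, hmap)
        groups.setdefault(biome, []).append(u.polygon)
    return {cls: unary_union(gs) for cls, gs in groups.items()}


def _render_coords(rng: np.random.Generator, lat: float, lon: float,
                   dms_fraction: float) -> tuple[str, str]:
    if rng.uniform() < dms_fraction:
        return format_dms(lat, "N", "S"), format_dms(lon, "E", "W")
    return f"{lat:.6f}", f"{lon:.6f}"


def _qds_center(value: float) -> float:
    """Snap a coordinate to the centre of its quarter-degree cell."""
    sign = -1.0 if value < 0 else 1.0
    a = abs(value)
    return sign * (math.floor(a * 4.0) / 4.0 + 0.125)


def generate_collections(config: ScenarioConfig, area: StudyArea,
                         hmap: HabitatMap,
                         ) -> tuple[list[SpecimenRecord], TruthBundle]:
    """Generate the raw museum table with injected defects and its truth.

    Localities are drawn per taxon from its class-occupancy vector
    (uniformly within the class's polygons, never in water); specimen
    counts per locality follow the configured distribution, one record per
    specimen. Each defect is injected into a disjoint subset of records at
    its configured rate, and every injection is labelled in the truth
    bundle. Record order is shuffled before return.
    """
    config.check()
    rng = np.random.default_rng(config.child_seeds()["collections"])
    taxa = config.taxa or default_taxa([b for b in hmap.biomes if b != AZONAL_BIOME_ID])
    for t in taxa:
        t.check()
    regions = _class_regions(hmap)
    water = unary_union(area.aquatic) if area.aquatic else None
    unit_tree = STRtree([u.polygon for u in hmap.units])

    def locate(lat: float, lon: float) -> tuple[str, str, str]:
        from .habitat import rollup
        idx = unit_tree.query(Point(lon, lat), predicate="covered_by")
        if len(idx) == 0:
            raise GenerationError(f"sampled point ({lat}, {lon}) in no unit")
        unit_id = min(hmap.units[i].unit_id for i in idx)
        br, biome = rollup(unit_id, hmap)
        return unit_id, br, biome

    def province_of(lat: float, lon: float) -> str:
        for unit in area.admin_units:
            if unit.polygon.covers(Point(lon, lat)):
                return unit.name
        return ""

    counters = {Source.DM: 0, Source.NMNH: 0}

    def next_accession(source: Source) -> str:
        counters[source] += 1
        return f"{source.value}-{counters[source]:06d}"

    records: list[SpecimenRecord] = []
    truths: list[TruthRecord] = []
    loc_key = 0
    for spec in taxa:
        classes = sorted(spec.class_probs)
        probs = np.array([spec.class_probs[c] for c in classes])
        for cls in classes:
            if cls not in regions:
                raise GenerationError(f"taxon {spec.name}: no units in class {cls!r}")
        draws = rng.choice(len(classes), size=spec.n_localities, p=probs)
        for ci in draws:
            region = regions[classes[ci]]
            while True:
                p = _sample_point_in(rng, region)
                if water is None or not water.covers(p):
                    break
            lat, lon = round(p.y, 6), round(p.x, 6)
            unit_id, br, biome = locate(lat, lon)
            loc_key += 1
            dist = spec.specimens
            if dist.get("kind") == "fixed":
                n_spec = int(dist["value"])
            else:
                n_spec = 1 + int(rng.poisson(max(dist.get("mean", 3.0) - 1.0, 0.0)))
            lat_s, lon_s = _render_coords(rng, lat, lon, config.dms_fraction)
            for _ in range(n_spec):
                source = Source.DM if rng.uniform() < 0.6 else Source.NMNH
                acc = next_accession(source)
                records.append(SpecimenRecord(
                    accession_id=acc, source=source, genus=spec.name,
                    species="typicus", lat_raw=lat_s, lon_raw=lon_s,
                    coord_format=CoordFormat.DECIMAL,
                    datum_tag=(DatumTag.WGS84, DatumTag.HARTEBEESTHOEK94,
                               DatumTag.UNKNOWN)[int(rng.integers(3))],
                    province_claim=province_of(lat, lon),
                    locality_text=f"synthetic locality {loc_key}"))
                truths.append(TruthRecord(acc, source.value, spec.name, lat, lon,
                                          unit_id, br, biome, loc_key))

    # ----- defect injection over disjoint record subsets -------------------
    n = len(records)
    order = list(rng.permutation(n))
    pos = 0

    def take(count: int) -> list[int]:
        nonlocal pos
        got = order[pos:pos + count]
        pos += len(got)
        return got

    rates = config.error_rates

    def replace_rec(i: int, **kw) -> None:
        records[i] = SpecimenRecord(**{**records[i].__dict__, **kw})

    # blanked coordinates
    for i in take(int(round(rates.get("missing_coords", 0.0) * n))):
        replace_rec(i, lat_raw="", lon_raw="", coord_format=CoordFormat.ABSENT)
        truths[i].error = "missing_coords"

    # quarter-degree-precision reporting
    for i in take(int(round(rates.get("quarter_degree", 0.0) * n))):
        qlat, qlon = _qds_center(truths[i].true_lat), _qds_center(truths[i].true_lon)
        replace_rec(i, lat_raw=f"{qlat:.6f}", lon_raw=f"{qlon:.6f}",
                    coord_format=CoordFormat.QUARTER_DEGREE)
        truths[i].error = "quarter_degree"
        truths[i].detail = f"reported at QDS centre ({qlat}, {qlon})"

    # cross-taxon accession collisions: pairs, whole group removed downstream
    n_pairs = int(round(rates.get("accession_collision", 0.0) * n / 2.0))
    for _ in range(n_pairs):
        got = take(2)
        if len(got) < 2:
            break
        a, b = got
        replace_rec(b, accession_id=records[a].accession_id, source=records[a].source)
        if records[b].genus == records[a].genus:
            # force a cross-taxon collision
            replace_rec(b, genus=records[a].genus + "x")
        truths[a].error = truths[b].error = "accession_collision"
        truths[b].accession_id = records[b].accession_id
        truths[b].source = records[b].source.value

    # boundary overshoot: reported point displaced just outside the area
    for i in take(int(round(rates.get("boundary_overshoot", 0.0) * n))):
        lat, lon = truths[i].true_lat, truths[i].true_lon
        slon, slat, _ = geomutil.nearest_point_on(area.boundary.exterior, lon, lat)
        d = rng.uniform(20.0, config.boundary_overshoot_m)
        olon, olat = geomutil.nudge_outside(lon, lat, slon, slat, area.boundary,
                                            step_deg=d / geomutil.M_PER_DEG)
        # truth locality moves to just inside the nearest boundary point
        ilon, ilat = geomutil.nudge_inside(olon, olat, slon, slat, area.boundary)
        ilat, ilon = round(ilat, 6), round(ilon, 6)
        truths[i].true_lat, truths[i].true_lon = ilat, ilon
        u, br, biome = locate(ilat, ilon)
        truths[i].unit_id, truths[i].bioregion_id, truths[i].biome_id = u, br, biome
        replace_rec(i, lat_raw=f"{round(olat, 6):.6f}", lon_raw=f"{round(olon, 6):.6f}",
                    province_claim="")
        truths[i].error = "boundary_overshoot"
        truths[i].detail = f"displaced {d:.1f} m outside"

    # points dropped into water
    if area.aquatic:
        for i in take(int(round(rates.get("water_point", 0.0) * n))):
            lake = area.aquatic[int(rng.integers(len(area.aquatic)))]
            p = _sample_point_in(rng, lake)
            replace_rec(i, lat_raw=f"{round(p.y, 6):.6f}", lon_raw=f"{round(p.x, 6):.6f}",
                        province_claim="")
            truths[i].error = "water_point"

    # exact duplicate rows (append identical copies; the copy is the defect)
    dups = take(int(round(rates.get("duplicate", 0.0) * n)))
    for i in dups:
        records.append(records[i])
        t = truths[i]
        truths.append(TruthRecord(t.accession_id, t.source, t.taxon, t.true_lat,
                                  t.true_lon, t.unit_id, t.bioregion_id, t.biome_id,
                                  t.locality_key, error="duplicate",
                                  detail="appended identical copy"))

    # introduced/commensal rows (extra records, matched by the QC list)
    n_intro = int(round(rates.get("introduced", 0.0) * n))
    for _ in range(n_intro):
        genus, species = INTRODUCED_TAXA[int(rng.integers(len(INTRODUCED_TAXA)))]
        p = _sample_point_in(rng, area.boundary)
        source = Source.DM if rng.uniform() < 0.6 else Source.NMNH
        acc = next_accession(source)
        records.append(SpecimenRecord(
            accession_id=acc, source=source, genus=genus, species=species,
            lat_raw=f"{round(p.y, 6):.6f}", lon_raw=f"{round(p.x, 6):.6f}",
            coord_format=CoordFormat.DECIMAL, introduced=False,
            locality_text="synthetic commensal record"))
        truths.append(TruthRecord(acc, source.value, genus, round(p.y, 6),
                                  round(p.x, 6), "", "", "", -1, error="introduced"))

    # shuffle output row order (museum exports are not sorted either)
    perm = rng.permutation(len(records))
    records = [records[i] for i in perm]
    truths = [truths[i] for i in perm]

    bundle = TruthBundle(
        records=truths,
        occupancy={t.name: dict(t.class_probs) for t in taxa},
        seeds=config.child_seeds(),
    )
    return records, bundle


def generate_scenario(config: ScenarioConfig):
    """Run all three generators; returns (area, map, surfaces, records, truth)."""
    area, hmap = generate_landscape(config)
    surfaces, params = generate_climate(config, area)
    records, truth = generate_collections(config, area, hmap)
    truth.climate_params = params
    return area, hmap, surfaces, records, truth
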