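"""Coordinate standardization, boundary snapping, and locality building."""

import math

import numpy as np
import pytest
from shapely.geometry import Point

from museoclim.coords import format_dms, parse_angle
from museoclim.georef import (
    AdminStatus, CoordinateError, GeoPoint, PlacementStatus,
    build_localities, check_admin_consistency, displace_from_water, distance_m,
    georeference, standardize_coordinates, taxon_locality_table,
    validate_against_area,
)
from museoclim.records_qc import CoordFormat, Source, SpecimenRecord
from museoclim import geomutil
from oracles import law_of_cosines_m


def rec(lat, lon, fmt=CoordFormat.DECIMAL, **kw) -> SpecimenRecord:
    defaults = dict(accession_id="A1", source=Source.DM, genus="Otomys",
                    species="irroratus")
    defaults.update(kw)
    return SpecimenRecord(lat_raw=lat, lon_raw=lon, coord_format=fmt, **defaults)


class TestStandardize:
    def test_dms_conversion_is_exact(self):
        # 26 + 5/60 + 24/3600 = 26.09 exactly
        pt = standardize_coordinates(rec("26°05'24\"S", "28°13'48\"E", CoordFormat.DMS))
        assert pt == GeoPoint(-26.09, 28.23)

    def test_decimal_passthrough(self):
        assert standardize_coordinates(rec("-26.09", "28.23")) == GeoPoint(-26.09, 28.23)

    def test_unparseable_raises_naming_the_record(self):
        with pytest.raises(CoordinateError, match="A1"):
            standardize_coordinates(rec("nonsense", "28.23"))

    def test_absent_format_is_rejected(self):
        with pytest.raises(CoordinateError):
            standardize_coordinates(rec("", "", CoordFormat.ABSENT))

    def test_dms_round_trip(self):
        """DD -> DMS -> DD within 1e-6 over 500 random coordinates."""
        rng = np.random.default_rng(42)
        lats = rng.uniform(-35, -22, 500)
        lons = rng.uniform(16, 33, 500)
        for lat, lon in zip(lats, lons):
            assert abs(parse_angle(format_dms(lat, "N", "S")) - lat) < 1e-6
            assert abs(parse_angle(format_dms(lon, "E", "W")) - lon) < 1e-6


class TestDistance:
    def test_zero_iff_identical(self):
        p = GeoPoint(-26.09, 28.23)
        assert distance_m(p, p) == 0.0
        assert distance_m(p, GeoPoint(-26.09, 28.231)) > 0

    def test_one_degree_of_arc(self):
        # 2*pi*R/360 along the equator
        assert distance_m(GeoPoint(0, 0), GeoPoint(0, 1)) == pytest.approx(111_195, abs=1)

    def test_agrees_with_law_of_cosines_oracle(self):
        rng = np.random.default_rng(7)
        for _ in range(200):
            a = GeoPoint(rng.uniform(-35, -22), rng.uniform(16, 33))
            b = GeoPoint(rng.uniform(-35, -22), rng.uniform(16, 33))
            ours = distance_m(a, b)
            oracle = law_of_cosines_m(a.lat, a.lon, b.lat, b.lon)
            assert ours == pytest.approx(oracle, rel=1e-3, abs=0.5)

    def test_metric_properties_on_random_triples(self):
        rng = np.random.default_rng(11)
        for _ in range(100):
            pts = [GeoPoint(rng.uniform(-35, -22), rng.uniform(16, 33))
                   for _ in range(3)]
            a, b, c = pts
            assert distance_m(a, b) >= 0
            assert distance_m(a, b) == pytest.approx(distance_m(b, a), rel=1e-12)
            assert distance_m(a, c) <= distance_m(a, b) + distance_m(b, c) + 1e-6


class TestAreaValidation:
    def test_interior_point_untouched(self, square_area):
        pt = GeoPoint(-28.0, 25.5)
        status, out = validate_against_area(pt, square_area)
        assert status is PlacementStatus.INSIDE
        assert out == pt

    def test_point_150m_outside_snapped_back(self, square_area):
        # construct a point 150 m due east of the straight eastern edge
        lat = -28.0
        offset_deg = 150.0 / (geomutil.M_PER_DEG * math.cos(math.radians(lat)))
        pt = GeoPoint(lat, 26.0 + offset_deg)
        status, out = validate_against_area(pt, square_area)
        assert status is PlacementStatus.SNAPPED
        assert square_area.boundary.covers(Point(out.lon, out.lat))
        assert 149.0 <= distance_m(pt, out) <= 151.0

    def test_point_5km_outside_removed(self, square_area):
        pt = GeoPoint(-28.0, 26.0 + 5000.0 / geomutil.M_PER_DEG)
        status, out = validate_against_area(pt, square_area)
        assert status is PlacementStatus.REMOVED
        assert out is None

    def test_snapped_points_always_inside(self, square_area):
        """Random overshoots around the whole perimeter land back inside."""
        rng = np.random.default_rng(3)
        ring = square_area.boundary.exterior
        for _ in range(100):
            b = ring.interpolate(rng.uniform(0, ring.length))
            out_lon, out_lat = geomutil.nudge_outside(
                square_area.boundary.centroid.x, square_area.boundary.centroid.y,
                b.x, b.y, square_area.boundary,
                step_deg=rng.uniform(20, 195) / geomutil.M_PER_DEG)
            status, out = validate_against_area(GeoPoint(out_lat, out_lon), square_area)
            assert status is PlacementStatus.SNAPPED
            assert square_area.boundary.covers(Point(out.lon, out.lat))


class TestWaterDisplacement:
    def test_dry_point_passes_unchanged(self, square_area):
        pt = GeoPoint(-27.7, 25.8)
        assert displace_from_water(pt, square_area.aquatic) == (
            PlacementStatus.INSIDE, pt)

    def test_point_inside_lake_moved_to_shore(self, square_area):
        lake = square_area.aquatic[0]
        c = lake.centroid  # 150 m radius: centre is ~150 m from shore
        status, out = displace_from_water(GeoPoint(c.y, c.x), square_area.aquatic)
        assert status is PlacementStatus.SNAPPED
        assert not lake.covers(Point(out.lon, out.lat))
        assert distance_m(GeoPoint(c.y, c.x), out) <= 160.0

    def test_mid_lake_beyond_threshold_removed(self, square_area):
        c = square_area.aquatic[0].centroid
        status, out = displace_from_water(GeoPoint(c.y, c.x), square_area.aquatic,
                                          max_snap_m=50.0)
        assert status is PlacementStatus.REMOVED


class TestAdminConsistency:
    def test_matching_claim_is_consistent(self, square_area):
        r = rec("-28.0", "25.2", province_claim="West Province")
        status, out = check_admin_consistency(GeoPoint(-28.0, 25.2), r, square_area)
        assert status is AdminStatus.CONSISTENT

    def test_claim_near_border_corrected_into_claimed_unit(self, square_area):
        # point 100 m east of the provincial border, claimed West
        lat = -28.0
        lon = 25.5 + 100.0 / (geomutil.M_PER_DEG * math.cos(math.radians(lat)))
        r = rec(str(lat), str(lon), province_claim="West Province")
        status, out = check_admin_consistency(GeoPoint(lat, lon), r, square_area)
        assert status is AdminStatus.CORRECTED
        west = square_area.admin_by_name("West Province").polygon
        assert west.covers(Point(out.lon, out.lat))

    def test_distant_mismatch_unresolved(self, square_area):
        r = rec("-28.0", "25.9", province_claim="West Province")
        status, out = check_admin_consistency(GeoPoint(-28.0, 25.9), r, square_area)
        assert status is AdminStatus.UNRESOLVED
        assert out is None

    def test_unknown_claim_treated_as_no_claim(self, square_area):
        r = rec("-28.0", "25.9", province_claim="Atlantis")
        status, _ = check_admin_consistency(GeoPoint(-28.0, 25.9), r, square_area)
        assert status is AdminStatus.NO_CLAIM


class TestLocalities:
    def make_records(self):
        coords = [("-28.1", "25.2"), ("-28.1", "25.2"), ("-27.9", "25.8"),
                  ("-27.9", "25.8"), ("-28.3", "25.5")]
        return [rec(lat, lon, accession_id=f"A{i}")
                for i, (lat, lon) in enumerate(coords)]

    def test_grouping_and_conservation(self):
        placed = [(r, standardize_coordinates(r)) for r in self.make_records()]
        locs = build_localities(placed)
        assert len(locs) == 3
        assert sum(l.specimen_count for l in locs) == 5

    def test_single_record(self):
        r = rec("-28.0", "25.5")
        locs = build_localities([(r, standardize_coordinates(r))])
        assert len(locs) == 1
        assert locs[0].specimen_count == 1

    def test_ids_invariant_under_permutation(self):
        records = self.make_records()
        placed = [(r, standardize_coordinates(r)) for r in records]
        locs1 = build_localities(placed)
        locs2 = build_localities(list(reversed(placed)))
        assert locs1 == locs2

    def test_taxon_locality_table_splits_by_genus(self):
        records = [rec("-28.1", "25.2", accession_id="A1", genus="Otomys"),
                   rec("-28.1", "25.2", accession_id="A2", genus="Otomys"),
                   rec("-28.1", "25.2", accession_id="A3", genus="Mastomys")]
        placed = [(r, standardize_coordinates(r)) for r in records]
        locs = build_localities(placed)
        table = taxon_locality_table(placed, locs)
        assert len(locs) == 1
        assert sorted((t, n) for t, _, _, n in table) == [("Mastomys", 1), ("Otomys", 2)]


def test_record_conservation_through_module(square_area):
    """Every record is retained-with-point or removed-with-audit-event."""
    records = [
        rec("-28.0", "25.3", accession_id="IN1"),
        rec("-28.0", str(26.0 + 100 / geomutil.M_PER_DEG), accession_id="SNAP1"),
        rec("-28.0", "27.0", accession_id="FAR1"),
        rec("-28.0", "25.9", accession_id="BADCLAIM", province_claim="West Province"),
    ]
    placed, audit = georeference(records, square_area)
    removal_rules = {"OUTSIDE_AREA_UNRESOLVED", "ADMIN_UNRESOLVED"}
    removals = [e for e in audit.events if e.rule_code.value in removal_rules]
    assert len(placed) + len(removals) == len(records)
    assert {e.accession_id for e in removals} == {"FAR1", "BADCLAIM"}
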