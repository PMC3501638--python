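"""Record parsing and the ordered exclusion rules."""

import textwrap

import pytest
from hypothesis import given, strategies as st

from museoclim.records_qc import (
    ColumnMappingError, CoordFormat, RuleCode, Source, SpecimenRecord,
    apply_exclusion_rules, harmonize_taxonomy, read_records, write_records,
)
from oracles import collision_groups


def rec(acc="A1", source=Source.DM, genus="Aethomys", species="chrysophilus",
        lat="-26.09", lon="28.23", fmt=CoordFormat.DECIMAL, **kw) -> SpecimenRecord:
    return SpecimenRecord(accession_id=acc, source=source, genus=genus,
                          species=species, lat_raw=lat, lon_raw=lon,
                          coord_format=fmt, **kw)


class TestReadRecords:
    def test_well_formed_rows_parse_without_warnings(self, tmp_path):
        p = tmp_path / "r.csv"
        p.write_text(textwrap.dedent("""\
            accession_id,source,genus,species,lat,lon
            TM1,DM,Aethomys,chrysophilus,-26.09,28.23
            TM2,DM,Mastomys,coucha,"26°05'24""S","28°13'48""E"
            USNM1,NMNH,Otomys,irroratus,-29.5,30.25
            """))
        records, audit = read_records(p)
        assert len(records) == 3
        assert audit.events == []
        assert records[0].coord_format is CoordFormat.DECIMAL
        assert records[1].coord_format is CoordFormat.DMS
        assert records[2].source is Source.NMNH

    def test_empty_coordinate_cells_yield_absent_format(self, tmp_path):
        p = tmp_path / "r.csv"
        p.write_text("accession_id,source,genus,species,lat,lon\nTM1,DM,Mus,,,\n")
        records, audit = read_records(p)
        assert records[0].coord_format is CoordFormat.ABSENT
        assert audit.events == []  # empty is not malformed

    def test_malformed_coordinates_counted_as_warnings(self, tmp_path):
        rows = ["accession_id,source,genus,species,lat,lon"]
        for i in range(20):
            if i in (3, 11):
                rows.append(f"TM{i},DM,Mus,minutoides,garbage,28.2")
            else:
                rows.append(f"TM{i},DM,Mus,minutoides,-26.{i:02d},28.2")
        p = tmp_path / "r.csv"
        p.write_text("\n".join(rows) + "\n")
        records, audit = read_records(p)
        assert len(records) == 20
        assert audit.count(RuleCode.PARSE_WARNING) == 2
        assert all(r.coord_format is CoordFormat.ABSENT
                   for r in records if r.accession_id in ("TM3", "TM11"))

    def test_quarter_degree_detected_from_cell_centre_fractions(self, tmp_path):
        p = tmp_path / "r.csv"
        p.write_text("accession_id,source,genus,species,lat,lon\n"
                     "TM1,DM,Mus,minutoides,-26.125,28.375\n")
        records, _ = read_records(p)
        assert records[0].coord_format is CoordFormat.QUARTER_DEGREE

    def test_tab_delimited_and_column_mapping(self, tmp_path):
        p = tmp_path / "r.tsv"
        p.write_text("CatNo\tMuseum\tGen\tSp\tLatitude\tLongitude\n"
                     "TM1\tDM\tAethomys\tchrysophilus\t-26.09\t28.23\n")
        dialect = {"accession_id": "CatNo", "source": "Museum", "genus": "Gen",
                   "species": "Sp", "lat_raw": "Latitude", "lon_raw": "Longitude"}
        records, _ = read_records(p, dialect)
        assert records[0].accession_id == "TM1"
        assert records[0].genus == "Aethomys"

    def test_missing_mandatory_column_names_the_column(self, tmp_path):
        p = tmp_path / "r.csv"
        p.write_text("accession_id,source,genus,species,lat\nTM1,DM,Mus,,x\n")
        with pytest.raises(ColumnMappingError, match="lon"):
            read_records(p)

    def test_write_read_round_trip(self, tmp_path):
        records = [rec(acc=f"A{i}") for i in range(5)]
        p = tmp_path / "out.csv"
        write_records(records, p)
        back, _ = read_records(p)
        assert back == records


class TestHarmonizeTaxonomy:
    def test_empty_table_is_identity(self):
        records = [rec(), rec(acc="A2", genus="Mus", species="minutoides")]
        out, audit = harmonize_taxonomy(records, {})
        assert out == records
        assert audit.events == []

    def test_synonym_applied_and_logged(self):
        records = [rec(genus="Tatera", species="brantsii")]
        out, audit = harmonize_taxonomy(
            records, {("Tatera", "brantsii"): ("Gerbilliscus", "brantsii")})
        assert out[0].genus == "Gerbilliscus"
        assert audit.count(RuleCode.TAXONOMY_UPDATED) == 1

    def test_exactly_matching_records_change(self):
        records = [rec(acc=f"M{i}", genus="Tatera", species="brantsii") for i in range(5)]
        records += [rec(acc=f"N{i}", genus="Otomys", species="irroratus") for i in range(7)]
        out, audit = harmonize_taxonomy(
            records, {("Tatera", "brantsii"): ("Gerbilliscus", "brantsii")})
        assert audit.count(RuleCode.TAXONOMY_UPDATED) == 5
        assert sum(r.genus == "Gerbilliscus" for r in out) == 5


class TestExclusionRules:
    def make_mixed_fixture(self):
        """10 records: 2 missing coords, 1 duplicate pair, 1 cross-genus
        accession collision pair, 1 quarter-degree, 4 clean."""
        dup = rec(acc="D1", genus="Mastomys", species="coucha")
        return [
            rec(acc="M1", lat="", lon="", fmt=CoordFormat.ABSENT),
            rec(acc="M2", lat="", lon="", fmt=CoordFormat.ABSENT),
            dup, dup,
            rec(acc="C1", genus="Gerbilliscus", species="leucogaster"),
            rec(acc="C1", genus="Aethomys", species="ineptus"),
            rec(acc="Q1", lat="-26.125", lon="28.375", fmt=CoordFormat.QUARTER_DEGREE),
            rec(acc="K1"), rec(acc="K2"), rec(acc="K3"),
        ]

    def test_mixed_fixture_counts(self):
        clean, audit = apply_exclusion_rules(self.make_mixed_fixture())
        assert len(clean) == 4  # K1-K3 plus the kept copy of D1
        assert audit.counts_by_rule == {
            RuleCode.MISSING_COORDS: 2, RuleCode.DUPLICATE: 1,
            RuleCode.ACCESSION_COLLISION: 2, RuleCode.QUARTER_DEGREE: 1,
        }

    def test_all_clean_input_is_identity(self):
        records = [rec(acc=f"K{i}") for i in range(6)]
        clean, audit = apply_exclusion_rules(records)
        assert clean == records
        assert audit.events == []

    def test_genus_only_record_in_ambiguous_genus_removed(self):
        records = [rec(acc="X1", genus="Mus", species=""),
                   rec(acc="X2", genus="Mus", species="minutoides")]
        clean, audit = apply_exclusion_rules(records, ambiguous_genera={"Mus"})
        assert [r.accession_id for r in clean] == ["X2"]
        assert audit.count(RuleCode.AMBIGUOUS_GENUS) == 1

    def test_introduced_genus_wildcard(self):
        records = [rec(acc="R1", genus="Rattus", species="rattus"),
                   rec(acc="R2", genus="Rattus", species="norvegicus"),
                   rec(acc="K1")]
        clean, audit = apply_exclusion_rules(records, introduced_list={("Rattus", "*")})
        assert len(clean) == 1
        assert audit.count(RuleCode.INTRODUCED) == 2

    def test_collision_scoped_per_source_collection(self):
        # same accession number in different museums is not a collision
        records = [rec(acc="1001", source=Source.DM, genus="Otomys"),
                   rec(acc="1001", source=Source.NMNH, genus="Mastomys")]
        clean, audit = apply_exclusion_rules(records)
        assert len(clean) == 2
        assert audit.events == []


# --- properties -----------------------------------------------------------

_record_strategy = st.builds(
    rec,
    acc=st.sampled_from([f"A{i}" for i in range(8)]),
    source=st.sampled_from([Source.DM, Source.NMNH]),
    genus=st.sampled_from(["Mus", "Otomys", "Aethomys"]),
    species=st.sampled_from(["", "sp1", "sp2"]),
    lat=st.sampled_from(["-26.1", "-27.2", ""]),
    lon=st.sampled_from(["28.2", ""]),
)


def _fix_format(r: SpecimenRecord) -> SpecimenRecord:
    from dataclasses import replace

    absent = not r.lat_raw or not r.lon_raw
    return replace(r, coord_format=CoordFormat.ABSENT if absent else CoordFormat.DECIMAL)


@given(st.lists(_record_strategy.map(_fix_format), max_size=40))
def test_conservation_and_idempotence(records):
    """|input| = |output| + removals, and a second pass removes nothing."""
    clean, audit = apply_exclusion_rules(records)
    assert len(records) == len(clean) + len(audit.events)
    again, audit2 = apply_exclusion_rules(clean)
    assert again == clean
    assert audit2.events == []


@given(st.lists(_record_strategy.map(_fix_format), max_size=40))
def test_collision_rule_removes_whole_groups(records):
    """Collision removal matches a brute-force group-by on the post-duplicate,
    post-missing-coordinate record set, and never a proper subset."""
    survivors, audit = apply_exclusion_rules(records)
    # reconstruct the stage-3 input the way the pipeline defines it
    staged = [r for r in records if r.coord_format is not CoordFormat.ABSENT]
    staged = list(dict.fromkeys(staged))  # drop exact duplicates, keep first
    expected_keys = collision_groups(staged)
    removed = {(e.accession_id, e.source) for e in audit.events
               if e.rule_code is RuleCode.ACCESSION_COLLISION}
    assert removed == expected_keys
    for key in expected_keys:
        assert all((r.accession_id, r.source.value) != key for r in survivors)
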