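"""Interaction assembly, export schemas and the category cross-tab."""

from __future__ import annotations

import io

import pytest

from cargomine.interactions import (
    INTERACTION_COLUMNS,
    Interaction,
    Origin,
    build_species_interactions,
    build_species_locations,
    crosstab_by_category,
    export_interactions_csv,
    read_interactions_csv,
    triage_records,
)
from cargomine.sequence_meta import SequenceRecord


@pytest.fixture(scope="module")
def built(clean_fixture):
    return build_species_interactions(
        clean_fixture.records,
        clean_fixture.taxonomy,
        organism_pmids=clean_fixture.organism_pmids,
    )


class TestAssembly:
    def test_single_record_single_pair(self, clean_fixture):
        record = SequenceRecord(seq_id="7", tax_id=11096, host="sheep")
        (it,) = build_species_interactions([record], clean_fixture.taxonomy)
        assert (it.cargo_id, it.carrier_id) == (11096, 9940)
        assert it.sequence_ids == frozenset({"7"})
        assert it.origin == Origin.SEQUENCE_BACKED

    def test_unresolved_host_contributes_nothing(self, clean_fixture):
        record = SequenceRecord(seq_id="7", tax_id=11096, host="unknown vertebrate")
        assert build_species_interactions([record], clean_fixture.taxonomy) == []

    def test_publication_only_needs_five_shared_papers(self, clean_fixture):
        tax = clean_fixture.taxonomy
        # seed the pair universe with two disjoint sequence-backed pairs
        records = [
            SequenceRecord(seq_id="1", tax_id=11096, host="sheep"),
            SequenceRecord(seq_id="2", tax_id=1000000, host="cattle"),
        ]
        for n_shared, expected_pairs in [(4, 2), (5, 4)]:
            shared_a = frozenset(range(100, 100 + n_shared))
            shared_b = frozenset(range(200, 200 + n_shared))
            pmids = {
                11096: shared_a | {1},
                1000000: shared_b | {2},
                9940: shared_b | {3},
                9913: shared_a | {4},
            }
            built = build_species_interactions(records, tax, organism_pmids=pmids)
            assert len(built) == expected_pairs
            for it in built:
                if it.origin == Origin.PUBLICATION_ONLY:
                    assert len(it.pmids) >= 5

    def test_no_publication_only_below_threshold_in_corpus(self, built):
        for it in built:
            if it.origin == Origin.PUBLICATION_ONLY:
                assert len(it.pmids) >= 5
            else:
                assert it.sequence_ids

    def test_evidence_conservation(self, clean_fixture, built):
        triage = triage_records(clean_fixture.records, clean_fixture.taxonomy,
                                clean_fixture.resolver)
        total_seq_evidence = sum(len(it.sequence_ids) for it in built)
        # each eligible record contributes exactly one (cargo, carrier) pair
        assert total_seq_evidence == len(triage.eligible)


class TestLocations:
    def test_sequence_route_adds_country_and_region(self, clean_fixture):
        record = SequenceRecord(seq_id="9", tax_id=11096, country="Italy: Milan")
        locs = build_species_locations(
            [record], clean_fixture.taxonomy, clean_fixture.geolocator
        )
        keys = {(l.species_id, l.country, l.region) for l in locs}
        assert keys == {(11096, "Italy", None), (11096, "Italy", "Regione Lombardia")}

    def test_discarded_location_contributes_nothing(self, clean_fixture):
        record = SequenceRecord(seq_id="9", tax_id=11096, country="USSR")
        assert build_species_locations(
            [record], clean_fixture.taxonomy, clean_fixture.geolocator
        ) == []

    def test_publication_route_threshold_boundary(self, clean_fixture):
        record = SequenceRecord(seq_id="9", tax_id=11096)  # species seen, no location
        for n_shared, expect in [(4, 0), (5, 1)]:
            shared = frozenset(range(50, 50 + n_shared))
            locs = build_species_locations(
                [record],
                clean_fixture.taxonomy,
                clean_fixture.geolocator,
                species_pmids={11096: shared | frozenset({1})},
                country_pmids={"France": shared | frozenset({2})},
            )
            assert len(locs) == expect
            if locs:
                assert locs[0].origin == Origin.PUBLICATION_ONLY
                assert (locs[0].species_id, locs[0].country) == (11096, "France")


class TestExport:
    def test_column_schema_is_exact(self, built, clean_fixture):
        frame = export_interactions_csv(
            built, clean_fixture.taxonomy, domestic_ids=clean_fixture.bundle.domestic_ids
        )
        assert list(frame.columns) == INTERACTION_COLUMNS

    def test_identifier_cap_preserves_counts(self, clean_fixture):
        many = Interaction(
            cargo_id=11096,
            carrier_id=9940,
            sequence_ids=frozenset(str(i) for i in range(250)),
            pmids=frozenset(),
            origin=Origin.SEQUENCE_BACKED,
        )
        frame = export_interactions_csv([many], clean_fixture.taxonomy)
        row = frame.iloc[0]
        listed = row["Sequences"].split(";")
        assert len(listed) == 100
        assert row["Sequences count"] == 250
        assert listed == sorted((str(i) for i in range(100)), key=int)
        assert row["Publications"] == ""

    def test_empty_set_exports_header_only(self, clean_fixture):
        buf = io.StringIO()
        export_interactions_csv([], clean_fixture.taxonomy, fh=buf)
        assert buf.getvalue().strip() == ",".join(INTERACTION_COLUMNS)

    def test_round_trip_preserves_fields_up_to_cap(self, built, clean_fixture):
        buf = io.StringIO()
        export_interactions_csv(
            built, clean_fixture.taxonomy,
            domestic_ids=clean_fixture.bundle.domestic_ids, fh=buf,
        )
        buf.seek(0)
        back = read_interactions_csv(buf)
        assert len(back) == len(built)
        by_name = {
            (clean_fixture.taxonomy.scientific_name(it.cargo_id),
             clean_fixture.taxonomy.scientific_name(it.carrier_id)): it
            for it in built
        }
        for _, row in back.iterrows():
            it = by_name[(row["Cargo"], row["Carrier"])]
            assert row["Sequences count"] == len(it.sequence_ids)
            assert row["Publication count"] == len(it.pmids)
            if len(it.sequence_ids) <= 100:
                assert set(row["Sequences"].split(";")) - {""} == it.sequence_ids
            if 0 < len(it.pmids) <= 100:
                assert {int(p) for p in row["Publications"].split(";")} == it.pmids


class TestCrosstab:
    def test_pair_level_counting_and_conservation(self, built, clean_fixture):
        table = crosstab_by_category(
            built, clean_fixture.taxonomy, clean_fixture.bundle.domestic_ids
        )
        pairs = {(it.cargo_id, it.carrier_id) for it in built}
        assert table.loc["Total", "Total"] == len(pairs)
        inner = table.drop(index="Total", columns="Total")
        assert inner.to_numpy().sum() == len(pairs)
        assert (inner.sum(axis=1) == table.drop(index="Total")["Total"]).all()

    def test_human_and_domestic_carrier_rows(self, built, clean_fixture):
        table = crosstab_by_category(
            built, clean_fixture.taxonomy, clean_fixture.bundle.domestic_ids
        )
        assert "human" in table.index
        assert "domestic" in table.index

    def test_single_pair_cell(self, clean_fixture):
        it = Interaction(11096, 9606, frozenset({"1"}), frozenset(), Origin.SEQUENCE_BACKED)
        table = crosstab_by_category([it], clean_fixture.taxonomy)
        assert table.loc["human", "virus"] == 1
        assert table.loc["Total", "Total"] == 1

    def test_unknown_species_raises(self, clean_fixture):
        it = Interaction(424242, 9606, frozenset({"1"}), frozenset(), Origin.SEQUENCE_BACKED)
        with pytest.raises(ValueError, match="424242"):
            crosstab_by_category([it], clean_fixture.taxonomy)
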