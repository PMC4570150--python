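"""Metadata parsing and host (carrier) disambiguation."""

from __future__ import annotations

import pytest

from cargomine._text import normalize
from cargomine.sequence_meta import (
    HostResolver,
    Method,
    ParseError,
    read_records_insdxml,
    read_records_tsv,
    triage_records,
)
from cargomine.taxonomy import Rank


class TestReaders:
    def test_tsv_and_xml_dialects_are_equivalent(self, tmp_path):
        from cargomine import fixtures as fx

        bundle = fx.generate(fx.FixtureSpec(seed=5, n_records=300))
        paths = bundle.write(tmp_path)
        from_tsv = read_records_tsv(paths["sequences.tsv"])
        from_xml = read_records_insdxml(paths["sequences.xml"])
        assert from_tsv == from_xml

    def test_missing_qualifiers_become_none(self, tmp_path):
        doc = tmp_path / "one.xml"
        doc.write_text(
            "<INSDSet><INSDSeq>"
            "<INSDSeq_primary-accession>42</INSDSeq_primary-accession>"
            "<INSDSeq_create-date></INSDSeq_create-date>"
            "<INSDSeq_feature-table><INSDFeature><INSDFeature_quals>"
            "<INSDQualifier><INSDQualifier_name>db_xref</INSDQualifier_name>"
            "<INSDQualifier_value>taxon:9606</INSDQualifier_value></INSDQualifier>"
            "</INSDFeature_quals></INSDFeature></INSDSeq_feature-table>"
            "</INSDSeq></INSDSet>"
        )
        (record,) = read_records_insdxml(doc)
        assert record.host is None and record.country is None and record.year is None
        assert record.tax_id == 9606

    def test_truncated_document_is_a_parse_error(self, tmp_path):
        doc = tmp_path / "broken.xml"
        doc.write_text("<INSDSet><INSDSeq><INSDSeq_primary-acces")
        with pytest.raises(ParseError):
            read_records_insdxml(doc)

    def test_record_without_taxon_is_skipped_and_logged(self, tmp_path):
        doc = tmp_path / "missing.xml"
        doc.write_text(
            "<INSDSet>"
            "<INSDSeq><INSDSeq_primary-accession>1</INSDSeq_primary-accession></INSDSeq>"
            "<INSDSeq><INSDSeq_primary-accession>2</INSDSeq_primary-accession>"
            "<INSDSeq_feature-table><INSDFeature><INSDFeature_quals>"
            "<INSDQualifier><INSDQualifier_name>db_xref</INSDQualifier_name>"
            "<INSDQualifier_value>taxon:9606</INSDQualifier_value></INSDQualifier>"
            "</INSDFeature_quals></INSDFeature></INSDSeq_feature-table></INSDSeq>"
            "</INSDSet>"
        )
        skipped: list[dict] = []
        records = read_records_insdxml(doc, skipped=skipped)
        assert [r.seq_id for r in records] == ["2"]
        assert skipped and skipped[0]["seq_id"] == "1"

    def test_malformed_tsv_row_is_skipped(self, tmp_path):
        path = tmp_path / "rows.tsv"
        path.write_text(
            "seq_id\ttax_id\thost\tcountry\tyear\n"
            "1\t9606\t\t\t2001\n"
            "2\tnot-a-taxid\t\t\t2001\n"
            "3\t9913\tcow\tItaly\t\n"
        )
        skipped: list[dict] = []
        records = read_records_tsv(path, skipped=skipped)
        assert [r.seq_id for r in records] == ["1", "3"]
        assert len(skipped) == 1


class TestDisambiguateHost:
    @pytest.mark.parametrize(
        ("host", "species", "method"),
        [
            ("Homo sapiens", 9606, Method.DIRECT_LATIN),
            ("Canis lupus familiaris", 9612, Method.DIRECT_LATIN),  # rolls up
            ("sheep", 9940, Method.ALT_NAME),
            ("Dog", 9612, Method.ALT_NAME),
            ("cattle (dairy)", 9913, Method.HEURISTIC),
            ("Bos taurus Holstein", 9913, Method.HEURISTIC),  # leading binomial
        ],
    )
    def test_staged_resolution(self, clean_fixture, host, species, method):
        a = clean_fixture.resolver.disambiguate_host(host)
        assert (a.species_id, a.method) == (species, method)

    @pytest.mark.parametrize(
        "host", ["unknown vertebrate", "cow; goat", "sheeep", "Primates"]
    )
    def test_unresolvable_strings(self, clean_fixture, host):
        a = clean_fixture.resolver.disambiguate_host(host)
        assert a.species_id is None
        assert a.method == Method.UNRESOLVED

    def test_ambiguous_alternative_name_is_never_guessed(self, clean_fixture):
        tax = clean_fixture.taxonomy
        tax.name_sets[9940].alternative_names.add("twinname")
        tax.name_sets[9913].alternative_names.add("twinname")
        tax._alt_index = None
        try:
            a = clean_fixture.resolver.disambiguate_host("twinname")
            assert a.species_id is None
        finally:
            tax.name_sets[9940].alternative_names.discard("twinname")
            tax.name_sets[9913].alternative_names.discard("twinname")
            tax._alt_index = None

    def test_empty_host_is_an_input_error(self, clean_fixture):
        with pytest.raises(ValueError):
            clean_fixture.resolver.disambiguate_host("  ")

    def test_never_returns_non_species(self, noisy_fixture):
        tax = noisy_fixture.taxonomy
        for record in noisy_fixture.records[:500]:
            if record.host is None:
                continue
            a = noisy_fixture.resolver.disambiguate_host(record.host)
            if a.species_id is not None:
                assert tax.nodes[a.species_id].effective_rank == Rank.SPECIES

    def test_matches_exhaustive_search_when_unique(self, clean_fixture):
        """Staged matching equals brute-force search over all names whenever
        exactly one species candidate exists for the raw string."""
        tax = clean_fixture.taxonomy
        lookup: dict[str, set[int]] = {}
        for tax_id, node in tax.nodes.items():
            if node.scientific_name:
                lookup.setdefault(normalize(node.scientific_name), set()).add(tax_id)
        for ns in tax.name_sets.values():
            for alt in ns.alternative_names:
                lookup.setdefault(normalize(alt), set()).add(ns.tax_id)
        hosts = {r.host for r in clean_fixture.records if r.host}
        checked = 0
        for host in sorted(hosts):
            candidates = {
                s
                for c in lookup.get(normalize(host), set())
                for s in [tax.resolve_to_species(c)]
                if s is not None
            }
            if len(candidates) == 1:
                a = clean_fixture.resolver.disambiguate_host(host)
                assert a.species_id == next(iter(candidates)), host
                checked += 1
        assert checked > 5


def test_triage_partition_sums_to_corpus_size(noisy_fixture):
    triage = triage_records(noisy_fixture.records, noisy_fixture.taxonomy, noisy_fixture.resolver)
    counts = triage.counts
    assert sum(counts.values()) == len(noisy_fixture.records)
    assert counts["host_unresolved"] > 0  # the noise classes actually fired
    assert counts["cargo_discarded"] > 0
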