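"""Search-term generation and PMID-set algebra."""

from __future__ import annotations

import io

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cargomine.literature import (
    PmidSet,
    Scope,
    build_location_queries,
    build_organism_query,
    co_citation,
    pmids_from_documents,
    read_pmid_sets,
    region_evidence,
    write_pmid_sets,
)
from cargomine.taxonomy import NameSet

CSFV_QUERY = (
    "(‘classical swine fever virus’ [Text Word] OR ‘csfv’ [Text Word] OR "
    "‘hog cholera virus’ [Text Word] OR ‘pestivirus type 2’ [Text Word] OR "
    "‘swine fever virus’ [Text Word]) NOT ‘african swine fever’ [Text Word]"
)


class TestOrganismQuery:
    def test_csfv_query_reproduced_exactly(self, clean_fixture):
        tax = clean_fixture.taxonomy
        csfv = next(
            t for t, n in tax.nodes.items()
            if n.scientific_name == "Classical swine fever virus"
        )
        term = build_organism_query(csfv, tax.scientific_name(csfv), tax.name_set(csfv))
        assert term.query_text == CSFV_QUERY
        assert term.scope == Scope.TEXT_WORD

    def test_single_name_degenerate_or(self):
        term = build_organism_query(1, "x y")
        assert term.query_text == "(‘x y’ [Text Word])"

    def test_inclusion_terms_are_and_joined(self):
        ns = NameSet(tax_id=1, inclusion_terms={"virus", "disease"})
        term = build_organism_query(1, "x y", ns)
        assert term.query_text == (
            "(‘x y’ [Text Word]) AND (‘disease’ [Text Word]) AND (‘virus’ [Text Word])"
        )

    def test_multiple_exclusions_are_or_grouped(self):
        ns = NameSet(tax_id=1, exclusion_terms={"b", "a"})
        term = build_organism_query(1, "x y", ns)
        assert term.query_text.endswith("NOT (‘a’ [Text Word] OR ‘b’ [Text Word])")

    def test_names_are_lowercased_deduplicated_sorted(self):
        ns = NameSet(tax_id=1, alternative_names={"ALPHA", "x y", "beta"})
        term = build_organism_query(1, "X Y", ns)
        assert term.query_text == (
            "(‘alpha’ [Text Word] OR ‘beta’ [Text Word] OR ‘x y’ [Text Word])"
        )

    def test_no_names_is_an_error(self):
        with pytest.raises(ValueError):
            build_organism_query(1, "   ")

    def test_deterministic_and_injective_on_distinct_name_sets(self):
        a = build_organism_query(1, "x y", NameSet(1, alternative_names={"p"}))
        b = build_organism_query(1, "x y", NameSet(1, alternative_names={"q"}))
        assert a == build_organism_query(1, "x y", NameSet(1, alternative_names={"p"}))
        assert a.query_text != b.query_text


class TestLocationQueries:
    def test_mesh_listed_country_uses_mesh_scope(self):
        terms = build_location_queries("Italy", True, ["Italy"], [])
        assert terms[0].scope == Scope.MESH
        assert "Italy" in terms[0].query_text

    def test_non_mesh_country_searches_title_abstract_over_all_names(self):
        terms = build_location_queries("Kosovo", False, ["Kosovo", "Republic of Kosovo"], [])
        assert terms[0].scope == Scope.TITLE_ABSTRACT
        assert terms[0].query_text == (
            "(‘Kosovo’ [title or abstract] OR ‘Republic of Kosovo’ [title or abstract])"
        )

    def test_region_query_or_joins_region_and_major_places(self):
        terms = build_location_queries(
            "United Kingdom", True, ["United Kingdom"],
            [("Scotland", ["Glasgow", "Edinburgh"])],
        )
        region_term = terms[1]
        assert region_term.subject_id == ("United Kingdom", "Scotland")
        assert region_term.query_text == (
            "(‘Scotland’ [title or abstract] OR ‘Glasgow’ [title or abstract] "
            "OR ‘Edinburgh’ [title or abstract])"
        )


class TestPmidAlgebra:
    def test_region_evidence_is_exact_intersection(self):
        c = PmidSet("C", frozenset({1, 2, 3}))
        r = PmidSet(("C", "R"), frozenset({2, 3, 4}))
        assert region_evidence(c, r).pmids == frozenset({2, 3})

    def test_intersection_identities(self):
        x = PmidSet("x", frozenset({1, 2}))
        empty = PmidSet("c", frozenset())
        assert region_evidence(empty, x).pmids == frozenset()
        assert region_evidence(PmidSet("c", x.pmids), x).pmids == x.pmids

    @pytest.mark.parametrize(("n_shared", "passes"), [(4, False), (5, True), (6, True)])
    def test_threshold_is_boundary_inclusive(self, n_shared, passes):
        a = set(range(100, 100 + n_shared)) | {1, 2}
        b = set(range(100, 100 + n_shared)) | {3, 4}
        shared, ok = co_citation(a, b, threshold=5)
        assert len(shared) == n_shared
        assert ok is passes

    def test_disjoint_sets_fail(self):
        assert co_citation({1}, {2}) == (frozenset(), False)

    def test_invalid_threshold(self):
        with pytest.raises(ValueError):
            co_citation({1}, {1}, threshold=0)

    @settings(max_examples=100, derandomize=True)
    @given(
        a=st.frozensets(st.integers(1, 40), max_size=15),
        b=st.frozensets(st.integers(1, 40), max_size=15),
        extra=st.frozensets(st.integers(41, 60), max_size=10),
    )
    def test_symmetric_and_monotone(self, a, b, extra):
        shared_ab, pass_ab = co_citation(a, b)
        shared_ba, pass_ba = co_citation(b, a)
        assert (shared_ab, pass_ab) == (shared_ba, pass_ba)
        # growing both sets can only keep or gain shared papers
        shared_big, pass_big = co_citation(a | extra, b | extra)
        assert shared_ab <= shared_big
        assert pass_big >= pass_ab

    def test_pmid_set_rejects_non_positive(self):
        with pytest.raises(ValueError):
            PmidSet("x", frozenset({0, 3}))


def test_pmid_tsv_round_trip(tmp_path):
    sets = {9606: {3, 1, 2}, "France": {7}, ("France", "Ile-de-France"): {9, 8}}
    buf = io.StringIO()
    write_pmid_sets(sets, buf)
    path = tmp_path / "pmids.tsv"
    path.write_text(buf.getvalue())
    back = read_pmid_sets(path)
    assert back == {k: frozenset(v) for k, v in sets.items()}


def test_adapter_matches_subject_terms_in_titles():
    docs = [
        (1, "Classical swine fever virus outbreak in pigs"),
        (2, "A study of rice genomics"),
        (3, "CSFV prevalence in wild boar"),
    ]
    sets = pmids_from_documents(docs, {11096: ["classical swine fever virus", "CSFV"]})
    assert sets[11096] == frozenset({1, 3})
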