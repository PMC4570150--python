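"""Citation-metadata evidence: search-term generation and PMID-set algebra.

Organism queries follow the rule *((any of the organism names and
alternative names) AND (all of the inclusion terms)) NOT (any of the
exclusion terms)*, rendered with curly quotes and ``[Text Word]`` field tags
and deterministic (alphabetical, lowercased, deduplicated) ordering inside
each OR group. Location queries use a MeSH term for MeSH-listed countries,
otherwise a title/abstract query over the country's official and alternative
names; each region gets a title/abstract query OR-joining the region name
with its configured major places.

Publication evidence is pure set algebra on PMID sets: region evidence is
the intersection of the region set with its country set, and a co-citation
link passes when the intersection holds at least ``threshold`` papers
(default 5, boundary inclusive).

Everything here is file-driven: PMID sets come from TSV files or from the
bundled title/abstract substring adapter, never from a live service.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from enum import Enum
from pathlib import Path
from typing import IO, Iterable, Mapping

from ._text import normalize
from .taxonomy import NameSet

LQ = "‘"  # ‘
RQ = "’"  # ’


class Scope(str, Enum):
    TEXT_WORD = "text_word"
    MESH = "mesh"
    TITLE_ABSTRACT = "title_abstract"


@dataclass(frozen=True)
class SearchTerm:
    subject_id: object
    query_text: str
    scope: Scope


@dataclass(frozen=True)
class PmidSet:
    subject_id: object
    pmids: frozenset[int]

    def __post_init__(self) -> None:
        if any(p <= 0 for p in self.pmids):
            raise ValueError("PMIDs must be positive integers")


def _tw(term: str) -> str:
    return f"{LQ}{term}{RQ} [Text Word]"


def _ta(term: str) -> str:
    return f"{LQ}{term}{RQ} [title or abstract]"


def build_organism_query(
    subject_id: object, scientific_name: str, names: NameSet | None = None
) -> SearchTerm:
    """Organism search term from the scientific name and its name set."""
    alt = names.alternative_names if names else set()
    include = names.inclusion_terms if names else set()
    exclude = names.exclusion_terms if names else set()
    all_names = sorted({n.lower() for n in {scientific_name, *alt} if n.strip()})
    if not all_names:
        raise ValueError("at least one organism name is required")
    query = "(" + " OR ".join(_tw(n) for n in all_names) + ")"
    for term in sorted({t.lower() for t in include}):
        query += f" AND ({_tw(term)})"
    exclusions = sorted({t.lower() for t in exclude})
    if len(exclusions) == 1:
        query += f" NOT {_tw(exclusions[0])}"
    elif exclusions:
        query += " NOT (" + " OR ".join(_tw(t) for t in exclusions) + ")"
    return SearchTerm(subject_id=subject_id, query_text=query, scope=Scope.TEXT_WORD)


def build_location_queries(
    country: str,
    mesh_listed: bool,
    country_names: Iterable[str],
    regions: Iterable[tuple[str, Iterable[str]]],
) -> list[SearchTerm]:
    """One query for the country plus one per region.

    ``country_names`` is the official name followed by alternatives (used
    when the country is not a MeSH heading); ``regions`` yields
    (region name, major places) pairs, places kept in their given order.
    """
    terms: list[SearchTerm] = []
    if mesh_listed:
        terms.append(
            SearchTerm(country, f"{LQ}{country}{RQ} [MeSH Terms]", Scope.MESH)
        )
    else:
        names = [n for n in country_names if n.strip()] or [country]
        query = "(" + " OR ".join(_ta(n) for n in names) + ")"
        terms.append(SearchTerm(country, query, Scope.TITLE_ABSTRACT))
    for region, places in regions:
        parts = [region, *places]
        query = "(" + " OR ".join(_ta(p) for p in parts) + ")"
        terms.append(SearchTerm((country, region), query, Scope.TITLE_ABSTRACT))
    return terms


def region_evidence(pmid_c: PmidSet, pmid_r: PmidSet) -> PmidSet:
    """PMIDs about a region *within its country*: the exact intersection of
    the country set and the region set."""
    return PmidSet(subject_id=pmid_r.subject_id, pmids=pmid_c.pmids & pmid_r.pmids)


def co_citation(
    pmids_a: frozenset[int] | set[int], pmids_b: frozenset[int] | set[int], threshold: int = 5
) -> tuple[frozenset[int], bool]:
    """Shared PMIDs of two subjects and whether they clear the evidence
    threshold (>= threshold papers, boundary inclusive)."""
    if threshold < 1:
        raise ValueError("threshold must be >= 1")
    shared = frozenset(pmids_a) & frozenset(pmids_b)
    return shared, len(shared) >= threshold


# -- file I/O and the fixture adapter --------------------------------------


def read_pmid_sets(path: str | Path) -> dict[object, frozenset[int]]:
    """TSV of (subject_id, pmid); numeric subject ids come back as ints,
    anything else as strings. Compound subjects (country<TAB>region rows in a
    3-column file) come back as tuples."""
    acc: dict[object, set[int]] = {}
    with open(path, encoding="utf-8", newline="") as fh:
        for row in csv.reader(fh, delimiter="\t"):
            if not row or row[0].startswith("#"):
                continue
            *subject_parts, pmid = row
            subject_parts = [_coerce(p) for p in subject_parts]
            subject = subject_parts[0] if len(subject_parts) == 1 else tuple(subject_parts)
            acc.setdefault(subject, set()).add(int(pmid))
    return {s: frozenset(p) for s, p in acc.items()}


def write_pmid_sets(sets: Mapping[object, Iterable[int]], fh: IO[str]) -> None:
    writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
    for subject in sets:
        parts = list(subject) if isinstance(subject, tuple) else [subject]
        for pmid in sorted(sets[subject]):
            writer.writerow([*parts, pmid])


def _coerce(text: str) -> object:
    try:
        return int(text)
    except ValueError:
        return text


def pmids_from_documents(
    documents: Iterable[tuple[int, str]], subject_terms: Mapping[object, Iterable[str]]
) -> dict[object, frozenset[int]]:
    """Fixture adapter: derive PMID sets from raw (pmid, title+abstract)
    records by normalized substring matching of each subject's terms."""
    normalized_terms = {
        subject: [normalize(t) for t in terms] for subject, terms in subject_terms.items()
    }
    acc: dict[object, set[int]] = {subject: set() for subject in subject_terms}
    for pmid, text in documents:
        hay = " " + normalize(text) + " "
        for subject, terms in normalized_terms.items():
            if any(f" {t} " in hay or hay.strip() == t for t in terms if t):
                acc[subject].add(pmid)
    return {s: frozenset(p) for s, p in acc.items()}
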