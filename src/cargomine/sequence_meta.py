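"""Nucleotide-sequence metadata: parsing, cargo identification and host
(carrier) disambiguation.

Two input dialects are accepted and must behave identically:

* an INSDSeq-XML subset — the sequence identifier from
  ``INSDSeq_primary-accession``, the year from ``INSDSeq_create-date``, the
  taxon from a ``db_xref`` qualifier of the form ``taxon:<id>``, and the
  free-text ``host`` / ``country`` qualifiers;
* a TSV dialect with columns ``seq_id, tax_id, host, country, year``.

Host strings are resolved to carrier species by staged matching: exact
scientific (Latin) name, then the alternative-name dictionary, then a
cleanup heuristic (strip parenthetical qualifiers, try the leading two-token
binomial) that re-runs the first two stages. A string matching two or more
distinct species is never guessed: it stays unresolved, because precision is
what the downstream interaction tables are validated on. Matches below
species level roll up to the parent species; matches above species level are
discarded.
"""

from __future__ import annotations

import csv
import logging
import re
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import IO, Iterable

from lxml import etree

from ._text import normalize
from .taxonomy import Taxonomy

logger = logging.getLogger(__name__)


class ParseError(Exception):
    pass


@dataclass(frozen=True)
class SequenceRecord:
    seq_id: str
    tax_id: int
    host: str | None = None
    country: str | None = None
    year: int | None = None


class Method(str, Enum):
    DIRECT_LATIN = "direct_latin"
    ALT_NAME = "alt_name"
    HEURISTIC = "heuristic"
    UNRESOLVED = "unresolved"


@dataclass(frozen=True)
class CarrierAssignment:
    raw_host: str
    species_id: int | None
    method: Method


# -- readers ---------------------------------------------------------------

_TSV_COLUMNS = ["seq_id", "tax_id", "host", "country", "year"]


def read_records_tsv(path: str | Path, skipped: list[dict] | None = None) -> list[SequenceRecord]:
    """Read the TSV dialect; malformed rows are skipped and logged."""
    records: list[SequenceRecord] = []
    with open(path, encoding="utf-8", newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        for lineno, row in enumerate(reader, start=2):
            try:
                records.append(_record_from_row(row))
            except (ValueError, TypeError, KeyError) as exc:
                _log_skip(skipped, str(row.get("seq_id") or lineno), f"malformed row: {exc}")
    return records


def _record_from_row(row: dict) -> SequenceRecord:
    seq_id = (row.get("seq_id") or "").strip()
    if not seq_id:
        raise ValueError("missing seq_id")
    tax_raw = (row.get("tax_id") or "").strip()
    if not tax_raw:
        raise ValueError("missing tax_id")
    year_raw = (row.get("year") or "").strip()
    return SequenceRecord(
        seq_id=seq_id,
        tax_id=int(tax_raw),
        host=(row.get("host") or "").strip() or None,
        country=(row.get("country") or "").strip() or None,
        year=int(year_raw) if year_raw else None,
    )


def write_records_tsv(records: Iterable[SequenceRecord], fh: IO[str]) -> None:
    writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
    writer.writerow(_TSV_COLUMNS)
    for r in records:
        writer.writerow([r.seq_id, r.tax_id, r.host or "", r.country or "", r.year or ""])


_YEAR = re.compile(r"(\d{4})\s*$")


def read_records_insdxml(path: str | Path, skipped: list[dict] | None = None) -> list[SequenceRecord]:
    """Read the INSDSeq-XML subset; per-record problems skip that record,
    a syntactically broken document raises :class:`ParseError`."""
    try:
        tree = etree.parse(str(path))
    except etree.XMLSyntaxError as exc:
        raise ParseError(f"malformed XML document: {exc}") from exc
    records: list[SequenceRecord] = []
    for elem in tree.iter("INSDSeq"):
        try:
            records.append(parse_insdseq(elem))
        except ParseError as exc:
            seq_id = elem.findtext("INSDSeq_primary-accession") or "<unknown>"
            _log_skip(skipped, seq_id, str(exc))
    return records


def parse_insdseq(elem: etree._Element) -> SequenceRecord:
    """One ``INSDSeq`` element -> record; absent host/country are None,
    an absent taxon reference is a parse error."""
    seq_id = (elem.findtext("INSDSeq_primary-accession") or "").strip()
    if not seq_id:
        raise ParseError("missing INSDSeq_primary-accession")
    host = country = None
    tax_id: int | None = None
    for qual in elem.iter("INSDQualifier"):
        name = (qual.findtext("INSDQualifier_name") or "").strip()
        value = (qual.findtext("INSDQualifier_value") or "").strip()
        if name == "host" and value:
            host = value
        elif name == "country" and value:
            country = value
        elif name == "db_xref" and value.startswith("taxon:"):
            try:
                tax_id = int(value.partition(":")[2])
            except ValueError as exc:
                raise ParseError(f"bad taxon db_xref {value!r}") from exc
    if tax_id is None:
        raise ParseError("no taxon db_xref qualifier")
    year = None
    created = elem.findtext("INSDSeq_create-date") or ""
    m = _YEAR.search(created.strip())
    if m:
        year = int(m.group(1))
    return SequenceRecord(seq_id=seq_id, tax_id=tax_id, host=host, country=country, year=year)


def _log_skip(skipped: list[dict] | None, seq_id: str, reason: str) -> None:
    logger.warning("skipping record %s: %s", seq_id, reason)
    if skipped is not None:
        skipped.append({"seq_id": seq_id, "stage": "parse", "reason": reason})


# -- cargo and carrier resolution -----------------------------------------


def identify_cargo(record: SequenceRecord, taxonomy: Taxonomy) -> int | None:
    """Species of the sequenced organism; above-species and unresolvable
    entries return None and the record is excluded downstream."""
    from .taxonomy import UnknownTaxIdError

    try:
        return taxonomy.resolve_to_species(record.tax_id)
    except UnknownTaxIdError:
        logger.warning("record %s: unknown tax_id %s", record.seq_id, record.tax_id)
        return None


_PARENTHETICAL = re.compile(r"\([^()]*\)")


class HostResolver:
    """Staged free-text host -> carrier species matcher over a taxonomy."""

    def __init__(self, taxonomy: Taxonomy) -> None:
        self.taxonomy = taxonomy

    def disambiguate_host(self, host: str) -> CarrierAssignment:
        if not host or not host.strip():
            raise ValueError("host string must be non-empty")
        for method, text in self._attempts(host):
            species = self._match_unique(text, method)
            if species is not None:
                return CarrierAssignment(raw_host=host, species_id=species, method=method)
        return CarrierAssignment(raw_host=host, species_id=None, method=Method.UNRESOLVED)

    def _attempts(self, host: str) -> Iterable[tuple[Method, str]]:
        yield Method.DIRECT_LATIN, host
        yield Method.ALT_NAME, host
        # heuristic stage: strip parenthetical qualifiers, then retry both
        # dictionaries on the cleaned string and on its leading binomial
        cleaned = _PARENTHETICAL.sub(" ", host).strip()
        variants = []
        if normalize(cleaned) != normalize(host):
            variants.append(cleaned)
        tokens = cleaned.split()
        if len(tokens) > 2:
            variants.append(" ".join(tokens[:2]))
        for variant in variants:
            yield Method.HEURISTIC, variant

    def _match_unique(self, text: str, method: Method) -> int | None:
        key = normalize(text)
        if not key:
            return None
        if method == Method.DIRECT_LATIN:
            candidates = self.taxonomy.sci_name_index().get(key, set())
        elif method == Method.ALT_NAME:
            candidates = self.taxonomy.alt_name_index().get(key, set())
        else:  # heuristic retries both stages on the cleaned variant
            candidates = self.taxonomy.sci_name_index().get(key, set())
            if not candidates:
                candidates = self.taxonomy.alt_name_index().get(key, set())
        species = {
            s
            for s in (self.taxonomy.resolve_to_species(c) for c in candidates)
            if s is not None
        }
        if len(species) == 1:
            return next(iter(species))
        return None  # no match, above-species only, or ambiguous


# -- corpus triage ---------------------------------------------------------


@dataclass
class Triage:
    """Every record lands in exactly one bucket; bucket sizes sum to the
    corpus size (a tested invariant)."""

    cargo_discarded: list[SequenceRecord] = field(default_factory=list)
    host_absent: list[SequenceRecord] = field(default_factory=list)
    host_unresolved: list[SequenceRecord] = field(default_factory=list)
    eligible: list[tuple[SequenceRecord, int, int]] = field(default_factory=list)
    #: seq_id -> resolved cargo species for every record with a cargo
    cargo_of: dict[str, int] = field(default_factory=dict)
    discard_log: list[dict] = field(default_factory=list)

    @property
    def counts(self) -> dict[str, int]:
        return {
            "cargo_discarded": len(self.cargo_discarded),
            "host_absent": len(self.host_absent),
            "host_unresolved": len(self.host_unresolved),
            "eligible": len(self.eligible),
        }


def triage_records(
    records: Iterable[SequenceRecord], taxonomy: Taxonomy, resolver: HostResolver | None = None
) -> Triage:
    """Classify a corpus for interaction building: resolve each record's
    cargo, then (where a host tag exists) its carrier."""
    resolver = resolver or HostResolver(taxonomy)
    out = Triage()
    for record in records:
        cargo = identify_cargo(record, taxonomy)
        if cargo is None:
            out.cargo_discarded.append(record)
            out.discard_log.append(
                {"seq_id": record.seq_id, "stage": "cargo", "reason": "above_species_or_unknown"}
            )
            continue
        out.cargo_of[record.seq_id] = cargo
        if record.host is None:
            out.host_absent.append(record)
            continue
        assignment = resolver.disambiguate_host(record.host)
        if assignment.species_id is None:
            out.host_unresolved.append(record)
            out.discard_log.append(
                {"seq_id": record.seq_id, "stage": "host", "reason": "unresolved"}
            )
            continue
        out.eligible.append((record, cargo, assignment.species_id))
    return out
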