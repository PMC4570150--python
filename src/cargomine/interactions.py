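"""Assembly and export of the two interaction tables.

Species-species interactions ("cargoes are found in/on carriers") come from
two routes: (1) every sequence record whose sequenced organism resolves to a
cargo species and whose host tag resolves to a carrier species contributes
sequence evidence to that (cargo, carrier) pair; (2) the PMID sets of all
cargoes and carriers seen in route 1 are intersected pairwise — shared papers
attach as extra evidence to existing pairs, and *new* pairs enter the table
as publication-only interactions when backed by at least five papers.

Species-location interactions work the same way: the sequence route uses the
geolocated country qualifier, the publication route intersects each species'
PMID set with the country set (PMID_C) and the region-in-country set
(PMID_RC), again at the five-paper threshold.

Exports reproduce the published CSV schemas: evidence-identifier lists are
semicolon-separated and truncated to the first 100 identifiers in ascending
numeric order, while the count columns always report untruncated totals.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from enum import Enum
from pathlib import Path
from typing import IO, Iterable, Mapping

import pandas as pd

from .geolocate import Geolocator, Status
from .sequence_meta import HostResolver, SequenceRecord, Triage, triage_records
from .taxonomy import Category, Taxonomy

PUBLICATION_ONLY_THRESHOLD = 5
MAX_LISTED_IDS = 100

INTERACTION_COLUMNS = [
    "Cargo",
    "Cargo classification",
    "Carrier",
    "Carrier classification",
    "Sequences count",
    "Publication count",
    "Sequences",
    "Publications",
]

LOCATION_COLUMNS = [
    "Species",
    "Species classification",
    "Country",
    "Region",
    "Sequences count",
    "Publication count",
    "Sequences",
    "Publications",
]


class Origin(str, Enum):
    SEQUENCE_BACKED = "sequence_backed"
    PUBLICATION_ONLY = "publication_only"


@dataclass(frozen=True)
class Interaction:
    cargo_id: int
    carrier_id: int
    sequence_ids: frozenset[str]
    pmids: frozenset[int]
    origin: Origin


@dataclass(frozen=True)
class SpeciesLocation:
    species_id: int
    country: str
    region: str | None
    sequence_ids: frozenset[str]
    pmids: frozenset[int]
    origin: Origin


def build_species_interactions(
    records: Iterable[SequenceRecord],
    taxonomy: Taxonomy,
    organism_pmids: Mapping[int, frozenset[int]] | None = None,
    resolver: HostResolver | None = None,
    threshold: int = PUBLICATION_ONLY_THRESHOLD,
    triage: Triage | None = None,
) -> list[Interaction]:
    """Two-route assembly of the cargo-carrier table (see module docstring).

    Pass a precomputed ``triage`` to skip re-resolving the corpus.
    """
    if triage is None:
        triage = triage_records(records, taxonomy, resolver)
    seq_evidence: dict[tuple[int, int], set[str]] = {}
    for record, cargo, carrier in triage.eligible:
        seq_evidence.setdefault((cargo, carrier), set()).add(record.seq_id)

    pub_evidence: dict[tuple[int, int], frozenset[int]] = {}
    if organism_pmids:
        cargoes = sorted({c for c, _ in seq_evidence})
        carriers = sorted({h for _, h in seq_evidence})
        for cargo in cargoes:
            cargo_pmids = organism_pmids.get(cargo)
            if not cargo_pmids:
                continue
            for carrier in carriers:
                carrier_pmids = organism_pmids.get(carrier)
                if not carrier_pmids:
                    continue
                shared = cargo_pmids & carrier_pmids
                if not shared:
                    continue
                if (cargo, carrier) in seq_evidence:
                    pub_evidence[(cargo, carrier)] = frozenset(shared)
                elif len(shared) >= threshold:
                    pub_evidence[(cargo, carrier)] = frozenset(shared)

    out: list[Interaction] = []
    for pair in sorted(set(seq_evidence) | set(pub_evidence)):
        seqs = frozenset(seq_evidence.get(pair, set()))
        pmids = pub_evidence.get(pair, frozenset())
        out.append(
            Interaction(
                cargo_id=pair[0],
                carrier_id=pair[1],
                sequence_ids=seqs,
                pmids=pmids,
                origin=Origin.SEQUENCE_BACKED if seqs else Origin.PUBLICATION_ONLY,
            )
        )
    return out


def build_species_locations(
    records: Iterable[SequenceRecord],
    taxonomy: Taxonomy,
    geolocator: Geolocator,
    species_pmids: Mapping[int, frozenset[int]] | None = None,
    country_pmids: Mapping[str, frozenset[int]] | None = None,
    region_pmids: Mapping[tuple[str, str], frozenset[int]] | None = None,
    threshold: int = PUBLICATION_ONLY_THRESHOLD,
    assignment_log: list | None = None,
) -> list[SpeciesLocation]:
    """Two-route assembly of the species-location table.

    ``region_pmids`` must already be PMID_RC sets, i.e. region sets
    intersected with their country set (see
    :func:`cargomine.literature.region_evidence`).
    """
    seq_country: dict[tuple[int, str], set[str]] = {}
    seq_region: dict[tuple[int, str, str], set[str]] = {}
    species_seen: set[int] = set()
    for record in records:
        species = taxonomy.resolve_to_species(record.tax_id) if record.tax_id in taxonomy.nodes else None
        if species is None:
            continue
        species_seen.add(species)
        if record.country is None:
            continue
        assignment = geolocator.resolve(record.country)
        if assignment_log is not None:
            assignment_log.append((record.seq_id, assignment))
        if assignment.status == Status.DISCARDED:
            continue
        seq_country.setdefault((species, assignment.country), set()).add(record.seq_id)
        if assignment.region is not None:
            seq_region.setdefault(
                (species, assignment.country, assignment.region), set()
            ).add(record.seq_id)

    pub_country: dict[tuple[int, str], frozenset[int]] = {}
    pub_region: dict[tuple[int, str, str], frozenset[int]] = {}
    if species_pmids and country_pmids:
        for species in sorted(species_seen):
            sp_pmids = species_pmids.get(species)
            if not sp_pmids:
                continue
            for country in country_pmids:
                shared = sp_pmids & country_pmids[country]
                if not shared:
                    continue
                if (species, country) in seq_country or len(shared) >= threshold:
                    pub_country[(species, country)] = frozenset(shared)
            for (country, region), rc_pmids in (region_pmids or {}).items():
                shared = sp_pmids & rc_pmids
                if not shared:
                    continue
                key = (species, country, region)
                if key in seq_region or len(shared) >= threshold:
                    pub_region[key] = frozenset(shared)

    out: list[SpeciesLocation] = []
    for key in sorted(set(seq_country) | set(pub_country)):
        seqs = frozenset(seq_country.get(key, set()))
        pmids = pub_country.get(key, frozenset())
        out.append(
            SpeciesLocation(
                species_id=key[0],
                country=key[1],
                region=None,
                sequence_ids=seqs,
                pmids=pmids,
                origin=Origin.SEQUENCE_BACKED if seqs else Origin.PUBLICATION_ONLY,
            )
        )
    for key in sorted(set(seq_region) | set(pub_region)):
        seqs = frozenset(seq_region.get(key, set()))
        pmids = pub_region.get(key, frozenset())
        out.append(
            SpeciesLocation(
                species_id=key[0],
                country=key[1],
                region=key[2],
                sequence_ids=seqs,
                pmids=pmids,
                origin=Origin.SEQUENCE_BACKED if seqs else Origin.PUBLICATION_ONLY,
            )
        )
    return out


# -- categories -------------------------------------------------------------


def carrier_category(
    taxonomy: Taxonomy, tax_id: int, domestic_ids: frozenset[int] | set[int] = frozenset()
) -> Category:
    """Carrier classification: humans stay human, the domestic-animal list
    overrides the lineage category (carriers only), everything else keeps
    its lineage category."""
    lineage = taxonomy.node(tax_id).category
    if lineage == Category.HUMAN:
        return Category.HUMAN
    if tax_id in domestic_ids:
        return Category.DOMESTIC
    return lineage


def cargo_category(taxonomy: Taxonomy, tax_id: int) -> Category:
    return taxonomy.node(tax_id).category


# -- exports ----------------------------------------------------------------


def _id_list(ids: Iterable[object]) -> str:
    """Semicolon-joined identifier list, ascending numeric order, first 100."""
    ordered = sorted(ids, key=lambda x: (0, int(x)) if str(x).isdigit() else (1, str(x)))
    return ";".join(str(x) for x in ordered[:MAX_LISTED_IDS])


def export_interactions_csv(
    interactions: Iterable[Interaction],
    taxonomy: Taxonomy,
    domestic_ids: frozenset[int] | set[int] = frozenset(),
    fh: IO[str] | None = None,
    path: str | Path | None = None,
) -> pd.DataFrame:
    """Published species-species schema; returns the table and optionally
    writes the CSV."""
    rows = []
    for it in sorted(interactions, key=lambda i: (i.cargo_id, i.carrier_id)):
        rows.append(
            {
                "Cargo": taxonomy.scientific_name(it.cargo_id),
                "Cargo classification": cargo_category(taxonomy, it.cargo_id).value,
                "Carrier": taxonomy.scientific_name(it.carrier_id),
                "Carrier classification": carrier_category(
                    taxonomy, it.carrier_id, domestic_ids
                ).value,
                "Sequences count": len(it.sequence_ids),
                "Publication count": len(it.pmids),
                "Sequences": _id_list(it.sequence_ids),
                "Publications": _id_list(it.pmids),
            }
        )
    frame = pd.DataFrame(rows, columns=INTERACTION_COLUMNS)
    _write_csv(frame, fh, path)
    return frame


def export_locations_csv(
    locations: Iterable[SpeciesLocation],
    taxonomy: Taxonomy,
    fh: IO[str] | None = None,
    path: str | Path | None = None,
) -> pd.DataFrame:
    """Published species-location schema."""
    rows = []
    for loc in sorted(
        locations, key=lambda l: (l.species_id, l.country, l.region or "")
    ):
        rows.append(
            {
                "Species": taxonomy.scientific_name(loc.species_id),
                "Species classification": cargo_category(taxonomy, loc.species_id).value,
                "Country": loc.country,
                "Region": loc.region or "",
                "Sequences count": len(loc.sequence_ids),
                "Publication count": len(loc.pmids),
                "Sequences": _id_list(loc.sequence_ids),
                "Publications": _id_list(loc.pmids),
            }
        )
    frame = pd.DataFrame(rows, columns=LOCATION_COLUMNS)
    _write_csv(frame, fh, path)
    return frame


def _write_csv(frame: pd.DataFrame, fh: IO[str] | None, path: str | Path | None) -> None:
    if fh is not None:
        frame.to_csv(fh, index=False, lineterminator="\n")
    if path is not None:
        frame.to_csv(path, index=False, lineterminator="\n")


def read_interactions_csv(path_or_fh) -> pd.DataFrame:
    return pd.read_csv(path_or_fh, keep_default_na=False, dtype={"Sequences": str, "Publications": str})


def crosstab_by_category(
    interactions: Iterable[Interaction],
    taxonomy: Taxonomy,
    domestic_ids: frozenset[int] | set[int] = frozenset(),
) -> pd.DataFrame:
    """Carrier-category x cargo-category counts of unique (cargo, carrier)
    pairs, with row/column totals."""
    pairs = {(it.cargo_id, it.carrier_id) for it in interactions}
    rows = []
    for cargo, carrier in sorted(pairs):
        for tax_id in (cargo, carrier):
            if tax_id not in taxonomy.nodes:
                raise ValueError(f"uncategorized species: tax_id {tax_id}")
        rows.append(
            {
                "carrier": carrier_category(taxonomy, carrier, domestic_ids).value,
                "cargo": cargo_category(taxonomy, cargo).value,
            }
        )
    frame = pd.DataFrame(rows, columns=["carrier", "cargo"])
    if frame.empty:
        return pd.DataFrame()
    table = pd.crosstab(frame["carrier"], frame["cargo"], margins=True, margins_name="Total")
    table.index.name = "carrier"
    table.columns.name = "cargo"
    return table
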