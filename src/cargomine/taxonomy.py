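"""Taxonomic backbone: load an NCBI-taxdump-dialect tree, re-derive the
working ranks of cellular organisms from their name shape, and roll any
organism up to its species-level ancestor.

The working-rank rules reflect how strain/isolate entries are actually named
in public taxonomies: names containing digits or the tokens *unclassified*,
*uncultured* or *var* are demoted to "no rank"; clean two-token binomials are
species; three or more tokens are subspecies. Viruses and viroids keep their
curated ranks untouched, because virus nomenclature is not binomial.

Rule precedence (first match wins): digits, keyword tokens, word count 2,
word count >= 3, single word (-> no rank). Precedence and the single-word
case are this package's choices; see docs/methods.md.
"""

from __future__ import annotations

import csv
import re
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable


class Rank(str, Enum):
    SPECIES = "species"
    SUBSPECIES = "subspecies"
    NO_RANK = "no_rank"
    HIGHER = "higher"


#: ranks the reclassification rules apply to (everything else is "higher")
RECLASSIFIABLE = frozenset({Rank.SPECIES, Rank.SUBSPECIES, Rank.NO_RANK})


class Category(str, Enum):
    VIRUS = "virus"
    VIROID = "viroid"
    BACTERIA = "bacteria"
    FUNGI = "fungi"
    PROTOZOA = "protozoa"
    HELMINTH = "helminth"
    ARTHROPOD = "arthropod"
    PLANT = "plant"
    ALGAE = "algae"
    CNIDARIA = "cnidaria"
    BRYOZOA = "bryozoa"
    MOLLUSCA = "mollusca"
    SEGMENTED_WORM = "segmented_worm"
    PORIFERA = "porifera"
    FISH = "fish"
    AMPHIBIAN = "amphibian"
    REPTILE = "reptile"
    AVES = "aves"
    RODENT = "rodent"
    PRIMATE = "primate"
    HUMAN = "human"
    DOMESTIC = "domestic"
    OTHER_MAMMAL = "other_mammal"
    OTHER = "other"


class Source(str, Enum):
    NCBI_DUMP = "ncbi_dump"
    SUPPLEMENTAL = "supplemental"


@dataclass
class TaxonNode:
    tax_id: int
    scientific_name: str
    original_rank: Rank
    parent_id: int
    effective_rank: Rank | None = None
    category: Category = Category.OTHER
    source: Source = Source.NCBI_DUMP


@dataclass
class NameSet:
    """Alternative names plus PubMed inclusion (AND) / exclusion (NOT) terms
    for one organism. The scientific name itself is implicit, never stored."""

    tax_id: int
    alternative_names: set[str] = field(default_factory=set)
    inclusion_terms: set[str] = field(default_factory=set)
    exclusion_terms: set[str] = field(default_factory=set)


class TaxonomyError(Exception):
    pass


class UnknownTaxIdError(TaxonomyError, KeyError):
    pass


class DuplicateTaxIdError(TaxonomyError):
    pass


_KEYWORD = re.compile(r"(?<![a-z])(unclassified|uncultured|var)(?![a-z])", re.IGNORECASE)
_DIGIT = re.compile(r"\d")

_RANK_ALIASES = {
    "species": Rank.SPECIES,
    "subspecies": Rank.SUBSPECIES,
    "no rank": Rank.NO_RANK,
    "no_rank": Rank.NO_RANK,
}


def parse_rank(text: str) -> Rank:
    """Map a dump rank label to the working rank vocabulary; any formal rank
    other than species/subspecies ("genus", "family", ...) is HIGHER."""
    return _RANK_ALIASES.get(text.strip().lower(), Rank.HIGHER)


def reclassify_rank(name: str, original_rank: Rank, is_virus_or_viroid: bool) -> Rank:
    """Working rank of one organism from the shape of its name.

    Applies only to species / subspecies / no-rank entries of cellular
    organisms; viruses and viroids are returned unchanged.
    """
    if not name or not name.strip():
        raise ValueError("organism name must be non-empty")
    if original_rank not in RECLASSIFIABLE:
        raise ValueError(f"rank {original_rank} is not subject to reclassification")
    if is_virus_or_viroid:
        return original_rank
    if _DIGIT.search(name):
        return Rank.NO_RANK
    if _KEYWORD.search(name):
        return Rank.NO_RANK
    n_tokens = len(name.split())
    if n_tokens == 2:
        return Rank.SPECIES
    if n_tokens >= 3:
        return Rank.SUBSPECIES
    return Rank.NO_RANK  # single-token name cannot be a binomial


class Taxonomy:
    """The loaded tree plus name sets and category assignments.

    Typical construction::

        tax = Taxonomy.from_files(nodes, names, categories=cat_tsv,
                                  supplemental=suppl_tsv, name_sets=ns_tsv)

    which loads the dump, attaches supplemental organisms, assigns categories
    from the subtree-root map and applies the rank rules, in that order.
    """

    def __init__(self) -> None:
        self.nodes: dict[int, TaxonNode] = {}
        self.name_sets: dict[int, NameSet] = {}
        self.root_id: int | None = None
        #: subtree root tax_id -> category; nearest mapped ancestor wins
        self.category_roots: dict[int, Category] = {}
        #: category -> fallback parent tax_id for supplemental inserts
        self.fallback_parents: dict[Category, int] = {}
        self._sci_index: dict[str, set[int]] | None = None
        self._alt_index: dict[str, set[int]] | None = None

    # -- construction -----------------------------------------------------

    @classmethod
    def from_files(
        cls,
        nodes_dmp: str | Path,
        names_dmp: str | Path,
        categories: str | Path | None = None,
        supplemental: str | Path | None = None,
        name_sets: str | Path | None = None,
        fallback_parents: str | Path | None = None,
    ) -> "Taxonomy":
        tax = cls()
        tax._load_dump(Path(nodes_dmp), Path(names_dmp))
        if categories is not None:
            tax.load_categories(categories)
        if fallback_parents is not None:
            tax.load_fallback_parents(fallback_parents)
        if supplemental is not None:
            tax.load_supplemental(supplemental)
        if name_sets is not None:
            tax.load_name_sets(name_sets)
        tax.assign_categories()
        tax.apply_rank_rules()
        tax.validate_tree()
        return tax

    def _load_dump(self, nodes_dmp: Path, names_dmp: Path) -> None:
        for fields in _read_dmp(nodes_dmp):
            tax_id, parent_id, rank = int(fields[0]), int(fields[1]), fields[2]
            self.nodes[tax_id] = TaxonNode(
                tax_id=tax_id,
                scientific_name="",
                original_rank=parse_rank(rank),
                parent_id=parent_id,
            )
            if parent_id == tax_id:
                self.root_id = tax_id
        for fields in _read_dmp(names_dmp):
            tax_id, name_txt = int(fields[0]), fields[1]
            name_class = fields[3] if len(fields) > 3 else "scientific name"
            if name_class != "scientific name":
                continue
            node = self.nodes.get(tax_id)
            if node is not None:
                node.scientific_name = name_txt

    def load_categories(self, path: str | Path) -> None:
        """TSV of (tax_id, category): subtree roots defining categories."""
        for row in _read_tsv(path, 2):
            self.category_roots[int(row[0])] = Category(row[1])

    def load_fallback_parents(self, path: str | Path) -> None:
        """TSV of (category, tax_id): attachment points for supplemental
        organisms whose true parent is unknown."""
        for row in _read_tsv(path, 2):
            self.fallback_parents[Category(row[0])] = int(row[1])

    def load_supplemental(self, path: str | Path) -> None:
        """TSV of (tax_id, name, rank, parent_id, category); empty parent_id
        routes through the category fallback."""
        for row in _read_tsv(path, 5):
            node = TaxonNode(
                tax_id=int(row[0]),
                scientific_name=row[1],
                original_rank=parse_rank(row[2]),
                parent_id=-1,
                category=Category(row[4]),
                source=Source.SUPPLEMENTAL,
            )
            preferred = int(row[3]) if row[3] else None
            self.insert_supplemental(node, preferred)

    def load_name_sets(self, path: str | Path) -> None:
        """TSV of (tax_id, kind in {alt, include, exclude}, term)."""
        kind_attr = {
            "alt": "alternative_names",
            "include": "inclusion_terms",
            "exclude": "exclusion_terms",
        }
        for row in _read_tsv(path, 3):
            tax_id, kind, term = int(row[0]), row[1], row[2]
            ns = self.name_sets.setdefault(tax_id, NameSet(tax_id=tax_id))
            getattr(ns, kind_attr[kind]).add(term)
        # the scientific name is implicit in a name set, never stored
        for ns in self.name_sets.values():
            node = self.nodes.get(ns.tax_id)
            if node is not None:
                ns.alternative_names.discard(node.scientific_name)
        self._alt_index = None

    def insert_supplemental(self, node: TaxonNode, preferred_parent: int | None = None) -> int:
        """Force an extra organism into the tree; returns the parent used."""
        if node.tax_id in self.nodes:
            raise DuplicateTaxIdError(f"tax_id {node.tax_id} already present")
        if preferred_parent is not None:
            if preferred_parent not in self.nodes:
                raise UnknownTaxIdError(preferred_parent)
            parent = preferred_parent
        else:
            try:
                parent = self.fallback_parents[node.category]
            except KeyError:
                raise TaxonomyError(
                    f"no fallback parent configured for category {node.category.value}"
                ) from None
        node.parent_id = parent
        node.source = Source.SUPPLEMENTAL
        self.nodes[node.tax_id] = node
        self._sci_index = None
        return parent

    # -- derivation -------------------------------------------------------

    def assign_categories(self) -> None:
        cache: dict[int, Category] = {}
        for tax_id in self.nodes:
            self._category_of(tax_id, cache)
        for tax_id, cat in cache.items():
            self.nodes[tax_id].category = cat

    def _category_of(self, tax_id: int, cache: dict[int, Category]) -> Category:
        chain: list[int] = []
        cur = tax_id
        while cur not in cache:
            if cur in self.category_roots:
                cache[cur] = self.category_roots[cur]
                break
            node = self.nodes[cur]
            if node.parent_id == cur:  # root
                cache[cur] = Category.OTHER
                break
            chain.append(cur)
            cur = node.parent_id
        resolved = cache[cur] if cur in cache else cache[chain[-1]]
        for t in chain:
            cache.setdefault(t, resolved)
        return cache[tax_id]

    def apply_rank_rules(self) -> None:
        for node in self.nodes.values():
            if node.original_rank in RECLASSIFIABLE and node.scientific_name:
                node.effective_rank = reclassify_rank(
                    node.scientific_name,
                    node.original_rank,
                    node.category in (Category.VIRUS, Category.VIROID),
                )
            else:
                node.effective_rank = Rank.HIGHER if node.original_rank not in RECLASSIFIABLE else node.original_rank

    def validate_tree(self) -> None:
        if self.root_id is None:
            raise TaxonomyError("no root node (parent_id == tax_id) found")
        for node in self.nodes.values():
            seen = set()
            cur = node.tax_id
            while True:
                if cur in seen:
                    raise TaxonomyError(f"cycle through tax_id {cur}")
                seen.add(cur)
                parent = self.nodes.get(cur)
                if parent is None:
                    raise TaxonomyError(f"dangling parent link at {cur}")
                if parent.parent_id == cur:
                    if cur != self.root_id:
                        raise TaxonomyError(f"second root at {cur}")
                    break
                cur = parent.parent_id

    # -- queries ----------------------------------------------------------

    def node(self, tax_id: int) -> TaxonNode:
        try:
            return self.nodes[tax_id]
        except KeyError:
            raise UnknownTaxIdError(tax_id) from None

    def name_set(self, tax_id: int) -> NameSet:
        return self.name_sets.get(tax_id, NameSet(tax_id=tax_id))

    def resolve_to_species(self, tax_id: int) -> int | None:
        """Species-level ancestor of an organism.

        Species return themselves; subspecies and no-rank entries walk parent
        links to the first species-level ancestor. Organisms at or above
        genus level, and entries with no species ancestor, return None and
        are discarded by callers.
        """
        node = self.node(tax_id)
        if node.effective_rank == Rank.SPECIES:
            return tax_id
        if node.effective_rank == Rank.HIGHER:
            return None
        seen = {tax_id}
        cur = node
        while cur.parent_id not in seen and cur.parent_id != cur.tax_id:
            cur = self.node(cur.parent_id)
            seen.add(cur.tax_id)
            if cur.effective_rank == Rank.SPECIES:
                return cur.tax_id
        return None

    def scientific_name(self, tax_id: int) -> str:
        return self.node(tax_id).scientific_name

    # normalized name -> candidate tax_ids (scientific and alternative names)

    def sci_name_index(self) -> dict[str, set[int]]:
        from ._text import normalize

        if self._sci_index is None:
            idx: dict[str, set[int]] = {}
            for node in self.nodes.values():
                if node.scientific_name:
                    idx.setdefault(normalize(node.scientific_name), set()).add(node.tax_id)
            self._sci_index = idx
        return self._sci_index

    def alt_name_index(self) -> dict[str, set[int]]:
        from ._text import normalize

        if self._alt_index is None:
            idx: dict[str, set[int]] = {}
            for ns in self.name_sets.values():
                for alt in ns.alternative_names:
                    idx.setdefault(normalize(alt), set()).add(ns.tax_id)
            self._alt_index = idx
        return self._alt_index

    def rank_counts(self) -> dict[Rank, int]:
        counts: dict[Rank, int] = {r: 0 for r in Rank}
        for node in self.nodes.values():
            counts[node.effective_rank or node.original_rank] += 1
        return counts


def _read_dmp(path: Path) -> Iterable[list[str]]:
    """taxdump dialect: fields separated by tab-pipe-tab, trailing tab-pipe."""
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            if line.endswith("\t|"):
                line = line[: -len("\t|")]
            yield line.split("\t|\t")


def _read_tsv(path: str | Path, n_fields: int) -> Iterable[list[str]]:
    with open(path, encoding="utf-8", newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        for row in reader:
            if not row or row[0].startswith("#"):
                continue
            row = row + [""] * (n_fields - len(row))
            yield row[:n_fields]
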