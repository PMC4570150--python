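"""Dataset-overlap validation arithmetic and the shared-cargo network.

The validation tables compare the extracted interaction dataset against
independent pathogen lists (human pathogens, domestic-mammal pathogens, wild
mammal parasites). All of them reduce to the same share/union arithmetic:
given identifier sets A and B, report |A|, |B|, |A∩B|, the percentage of A
found in B and of B found in A (rounded half-up to two decimals), and
|A∪B| = |A| + |B| − |A∩B|.

Identifier harmonisation between datasets (synonyms, reclassified taxa) is a
user-supplied mapping applied before these functions; it is data, not
algorithm. External lists arrive as plain TSV; a non-negative-prevalence
pre-filter is available for presence/absence sources that record negative
surveys, since the mined dataset is presence-only.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import Hashable, Iterable, Mapping

import networkx as nx


@dataclass(frozen=True)
class OverlapStats:
    n_a: int
    n_b: int
    n_shared: int
    pct_a_in_b: float
    pct_b_in_a: float
    n_union: int


def round_half_up(value: float, ndigits: int = 2) -> float:
    return float(Decimal(str(value)).quantize(Decimal("1." + "0" * ndigits), ROUND_HALF_UP))


def overlap(set_a: Iterable[Hashable], set_b: Iterable[Hashable]) -> OverlapStats:
    """Share/union statistics for two pre-harmonised identifier sets."""
    a, b = set(set_a), set(set_b)
    if not a or not b:
        raise ValueError("overlap percentages are undefined for an empty set")
    shared = a & b
    return OverlapStats(
        n_a=len(a),
        n_b=len(b),
        n_shared=len(shared),
        pct_a_in_b=round_half_up(100.0 * len(shared) / len(a)),
        pct_b_in_a=round_half_up(100.0 * len(shared) / len(b)),
        n_union=len(a) + len(b) - len(shared),
    )


def overlap_by_category(
    set_a: Iterable[Hashable],
    set_b: Iterable[Hashable],
    category_map: Mapping[Hashable, str],
    totals_key: str = "Total",
) -> dict[str, OverlapStats]:
    """Per-category overlap plus a totals entry equal to overlap on the full
    sets. Every identifier must be categorised."""
    a, b = set(set_a), set(set_b)
    for ident in a | b:
        if ident not in category_map:
            raise ValueError(f"uncategorized identifier: {ident!r}")
    out: dict[str, OverlapStats] = {}
    categories = sorted({category_map[i] for i in a | b})
    for cat in categories:
        ca = {i for i in a if category_map[i] == cat}
        cb = {i for i in b if category_map[i] == cat}
        if ca and cb:
            out[cat] = overlap(ca, cb)
    out[totals_key] = overlap(a, b)
    return out


def pathogen_level_overlap(
    interactions_a: Iterable[tuple[Hashable, Hashable]],
    interactions_b: Iterable[tuple[Hashable, Hashable]],
    host_scope: Iterable[Hashable],
) -> OverlapStats:
    """Overlap of cargo (pathogen) sets after projecting each interaction
    list to the cargoes interacting with at least one in-scope host: two
    datasets share pathogen P if both record P on *any* host in scope."""
    scope = set(host_scope)
    if not scope:
        raise ValueError("host scope must be non-empty")

    def project(pairs: Iterable[tuple[Hashable, Hashable]]) -> set[Hashable]:
        return {cargo for cargo, host in pairs if host in scope}

    return overlap(project(interactions_a), project(interactions_b))


def shared_cargo_network(
    interactions: Iterable[tuple[Hashable, Hashable]],
    carrier_scope: Iterable[Hashable] | None = None,
    cargo_scope: Iterable[Hashable] | None = None,
) -> nx.Graph:
    """Undirected carrier network: node weight = number of unique cargoes of
    that carrier (within ``cargo_scope``); an edge joins two carriers iff
    they share at least one cargo, weighted by the shared-cargo count.

    ``interactions`` is any iterable of (cargo, carrier) pairs; objects with
    ``cargo_id``/``carrier_id`` attributes are accepted too.
    """
    carrier_filter = set(carrier_scope) if carrier_scope is not None else None
    cargo_filter = set(cargo_scope) if cargo_scope is not None else None
    cargoes_of: dict[Hashable, set[Hashable]] = {}
    for item in interactions:
        if hasattr(item, "cargo_id"):
            cargo, carrier = item.cargo_id, item.carrier_id
        else:
            cargo, carrier = item
        if carrier_filter is not None and carrier not in carrier_filter:
            continue
        if cargo_filter is not None and cargo not in cargo_filter:
            continue
        cargoes_of.setdefault(carrier, set()).add(cargo)

    graph = nx.Graph()
    for carrier, cargoes in cargoes_of.items():
        graph.add_node(carrier, weight=len(cargoes))
    carriers = sorted(cargoes_of, key=str)
    for i, u in enumerate(carriers):
        for v in carriers[i + 1 :]:
            shared = len(cargoes_of[u] & cargoes_of[v])
            if shared >= 1:
                graph.add_edge(u, v, weight=shared)
    return graph


def write_network(graph: nx.Graph, edgelist_path: str | Path, graphml_path: str | Path | None = None) -> None:
    """Weighted edge list (TSV) and optionally GraphML text."""
    with open(edgelist_path, "w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(["source", "target", "weight"])
        for u, v, data in sorted(graph.edges(data=True), key=lambda e: (str(e[0]), str(e[1]))):
            writer.writerow([u, v, data.get("weight", 1)])
    if graphml_path is not None:
        nx.write_graphml(graph, str(graphml_path))


# -- external list readers ---------------------------------------------------


def read_id_list(path: str | Path, require_nonnegative_prevalence: bool = False) -> list[dict]:
    """External comparison list: TSV with header, columns ``identifier``,
    optional ``category``, ``host`` and ``prevalence``. With the pre-filter
    enabled, rows whose prevalence is present and negative are dropped
    (presence-only comparison)."""
    rows: list[dict] = []
    with open(path, encoding="utf-8", newline="") as fh:
        for row in csv.DictReader(fh, delimiter="\t"):
            if require_nonnegative_prevalence:
                prevalence = (row.get("prevalence") or "").strip()
                if prevalence and float(prevalence) < 0:
                    continue
            rows.append(row)
    return rows
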