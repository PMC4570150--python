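"""Deterministic synthetic-data generator.

Emits a coherent bundle of every input the pipeline consumes — taxonomy dump,
supplemental-organism and name-set tables, gazetteer, sequence-metadata
corpus (TSV and INSDSeq-XML dialects), PMID sets — together with ground-truth
tables of every interaction and location a correct pipeline must recover.

The generator's default rates are the documented frequencies of the real
corpus: 7.1% of records carry a host tag, 17.5% a country tag, 59.9% of
country tags carry sub-country detail, 73.6% of host tags are the carrier's
Latin name, and ~5.5% of host strings are unresolvable free text. Scale
parameters (record and organism counts) are desk-scale defaults. All
randomness flows from the single seed: the same spec yields byte-identical
bundles.

The carrier fauna is a fixed cast of 12 common vertebrates (with their
common-name dictionaries and the European domestic-animal flags); cargo
organisms (viruses, bacteria, fungi, protozoa, helminths) are generated, with
subspecies, strain-level "no rank" children, and deliberately unresolvable
entries to exercise every discard path.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field as dfield
from importlib import resources
from pathlib import Path

from pydantic import BaseModel, Field

from .gazetteer import Gazetteer
from .sequence_meta import SequenceRecord

PUB_THRESHOLD = 5


class FixtureSpec(BaseModel):
    """Study conditions for one synthetic corpus."""

    seed: int = 0
    n_species: int = Field(default=30, ge=5)
    n_subspecies: int = Field(default=8, ge=0)
    n_norank: int = Field(default=8, ge=0)
    n_records: int = Field(default=10_000, ge=0)

    # documented corpus frequencies
    p_host_tag: float = Field(default=0.071, ge=0.0, le=1.0)
    p_country_tag: float = Field(default=0.175, ge=0.0, le=1.0)
    p_region_given_country: float = Field(default=0.599, ge=0.0, le=1.0)
    p_host_latin: float = Field(default=0.736, ge=0.0, le=1.0)

    # noise classes (0 = clean corpus)
    p_host_unresolved: float = Field(default=0.055, ge=0.0, le=1.0)
    p_location_discard: float = Field(default=0.0005, ge=0.0, le=1.0)

    # corpus composition
    p_cargo_subspecies: float = Field(default=0.15, ge=0.0, le=1.0)
    p_cargo_norank: float = Field(default=0.10, ge=0.0, le=1.0)
    p_cargo_discard: float = Field(default=0.02, ge=0.0, le=1.0)
    p_host_parenthetical: float = Field(default=0.2, ge=0.0, le=1.0)

    # publication evidence layout
    n_pub_only_interactions: int = Field(default=15, ge=0)
    n_near_miss_interactions: int = Field(default=10, ge=0)
    n_pub_attach: int = Field(default=10, ge=0)
    n_pub_only_locations: int = Field(default=10, ge=0)
    n_pub_only_regions: int = Field(default=5, ge=0)
    n_near_miss_locations: int = Field(default=8, ge=0)


# -- fixed cast --------------------------------------------------------------

#: (tax_id, name, rank, parent_id) high-level scaffold
_SCAFFOLD = [
    (1, "root", "no rank", 1),
    (10239, "Viruses", "superkingdom", 1),
    (12884, "Viroids", "superkingdom", 1),
    (2, "Bacteria", "superkingdom", 1),
    (4751, "Fungi", "kingdom", 1),
    (5500, "Protozoa", "kingdom", 1),
    (6157, "Platyhelminthes", "phylum", 1),
    (40674, "Mammalia", "class", 1),
    (9443, "Primates", "order", 40674),
    (9989, "Rodentia", "order", 40674),
    (8782, "Aves", "class", 1),
]

_CATEGORY_ROOTS = [
    (10239, "virus"),
    (12884, "viroid"),
    (2, "bacteria"),
    (4751, "fungi"),
    (5500, "protozoa"),
    (6157, "helminth"),
    (40674, "other_mammal"),
    (9443, "primate"),
    (9989, "rodent"),
    (8782, "aves"),
    (9606, "human"),
]

_FALLBACK_PARENTS = [
    ("virus", 10239),
    ("bacteria", 2),
    ("fungi", 4751),
    ("protozoa", 5500),
    ("helminth", 6157),
    ("other", 1),
]

#: (genus_id, genus_name, genus_parent, species_id, species_name, alt names)
_CARRIERS = [
    (9605, "Homo", 9443, 9606, "Homo sapiens", ["human", "man", "patient"]),
    (9935, "Ovis", 40674, 9940, "Ovis aries", ["sheep", "domestic sheep", "lamb"]),
    (9903, "Bos", 40674, 9913, "Bos taurus", ["cattle", "cow", "bovine"]),
    (9822, "Sus", 40674, 9823, "Sus scrofa", ["pig", "swine", "wild boar"]),
    (9922, "Capra", 40674, 9925, "Capra hircus", ["goat", "domestic goat"]),
    (9611, "Canis", 40674, 9612, "Canis lupus", ["wolf", "gray wolf"]),
    (9682, "Felis", 40674, 9685, "Felis catus", ["cat", "domestic cat"]),
    (9789, "Equus", 40674, 9796, "Equus caballus", ["horse"]),
    (9030, "Gallus", 8782, 9031, "Gallus gallus", ["chicken", "red junglefowl"]),
    (8835, "Anas", 8782, 8839, "Anas platyrhynchos", ["duck", "mallard"]),
    (10088, "Mus", 9989, 10090, "Mus musculus", ["mouse", "house mouse"]),
    (10114, "Rattus", 9989, 10116, "Rattus norvegicus", ["rat", "brown rat"]),
]

#: dog is a subspecies carrier that must roll up to Canis lupus
_DOG = (9615, "Canis lupus familiaris", 9612, ["dog", "domestic dog"])

#: European domestic-animal override list (species-level carrier ids)
DOMESTIC_IDS = frozenset({9940, 9913, 9823, 9925, 9612, 9685, 9796, 9031, 8839})

_CSFV = (
    11096,
    "Classical swine fever virus",
    11095,
    "Pestivirus",
    ["CSFV", "hog cholera virus", "pestivirus type 2", "swine fever virus"],
    ["african swine fever"],
)

_UNRESOLVED_HOSTS = [
    "unknown vertebrate",
    "environmental sample",
    "field collected specimen",
    "sheeep",
    "catle herd",
    "wild bird species",
]

_PARENTHETICALS = ["dairy", "farm", "adult", "juvenile", "captive"]

#: (country display names, [(place string, expected admin1 or None)])
_PLACE_POOL: list[tuple[str, list[str], list[tuple[str, str | None]]]] = [
    ("United States", ["United States", "USA"],
     [("MA", "Massachusetts"), ("NY", "New York"), ("Boston", "Massachusetts"),
      ("California", "California"), ("Los Angeles", "California")]),
    ("Italy", ["Italy"],
     [("Milan", "Regione Lombardia"), ("Rome", "Lazio"), ("Lombardia", "Regione Lombardia")]),
    ("China", ["China"],
     [("Shantou", "Quangdong sheng"), ("Guangzhou", "Quangdong sheng"), ("Beijing", "Beijing")]),
    ("United Kingdom", ["United Kingdom", "UK"],
     [("Yorkshire, Old Peak", "England"), ("Glasgow", "Scotland"), ("London", "England")]),
    ("France", ["France"], [("Paris", "Ile-de-France"), ("Marseille", "Provence-Alpes-Cote d'Azur")]),
    ("Germany", ["Germany"], [("Munich", "Bavaria"), ("Bavaria", "Bavaria")]),
    ("Japan", ["Japan"], [("Sapporo", "Hokkaido"), ("Tokyo", "Tokyo")]),
    ("Brazil", ["Brazil"], [("Sao Paulo", "Sao Paulo"), ("Rio de Janeiro", "Rio de Janeiro")]),
    ("Russia", ["Russia"], [("Moscow", "Moskva")]),
    # no administrative divisions: detail strings resolve to country only
    ("Andorra", ["Andorra"], [("Andorra la Vella", None)]),
]

_DISCARD_LOCATIONS = ["USSR", "Yugoslavia", "Pacific Ocean", "Atlantis"]

_SYL = ["ba", "ce", "di", "fo", "gu", "ha", "ki", "lo", "mu", "ne",
        "pa", "qui", "ro", "su", "ta", "ve", "wo", "xi", "yu", "za"]


def fixture_gazetteer_path() -> Path:
    """The gazetteer TSV shipped with the package (covers the worked
    location examples plus historical countries and water bodies)."""
    return Path(str(resources.files("cargomine").joinpath("data/fixture_gazetteer.tsv")))


def load_fixture_gazetteer() -> Gazetteer:
    return Gazetteer.from_tsv(fixture_gazetteer_path())


@dataclass
class FixtureBundle:
    """Everything :func:`generate` produced: input-file texts plus ground
    truth. ``files`` maps file name to text content."""

    spec: FixtureSpec
    files: dict[str, str]
    records: list[SequenceRecord]
    #: species-level (cargo_id, carrier_id) pairs a correct pipeline recovers
    truth_interactions: set[tuple[int, int]] = dfield(default_factory=set)
    truth_pub_only: set[tuple[int, int]] = dfield(default_factory=set)
    #: (species_id, country, region-or-None)
    truth_locations: set[tuple[int, str, str | None]] = dfield(default_factory=set)
    #: (seq_id, stage) of every record the pipeline must discard, stage in
    #: {cargo, host, location}
    expected_discards: list[tuple[str, str]] = dfield(default_factory=list)
    domestic_ids: frozenset[int] = DOMESTIC_IDS

    def write(self, outdir: str | Path) -> dict[str, Path]:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {}
        for name, text in self.files.items():
            path = outdir / name
            path.write_text(text, encoding="utf-8")
            paths[name] = path
        return paths


def _word(rng: random.Random, n_syll: int, used: set[str]) -> str:
    while True:
        w = "".join(rng.choice(_SYL) for _ in range(n_syll))
        if w not in used:
            used.add(w)
            return w


def generate(spec: FixtureSpec) -> FixtureBundle:
    rng = random.Random(spec.seed)
    used_words: set[str] = set()

    nodes: list[tuple[int, int, str]] = []      # (tax_id, parent, rank)
    names: list[tuple[int, str]] = []
    name_sets: list[tuple[int, str, str]] = []  # (tax_id, kind, term)

    def add(tax_id: int, name: str, rank: str, parent: int) -> None:
        nodes.append((tax_id, parent, rank))
        names.append((tax_id, name))

    for tax_id, name, rank, parent in _SCAFFOLD:
        add(tax_id, name, rank, parent)
    for genus_id, genus, gparent, sp_id, sp_name, alts in _CARRIERS:
        add(genus_id, genus, "genus", gparent)
        add(sp_id, sp_name, "species", genus_id)
        for alt in alts:
            name_sets.append((sp_id, "alt", alt))
    dog_id, dog_name, dog_parent, dog_alts = _DOG
    add(dog_id, dog_name, "subspecies", dog_parent)
    for alt in dog_alts:
        name_sets.append((dog_id, "alt", alt))

    csfv_id, csfv_name, csfv_genus, csfv_genus_name, csfv_alts, csfv_excl = _CSFV
    add(csfv_genus, csfv_genus_name, "genus", 10239)
    add(csfv_id, csfv_name, "species", csfv_genus)
    for alt in csfv_alts:
        name_sets.append((csfv_id, "alt", alt))
    for term in csfv_excl:
        name_sets.append((csfv_id, "exclude", term))

    # generated cargo species, cycling through the pathogen-like categories
    cargo_roots = {"virus": 10239, "bacteria": 2, "fungi": 4751,
                   "protozoa": 5500, "helminth": 6157}
    cargo_cats = list(cargo_roots)
    next_id = 1_000_000
    cargo_species: list[int] = [csfv_id]
    genera_by_cat: dict[str, list[int]] = {c: [] for c in cargo_cats}
    for i in range(spec.n_species):
        cat = cargo_cats[i % len(cargo_cats)]
        if cat == "virus":
            stem = _word(rng, 3, used_words).capitalize()
            name = f"{stem} virus {i + 1}" if i % 2 else f"{stem} virus"
            sp_id = next_id
            next_id += 1
            add(sp_id, name, "species", cargo_roots["virus"])
        else:
            if genera_by_cat[cat] and rng.random() < 0.5:
                genus_id = rng.choice(genera_by_cat[cat])
                genus_name = dict(names)[genus_id]
            else:
                genus_name = _word(rng, 3, used_words).capitalize()
                genus_id = next_id
                next_id += 1
                add(genus_id, genus_name, "genus", cargo_roots[cat])
                genera_by_cat[cat].append(genus_id)
            sp_id = next_id
            next_id += 1
            add(sp_id, f"{genus_name} {_word(rng, 3, used_words)}", "species", genus_id)
        cargo_species.append(sp_id)

    name_of = dict(names)
    # subspecies and strain-level children of non-viral cargo species
    non_viral = [s for s in cargo_species if s != csfv_id and " virus" not in name_of[s]]
    subspecies_of: dict[int, int] = {}
    for _ in range(spec.n_subspecies):
        parent = rng.choice(non_viral)
        sub_id = next_id
        next_id += 1
        add(sub_id, f"{name_of[parent]} {_word(rng, 2, used_words)}", "subspecies", parent)
        subspecies_of[sub_id] = parent
    norank_of: dict[int, int] = {}
    for j in range(spec.n_norank):
        parent = rng.choice(non_viral)
        nr_id = next_id
        next_id += 1
        add(nr_id, f"{name_of[parent]} strain {j + 1}", "no rank", parent)
        norank_of[nr_id] = parent
    name_of = dict(names)

    # deliberately unresolvable / above-species sequenced organisms
    discard_pool: list[int] = []
    uncult_id = next_id
    next_id += 1
    add(uncult_id, "uncultured bacterium", "species", 2)  # keyword -> no rank, no species parent
    discard_pool.append(uncult_id)
    for cat in ("bacteria", "fungi"):
        if genera_by_cat[cat]:
            genus_id = genera_by_cat[cat][0]
            sp_nr = next_id
            next_id += 1
            add(sp_nr, f"{name_of[genus_id]} sp. {len(discard_pool) + 1}", "no rank", genus_id)
            discard_pool.append(sp_nr)
            discard_pool.append(genus_id)  # genus-level sequenced entry

    # supplemental organisms: one with a preferred parent, two via fallback
    supplemental: list[tuple[int, str, str, int | None, str]] = []
    for k, (cat, preferred) in enumerate(
        [("bacteria", genera_by_cat["bacteria"][0] if genera_by_cat["bacteria"] else None),
         ("virus", None), ("protozoa", None)]
    ):
        sp_id = next_id
        next_id += 1
        sname = f"{_word(rng, 3, used_words).capitalize()} {_word(rng, 3, used_words)}"
        supplemental.append((sp_id, sname, "species", preferred, cat))
        cargo_species.append(sp_id)
        name_of[sp_id] = sname

    # -- sequence corpus ----------------------------------------------------
    carriers = [(sp_id, sp_name, alts) for _, _, _, sp_id, sp_name, alts in _CARRIERS]
    records: list[SequenceRecord] = []
    truth_interactions: set[tuple[int, int]] = set()
    truth_locations: set[tuple[int, str, str | None]] = set()
    expected_discards: list[tuple[str, str]] = []
    species_seen: set[int] = set()
    cargoes_seen: set[int] = set()
    carriers_seen: set[int] = set()

    for i in range(spec.n_records):
        seq_id = str(100_000_000 + i)
        u = rng.random()
        if u < spec.p_cargo_discard and discard_pool:
            tax_id, cargo = rng.choice(discard_pool), None
        elif u < spec.p_cargo_discard + spec.p_cargo_subspecies and subspecies_of:
            tax_id = rng.choice(sorted(subspecies_of))
            cargo = subspecies_of[tax_id]
        elif u < spec.p_cargo_discard + spec.p_cargo_subspecies + spec.p_cargo_norank and norank_of:
            tax_id = rng.choice(sorted(norank_of))
            cargo = norank_of[tax_id]
        else:
            tax_id = rng.choice(cargo_species)
            cargo = tax_id

        host = None
        host_carrier: int | None = None
        if rng.random() < spec.p_host_tag:
            v = rng.random()
            if v < spec.p_host_latin:
                if rng.random() < 0.08:  # subspecies-named carrier, rolls up
                    host, host_carrier = dog_name, dog_parent
                else:
                    sp_id, sp_name, _ = rng.choice(carriers)
                    host, host_carrier = sp_name, sp_id
            elif v < spec.p_host_latin + spec.p_host_unresolved:
                host, host_carrier = rng.choice(_UNRESOLVED_HOSTS), None
            else:
                sp_id, _, alts = rng.choice(carriers)
                alt = rng.choice(alts)
                if rng.random() < spec.p_host_parenthetical:
                    alt = f"{alt} ({rng.choice(_PARENTHETICALS)})"
                host, host_carrier = alt, sp_id

        country_str = None
        loc_truth: tuple[str, str | None] | None = None
        loc_discard = False
        if rng.random() < spec.p_country_tag:
            if rng.random() < spec.p_location_discard:
                country_str, loc_discard = rng.choice(_DISCARD_LOCATIONS), True
            else:
                country, display_names, places = rng.choice(_PLACE_POOL)
                display = rng.choice(display_names)
                if places and rng.random() < spec.p_region_given_country:
                    place, region = rng.choice(places)
                    country_str = f"{display}: {place}"
                    loc_truth = (country, region)
                else:
                    country_str = display
                    loc_truth = (country, None)

        records.append(
            SequenceRecord(
                seq_id=seq_id, tax_id=tax_id, host=host,
                country=country_str, year=rng.randint(1993, 2012),
            )
        )

        if cargo is None:
            expected_discards.append((seq_id, "cargo"))
            continue
        species_seen.add(cargo)
        if host is not None and host_carrier is None:
            expected_discards.append((seq_id, "host"))
        if host_carrier is not None:
            truth_interactions.add((cargo, host_carrier))
            cargoes_seen.add(cargo)
            carriers_seen.add(host_carrier)
        if loc_discard:
            expected_discards.append((seq_id, "location"))
        elif loc_truth is not None:
            truth_locations.add((cargo, loc_truth[0], None))
            if loc_truth[1] is not None:
                truth_locations.add((cargo, loc_truth[0], loc_truth[1]))

    # -- publication evidence ------------------------------------------------
    pmid_counter = iter(range(1, 10_000_000))

    def block(n: int) -> set[int]:
        return {next(pmid_counter) for _ in range(n)}

    organism_pmids: dict[int, set[int]] = {}
    for org in sorted(cargoes_seen | carriers_seen | species_seen):
        organism_pmids[org] = block(rng.randint(5, 15))

    seq_pairs = set(truth_interactions)
    complement = [
        (c, h)
        for c in sorted(cargoes_seen)
        for h in sorted(carriers_seen)
        if (c, h) not in seq_pairs
    ]
    rng.shuffle(complement)
    truth_pub_only: set[tuple[int, int]] = set()
    idx = 0
    for _ in range(min(spec.n_pub_only_interactions, len(complement) - idx)):
        c, h = complement[idx]
        idx += 1
        shared = block(rng.randint(PUB_THRESHOLD, PUB_THRESHOLD + 5))
        organism_pmids[c] |= shared
        organism_pmids[h] |= shared
        truth_pub_only.add((c, h))
    for _ in range(min(spec.n_near_miss_interactions, max(0, len(complement) - idx))):
        c, h = complement[idx]
        idx += 1
        shared = block(rng.randint(1, PUB_THRESHOLD - 1))
        organism_pmids[c] |= shared
        organism_pmids[h] |= shared
    for c, h in rng.sample(sorted(seq_pairs), min(spec.n_pub_attach, len(seq_pairs))):
        shared = block(rng.randint(1, PUB_THRESHOLD + 3))
        organism_pmids[c] |= shared
        organism_pmids[h] |= shared

    country_pmids: dict[str, set[int]] = {}
    region_pmids: dict[tuple[str, str], set[int]] = {}
    for country, _, places in _PLACE_POOL:
        country_pmids[country] = block(15)
        for region in sorted({r for _, r in places if r}):
            shared = block(5)  # region papers co-listed under the country
            country_pmids[country] |= shared
            region_pmids[(country, region)] = block(8) | shared

    # publication-only locations: each species used at most once so that
    # sub-threshold blocks can never accumulate past the threshold
    loc_species = sorted(species_seen)
    rng.shuffle(loc_species)
    countries = [c for c, _, _ in _PLACE_POOL]
    si = 0

    def next_species() -> int | None:
        nonlocal si
        while si < len(loc_species):
            s = loc_species[si]
            si += 1
            return s
        return None

    for _ in range(spec.n_pub_only_locations):
        s = next_species()
        if s is None:
            break
        candidates = [c for c in countries if (s, c, None) not in truth_locations]
        if not candidates:
            continue
        c = rng.choice(candidates)
        shared = block(rng.randint(PUB_THRESHOLD, PUB_THRESHOLD + 4))
        organism_pmids[s] |= shared
        country_pmids[c] |= shared
        truth_locations.add((s, c, None))
    for _ in range(spec.n_pub_only_regions):
        s = next_species()
        if s is None:
            break
        candidates = [(c, r) for (c, r) in region_pmids if (s, c, r) not in truth_locations]
        if not candidates:
            continue
        c, r = rng.choice(candidates)
        shared = block(rng.randint(PUB_THRESHOLD, PUB_THRESHOLD + 4))
        organism_pmids[s] |= shared
        country_pmids[c] |= shared
        region_pmids[(c, r)] |= shared
        truth_locations.add((s, c, r))
        truth_locations.add((s, c, None))  # implied by PMID_RC <= PMID_C
    for _ in range(spec.n_near_miss_locations):
        s = next_species()
        if s is None:
            break
        candidates = [c for c in countries if (s, c, None) not in truth_locations]
        if not candidates:
            continue
        c = rng.choice(candidates)
        shared = block(rng.randint(1, PUB_THRESHOLD - 1))
        organism_pmids[s] |= shared
        country_pmids[c] |= shared

    # -- serialise -----------------------------------------------------------
    files: dict[str, str] = {}
    files["nodes.dmp"] = "".join(
        f"{t}\t|\t{p}\t|\t{r}\t|\n" for t, p, r in nodes
    )
    files["names.dmp"] = "".join(
        f"{t}\t|\t{n}\t|\t\t|\tscientific name\t|\n" for t, n in names
    )
    files["supplemental.tsv"] = "".join(
        f"{t}\t{n}\t{r}\t{p if p is not None else ''}\t{c}\n"
        for t, n, r, p, c in supplemental
    )
    files["name_sets.tsv"] = "".join(f"{t}\t{k}\t{term}\n" for t, k, term in name_sets)
    files["categories.tsv"] = "".join(f"{t}\t{c}\n" for t, c in _CATEGORY_ROOTS)
    files["fallback_parents.tsv"] = "".join(f"{c}\t{t}\n" for c, t in _FALLBACK_PARENTS)
    files["gazetteer.tsv"] = fixture_gazetteer_path().read_text(encoding="utf-8")

    import io

    from .literature import write_pmid_sets
    from .sequence_meta import write_records_tsv

    buf = io.StringIO()
    write_records_tsv(records, buf)
    files["sequences.tsv"] = buf.getvalue()
    files["sequences.xml"] = _render_insdxml(records)

    buf = io.StringIO()
    write_pmid_sets({k: organism_pmids[k] for k in sorted(organism_pmids)}, buf)
    files["pmids_organisms.tsv"] = buf.getvalue()
    buf = io.StringIO()
    write_pmid_sets(dict(sorted(country_pmids.items())), buf)
    files["pmids_countries.tsv"] = buf.getvalue()
    buf = io.StringIO()
    write_pmid_sets(dict(sorted(region_pmids.items())), buf)
    files["pmids_regions.tsv"] = buf.getvalue()

    files["truth_interactions.tsv"] = "".join(
        f"{c}\t{h}\t{'publication_only' if (c, h) in truth_pub_only else 'sequence_backed'}\n"
        for c, h in sorted(truth_interactions | truth_pub_only)
    )
    files["truth_locations.tsv"] = "".join(
        f"{s}\t{c}\t{r or ''}\n" for s, c, r in sorted(
            truth_locations, key=lambda x: (x[0], x[1], x[2] or "")
        )
    )

    return FixtureBundle(
        spec=spec,
        files=files,
        records=records,
        truth_interactions=truth_interactions | truth_pub_only,
        truth_pub_only=truth_pub_only,
        truth_locations=truth_locations,
        expected_discards=expected_discards,
    )


def _xml_escape(text: str) -> str:
    return (
        text.replace("&", "&amp;").replace("<", "&lt;").replace(">", "&gt;")
    )


def _render_insdxml(records: list[SequenceRecord]) -> str:
    parts = ['<?xml version="1.0" encoding="UTF-8"?>\n<INSDSet>\n']
    for r in records:
        quals = [f"<INSDQualifier><INSDQualifier_name>db_xref</INSDQualifier_name>"
                 f"<INSDQualifier_value>taxon:{r.tax_id}</INSDQualifier_value></INSDQualifier>"]
        if r.host:
            quals.append(
                "<INSDQualifier><INSDQualifier_name>host</INSDQualifier_name>"
                f"<INSDQualifier_value>{_xml_escape(r.host)}</INSDQualifier_value></INSDQualifier>"
            )
        if r.country:
            quals.append(
                "<INSDQualifier><INSDQualifier_name>country</INSDQualifier_name>"
                f"<INSDQualifier_value>{_xml_escape(r.country)}</INSDQualifier_value></INSDQualifier>"
            )
        created = f"01-JAN-{r.year}" if r.year else ""
        parts.append(
            "<INSDSeq>"
            f"<INSDSeq_primary-accession>{r.seq_id}</INSDSeq_primary-accession>"
            f"<INSDSeq_create-date>{created}</INSDSeq_create-date>"
            "<INSDSeq_feature-table><INSDFeature>"
            "<INSDFeature_key>source</INSDFeature_key>"
            f"<INSDFeature_quals>{''.join(quals)}</INSDFeature_quals>"
            "</INSDFeature></INSDSeq_feature-table>"
            "</INSDSeq>\n"
        )
    parts.append("</INSDSet>\n")
    return "".join(parts)
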