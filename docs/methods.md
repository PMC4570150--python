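# Methods

`cargomine` extracts two evidence-backed tables from public-database
metadata: species–species interactions ("cargo found in/on carrier", most of
which are pathogen–host relationships) and species–location records at
country and first-administrative-division ("region") level. The pipeline is
entirely file-driven: taxonomy dumps, sequence-metadata records, gazetteer
tables and PMID sets all arrive as plain text, and nothing contacts a live
service.

## Working ranks

Public taxonomies label many strain, isolate and environmental entries
inconsistently. Working ranks for cellular organisms are therefore re-derived
from the shape of the scientific name:

1. any decimal digit in the name → *no rank*;
2. any of the tokens `unclassified`, `uncultured`, `var` (token-bounded,
   case-insensitive, so `var.` matches but `Varanus` does not) → *no rank*;
3. exactly two whitespace tokens → *species*;
4. three or more tokens → *subspecies*;
5. a single token → *no rank*.

Rules are evaluated in that order, first match wins. The precedence and the
single-token case are this package's choices: demotion rules must run before
the word-count rules (a name like "Bacillus sp. 56" both contains digits and
has a countable shape), and a single token cannot be a binomial. Viruses and
viroids keep their curated ranks untouched because virus nomenclature is not
binomial. Reclassification is idempotent, which the property suite asserts.

Every organism used downstream is rolled up to its species-level ancestor:
species map to themselves, subspecies and no-rank entries walk parent links
upward, and anything at genus level or above — or with no species ancestor,
such as "uncultured bacterium" hanging off a phylum — is discarded and
logged. Supplemental organisms absent from the dump are forced into the tree
under a stated parent, or under a per-category fallback node from a small
config table.

## Host (carrier) disambiguation

Host qualifiers are free text. Matching is staged and precision-oriented:

1. exact match against scientific names (after normalisation: case fold,
   diacritic strip, outer punctuation strip, whitespace collapse);
2. match against the alternative-name dictionary (common names, breeds,
   acronyms);
3. a cleanup heuristic: strip parenthetical qualifiers ("cattle (dairy)" →
   "cattle"), try the leading two-token binomial ("Bos taurus Holstein" →
   "Bos taurus"), and re-run stages 1–2 on the cleaned variants.

A string matching two or more distinct species at the same stage is left
unresolved rather than guessed, and multi-host strings ("cow; goat") are
deliberately unresolved — the downstream tables are validated on precision,
so a wrong carrier is worse than a missing one. Matches below species level
roll up; matches above species level are discarded.

## Location disambiguation

Country qualifiers follow the `Country: Location` layout and are resolved in
two passes. The country part is matched against country names, alternative
names, historical countries and water bodies. Historical countries are
rescued when the location part names a successor country or a place within
one (the successor mapping is configuration carried in the gazetteer TSV,
since no authoritative mapping exists); otherwise the record is discarded.
Water bodies are discarded unless the location part itself names a country,
and discarded outright when that part is also a water body. Contradictory
tags ("USA: Japan") resolve by the country part and are logged.

The region pass splits the location part into candidates — each
comma/semicolon-delimited chunk plus the chunk's individual whitespace
tokens — and matches every candidate against the tiered place dictionary
(admin1 and state codes, then capitals, admin2, admin3, cities, towns,
villages). The highest-tier match wins; at equal tier a whole-chunk match
beats a single-token match, then the leftmost candidate wins. The candidate
grammar and tie-breaks are this package's definitions; only the tier order is
externally given. State codes match only as raw uppercase 2–3 letter tokens
before normalisation, so the "ma" inside "Palma" can never hit
MA/Massachusetts. Countries without administrative divisions (no sub-country
entries in the gazetteer) skip the region pass.

## Publication evidence

Organism search terms follow *((any name or alternative name) AND (all
inclusion terms)) NOT (any exclusion term)*, rendered with curly quotes and
`[Text Word]` tags, names lowercased, deduplicated and alphabetically
ordered so generation is deterministic and injective on distinct name sets.
Country queries use a `[MeSH Terms]` clause for MeSH-listed countries and a
title/abstract query over official plus alternative names otherwise; region
queries OR-join the region name with its configured major places.

Evidence combination is set algebra on PMID sets. Region evidence within a
country is PMID_RC = PMID_R ∩ PMID_C. A species–species or species–location
link that has *no* sequence evidence enters the table only when the relevant
intersection holds **at least 5 papers** (boundary inclusive). Pairs that do
have sequence evidence attach whatever shared papers exist, with no
threshold — the threshold gates publication-only entries only.

The pair universe for the publication route is the set of cargoes and
carriers already observed in host-tagged sequence records: publications
extend the evidence base and add new combinations of known actors, they do
not introduce new actors.

## Exports

The species–species CSV carries `Cargo, Cargo classification, Carrier,
Carrier classification, Sequences count, Publication count, Sequences,
Publications`; the species–location CSV the analogous eight fields. Evidence
identifier lists are semicolon-separated and truncated to the first 100
identifiers in ascending numeric order (the truncation order is this
package's choice, for determinism); the count columns always report
untruncated totals. Carrier classification applies two overrides on top of
the lineage category: humans are always `human`, and species on the
domestic-animal list report as `domestic` (carriers only — the same species
as a cargo keeps its lineage category). The cross-tab counts unique
(cargo, carrier) pairs per carrier-category × cargo-category cell.

## Validation arithmetic

Comparisons against external datasets reduce to share/union arithmetic on
identifier sets: |A|, |B|, |A∩B|, 100·|A∩B|/|A| and 100·|A∩B|/|B| rounded
half-up to two decimals, and |A∪B| = |A|+|B|−|A∩B|. Interaction-level
comparisons against host-limited lists project each dataset to the cargoes
interacting with any in-scope host before overlapping. Name harmonisation
between datasets is a user-supplied mapping applied beforehand; a
non-negative-prevalence pre-filter is available on the external-list reader
because the mined dataset is presence-only. The shared-cargo network weights
each carrier node by its count of unique cargoes and each edge by the number
of cargoes the two carriers share; layout/visualisation is out of scope.

## Synthetic corpora

The generator emits every input file plus ground-truth tables, all derived
from a single seed (same seed → byte-identical bundle). Its default rates
are the documented frequencies of the real corpus: 7.1% of records carry a
host tag, 17.5% a country tag, 59.9% of country tags carry sub-country
detail, 73.6% of host tags are the carrier's Latin name, and ~5.5% of host
strings are unresolvable free text (so ~94.5% of host strings resolve).
Scale defaults — 10,000 records, ~33 cargo species across the five
pathogen-like categories, 12 fixed carrier species with common-name
dictionaries — are desk-scale choices; corpus-scale record counts are not a
goal. Noise classes (misspelled hosts, bare unresolvable phrases, historical
countries, water bodies, above-species sequenced organisms) are injected at
configurable rates, each with a known expected discard stage.

PMID sets are laid out block-wise so that every intersection is designed:
publication-only links receive ≥5 shared papers, near-miss links 1–4 (they
must *not* appear in the output), and attach blocks add shared papers to
pairs that already have sequence evidence. Each species participates in at
most one location allocation so sub-threshold blocks can never accumulate
past the threshold.

What the fixtures do **not** emulate: real qualifier spelling diversity
(beyond the enumerated noise classes), PubMed query semantics (PMID sets are
constructed, not retrieved), gazetteer scale and homonym density, and
sequence content itself (bases are never read). A clean-corpus recovery of
precision = recall = 1 therefore demonstrates the bookkeeping and the
matching logic are exact on well-formed inputs, not that real-corpus
disambiguation is error-free.

## Numerical and degenerate-input choices

Percentages round half-up (`decimal`), two decimals. Empty identifier sets
make overlap percentages undefined and raise. Empty host strings and empty
organism name sets are input errors; absent qualifiers are `None`, never
errors. Malformed metadata records are skipped and logged, a syntactically
broken XML document raises. Ties in region resolution and identifier
truncation break deterministically as described above. The publication
threshold is a parameter (default 5) on every function that applies it.

## Known limitations

* No fuzzy matching: misspelled hosts ("sheeep") stay unresolved by design.
* Multi-host and multi-location strings are not split into multiple claims.
* Historical-country rescue depends entirely on the configured successor
  lists.
* Region output stops at admin1; lower tiers serve only as evidence for
  their admin1 region.
* External-dataset comparisons assume identifiers were harmonised upstream.
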