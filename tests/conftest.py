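"""Shared fixtures: synthetic corpora written to disk and re-loaded through
the package's own file readers, so every test exercises the real I/O path."""

from __future__ import annotations

from dataclasses import dataclass

import pytest

from cargomine import fixtures as fx
from cargomine.gazetteer import Gazetteer
from cargomine.geolocate import Geolocator
from cargomine.literature import read_pmid_sets
from cargomine.sequence_meta import HostResolver, read_records_tsv
from cargomine.taxonomy import Taxonomy


@dataclass
class LoadedFixture:
    bundle: fx.FixtureBundle
    taxonomy: Taxonomy
    gazetteer: Gazetteer
    geolocator: Geolocator
    resolver: HostResolver
    records: list
    organism_pmids: dict
    country_pmids: dict
    region_rc_pmids: dict  # already intersected with the country sets


def load_bundle(bundle: fx.FixtureBundle, outdir) -> LoadedFixture:
    paths = bundle.write(outdir)
    taxonomy = Taxonomy.from_files(
        paths["nodes.dmp"],
        paths["names.dmp"],
        categories=paths["categories.tsv"],
        supplemental=paths["supplemental.tsv"],
        name_sets=paths["name_sets.tsv"],
        fallback_parents=paths["fallback_parents.tsv"],
    )
    gazetteer = Gazetteer.from_tsv(paths["gazetteer.tsv"])
    records = read_records_tsv(paths["sequences.tsv"])
    organism_pmids = read_pmid_sets(paths["pmids_organisms.tsv"])
    country_pmids = read_pmid_sets(paths["pmids_countries.tsv"])
    raw_regions = read_pmid_sets(paths["pmids_regions.tsv"])
    region_rc = {key: pmids & country_pmids[key[0]] for key, pmids in raw_regions.items()}
    return LoadedFixture(
        bundle=bundle,
        taxonomy=taxonomy,
        gazetteer=gazetteer,
        geolocator=Geolocator(gazetteer),
        resolver=HostResolver(taxonomy),
        records=records,
        organism_pmids=organism_pmids,
        country_pmids=country_pmids,
        region_rc_pmids=region_rc,
    )


CLEAN_SPEC = fx.FixtureSpec(
    seed=1, n_records=10_000, p_host_unresolved=0.0, p_location_discard=0.0
)

NOISY_SPEC = fx.FixtureSpec(seed=2, n_records=2_000, p_location_discard=0.02)


@pytest.fixture(scope="session")
def clean_fixture(tmp_path_factory) -> LoadedFixture:
    """Noise-free corpus: the pipeline must recover the ground truth exactly."""
    return load_bundle(fx.generate(CLEAN_SPEC), tmp_path_factory.mktemp("clean"))


@pytest.fixture(scope="session")
def noisy_fixture(tmp_path_factory) -> LoadedFixture:
    """Corpus with unresolvable hosts and discardable locations injected."""
    return load_bundle(fx.generate(NOISY_SPEC), tmp_path_factory.mktemp("noisy"))


@pytest.fixture(scope="session")
def taxonomy(clean_fixture) -> Taxonomy:
    return clean_fixture.taxonomy


@pytest.fixture(scope="session")
def gazetteer() -> Gazetteer:
    return fx.load_fixture_gazetteer()


@pytest.fixture(scope="session")
def geolocator(gazetteer) -> Geolocator:
    return Geolocator(gazetteer)
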