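import io

import pytest

import goannot
from goannot.fixtures import FixtureSpec, generate_fixture
from goannot.propagation import read_assertions, read_blocks


@pytest.fixture(scope="session")
def bundle():
    """Default synthetic bundle (seed 1)."""
    return generate_fixture(FixtureSpec(seed=1))


@pytest.fixture(scope="session")
def ontology(bundle):
    return goannot.parse_obo(io.StringIO(bundle.obo))


@pytest.fixture(scope="session")
def ortho(bundle):
    return goannot.read_homologene(io.StringIO(bundle.homologene))


@pytest.fixture(scope="session")
def docs(bundle):
    return {
        taxon: goannot.read_gaf(io.StringIO(text))
        for taxon, text in bundle.gaf_by_taxon.items()
    }


@pytest.fixture(scope="session")
def tree(bundle):
    return goannot.read_tree(bundle.newick)


@pytest.fixture(scope="session")
def assertions(bundle):
    return read_assertions(io.StringIO(bundle.assertions_tsv))


@pytest.fixture(scope="session")
def blocks(bundle):
    return read_blocks(io.StringIO(bundle.blocks_tsv))


@pytest.fixture(scope="session")
def slim(bundle):
    return goannot.read_slim(io.StringIO(bundle.slim))


def make_config(**overrides):
    base = dict(
        source_taxon=9606,
        target_taxon=10090,
        load_reference="GO_REF:0000096",
        assigned_by="goannot-test",
        target_db="MGI",
    )
    base.update(overrides)
    return goannot.TransferConfig(**base)


@pytest.fixture
def config():
    return make_config()
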