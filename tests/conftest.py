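import pytest

from v2rscan import mining as mn
from v2rscan import phylogeny as ph
from v2rscan.fixtures import default_fixture

FIXTURE_SEED = 20


@pytest.fixture(scope="session")
def fam():
    """The standard two-species synthetic study (fixed seed)."""
    return default_fixture(FIXTURE_SEED)


@pytest.fixture(scope="session")
def mined(fam):
    """Gene models mined from both synthetic genomes."""
    models = {}
    for sp in sorted(fam.genomes):
        models[sp] = mn.mine_genome(fam.genomes[sp].scaffolds, fam.queries)
    return models


@pytest.fixture(scope="session")
def mined_flat(mined):
    return [m for ms in mined.values() for m in ms]


@pytest.fixture(scope="session")
def noisy_tree(fam):
    """Bootstrapped NJ tree of the evolved sequences, rooted on CaSR."""
    msa = ph.progressive_align(fam.proteins)
    msa = ph.filter_columns(msa, 0.5)
    tree = ph.bootstrap(msa, n=100, seed=11)
    return ph.root_with_outgroup(tree, {"OUT|CaSR1"})
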