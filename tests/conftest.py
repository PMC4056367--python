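import pytest

from focal import flux_analysis as fa
from focal.model_core import split_reversible
from focal.synthetic_fixtures import example_media_sets, make_example_network

CHAIN_TSV = """#!biomass BIO
id\tequation\treversible\tgpr
EX_A\tA_ex ->\t1\t
T\tA_ex -> A\t0\tgT
BIO\tA ->\t0\t
"""


@pytest.fixture(scope="session")
def example_model():
    return make_example_network()


@pytest.fixture(scope="session")
def example_split(example_model):
    split = split_reversible(example_model)
    blocked = fa.find_blocked_reactions(split, fa.all_nutrient_context(example_media_sets()))
    return split.with_blocked(blocked)


@pytest.fixture(scope="session")
def example_sets():
    return example_media_sets()


@pytest.fixture(scope="session")
def example_sets_two_carbon():
    return example_media_sets(max_carbon=2)


@pytest.fixture
def chain_tsv(tmp_path):
    path = tmp_path / "chain.tsv"
    path.write_text(CHAIN_TSV)
    return path
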