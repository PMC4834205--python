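import pytest

from crowdcid import FixtureConfig, generate_corpus

TINY_BLOCK = """\
9000001|t|Toxicity report.
9000001|a|A dose of cispla caused nephrosis rapidly.
9000001\t27\t33\tcispla\tChemical\tD910001
9000001\t41\t50\tnephrosis\tDisease\tD920001
9000001\tCID\tD910001\tD920001
"""


@pytest.fixture
def tiny_block() -> str:
    """A hand-built one-document PubTator block with one gold relation."""
    return TINY_BLOCK


@pytest.fixture(scope="session")
def small_corpus():
    """A deterministic synthetic corpus exercising every routing branch."""
    return generate_corpus(FixtureConfig(n_documents=15, rng_seed=11))


@pytest.fixture(scope="session")
def clean_corpus():
    """A corpus with no unmapped concepts: every gold relation indexable."""
    return generate_corpus(
        FixtureConfig(n_documents=10, p_unmapped=0.0, rng_seed=5)
    )
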