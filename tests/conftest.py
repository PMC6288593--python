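import pytest

from adex.mtl import ExtractionSystem
from adex.ner import NerConfig
from adex.relation import ReConfig
from adex.synthetic import GenConfig, generate_corpus


@pytest.fixture(scope="session")
def small_corpus():
    """30 train / 8 test synthetic documents — fast shared fixture."""
    return generate_corpus(GenConfig(n_train=30, n_test=8, seed=13))


@pytest.fixture(scope="session")
def full_corpus():
    """The default 200 train / 50 test corpus at seed 13."""
    return generate_corpus(GenConfig(seed=13))


@pytest.fixture(scope="session")
def trained_pipeline(full_corpus):
    """Pipeline system trained at default settings on the full corpus."""
    system = ExtractionSystem(NerConfig(seed=13), ReConfig(seed=13))
    system.fit(full_corpus.train)
    return system


@pytest.fixture()
def tiny_docs(small_corpus):
    return small_corpus.train[:8]
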