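import numpy as np
import pytest

from semhub.corpus import CorpusConfig, generate_corpus
from semhub.network import Architecture
from semhub.topics import build_topics
from semhub.vocabulary import assign_sm_features, build_vocabulary


@pytest.fixture(scope="session")
def vocab():
    return build_vocabulary()


@pytest.fixture(scope="session")
def fmap(vocab):
    return assign_sm_features(vocab)


@pytest.fixture(scope="session")
def topics(vocab):
    return build_topics(vocab)


@pytest.fixture(scope="session")
def small_corpus(vocab, topics):
    """30k-episode corpus: enough for stable adjacency statistics."""
    return generate_corpus(CorpusConfig(n_episodes=30_000), rng=123,
                           topics=topics, vocab=vocab)


@pytest.fixture()
def tiny_arch():
    """A 5-pool architecture small enough for finite-difference oracles."""
    return Architecture(n_verbal=5, n_sm=6, n_hub=4, n_context=4,
                        n_prediction=5)
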