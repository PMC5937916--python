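"""Episode sampling and corpus containers.

An episode is five stimuli drawn i.i.d. from one topic's distribution.
Abstract concepts are always presented verbally; concrete concepts and
homonyms are presented verbally or as a sensory-motor pattern with equal
probability.  The corpus is stored column-wise in numpy arrays and can be
round-tripped through JSON-lines.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .topics import Topic, TopicConfig, build_topics
from .vocabulary import ABSTRACT, Concept, VocabConfig, build_vocabulary

__all__ = ["Episode", "Corpus", "CorpusConfig", "sample_episode",
           "generate_corpus", "default_environment"]

EPISODE_LEN = 5


@dataclass(frozen=True)
class Episode:
    """One five-stimulus episode (a view into, or row of, a corpus)."""

    topic_id: int
    concepts: np.ndarray  # (5,) concept ids
    verbal: np.ndarray  # (5,) bool: True = word token, False = S-M pattern
    senses: np.ndarray  # (5,) 0/1, nonzero only for homonyms


@dataclass(frozen=True)
class CorpusConfig:
    n_episodes: int = 400_000
    vocab: VocabConfig = field(default_factory=VocabConfig)
    topics: TopicConfig = field(default_factory=TopicConfig)


@dataclass
class Corpus:
    topic_ids: np.ndarray  # (n,)
    concepts: np.ndarray  # (n, 5)
    verbal: np.ndarray  # (n, 5) bool
    senses: np.ndarray  # (n, 5) uint8
    seed: int | None = None

    def __len__(self) -> int:
        return self.topic_ids.shape[0]

    def episode(self, i: int) -> Episode:
        return Episode(int(self.topic_ids[i]), self.concepts[i],
                       self.verbal[i], self.senses[i])

    def __iter__(self):
        return (self.episode(i) for i in range(len(self)))

    # -- serialization ------------------------------------------------------
    def save_jsonl(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for i in range(len(self)):
                fh.write(json.dumps({
                    "t": int(self.topic_ids[i]),
                    "c": self.concepts[i].tolist(),
                    "v": [int(v) for v in self.verbal[i]],
                    "s": self.senses[i].tolist(),
                }) + "\n")

    @classmethod
    def load_jsonl(cls, path: str | Path) -> "Corpus":
        t, c, v, s = [], [], [], []
        with open(path) as fh:
            for line in fh:
                rec = json.loads(line)
                t.append(rec["t"]); c.append(rec["c"])
                v.append(rec["v"]); s.append(rec["s"])
        return cls(np.asarray(t, dtype=np.int16),
                   np.asarray(c, dtype=np.int16),
                   np.asarray(v, dtype=bool),
                   np.asarray(s, dtype=np.uint8))


def default_environment(config: CorpusConfig | None = None):
    """Vocabulary, feature map and calibrated topics for a configuration."""
    from .vocabulary import assign_sm_features

    config = config or CorpusConfig()
    vocab = build_vocabulary(config.vocab)
    fmap = assign_sm_features(vocab)
    topics = build_topics(vocab, config.topics)
    return vocab, fmap, topics


def sample_episode(topics: list[Topic], vocab: list[Concept],
                   rng: np.random.Generator) -> Episode:
    """Draw a single episode (convenience wrapper over the batch sampler)."""
    corpus = _sample(topics, vocab, 1, rng)
    return corpus.episode(0)


def generate_corpus(config: CorpusConfig | None = None,
                    rng: np.random.Generator | int | None = None,
                    topics: list[Topic] | None = None,
                    vocab: list[Concept] | None = None) -> Corpus:
    """Sample the training corpus (default 400,000 episodes)."""
    config = config or CorpusConfig()
    if config.n_episodes < 1:
        raise ValueError("n_episodes must be >= 1")
    seed = rng if isinstance(rng, int) else None
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    if topics is None or vocab is None:
        vocab, _, topics = default_environment(config)
    corpus = _sample(topics, vocab, config.n_episodes, rng)
    corpus.seed = seed
    return corpus


def _sample(topics: list[Topic], vocab: list[Concept], n: int,
            rng: np.random.Generator) -> Corpus:
    weights = np.array([t.base_weight for t in topics])
    weights = weights / weights.sum()
    topic_ids = rng.choice(len(topics), size=n, p=weights).astype(np.int16)

    concepts = np.empty((n, EPISODE_LEN), dtype=np.int16)
    senses = np.zeros((n, EPISODE_LEN), dtype=np.uint8)
    is_abstract = np.array([c.cls == ABSTRACT for c in vocab])
    for t, topic in enumerate(topics):
        rows = np.nonzero(topic_ids == t)[0]
        if rows.size == 0:
            continue
        draws = rng.choice(topic.members, size=(rows.size, EPISODE_LEN),
                           p=topic.probs)
        concepts[rows] = draws
        for hid, sense in topic.homonym_sense.items():
            if sense:
                senses[rows] |= np.where(draws == hid, np.uint8(sense), np.uint8(0))
    verbal = rng.random((n, EPISODE_LEN)) < 0.5
    verbal |= is_abstract[concepts]  # abstract concepts are verbal-only
    return Corpus(topic_ids, concepts, verbal, senses)
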