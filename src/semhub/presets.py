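"""Canonical parameter presets.

``full`` is the published schedule: a 400,000-episode corpus, ten models,
five passes (20,000 weight updates), single continuous stream, and
200-presentation test denominators.  It is faithful but expensive (tens of
CPU-hours).

``scaled`` is the package's reduced schedule for routine runs: the same
400,000-episode corpus and statistics, but two models trained for one pass
over the first 250,000 episodes in 100 parallel streams (float32), with
test denominators rebalanced to keep at least ~200 presentations per trial
per condition.  Problem sizes are documented in docs/methods.md.
"""

from __future__ import annotations

from dataclasses import dataclass

from .corpus import CorpusConfig
from .experiments import ExperimentConfig
from .training import TrainingConfig

__all__ = ["Preset", "FULL", "SCALED", "get_preset"]


@dataclass(frozen=True)
class Preset:
    name: str
    corpus: CorpusConfig
    training: TrainingConfig
    experiment: ExperimentConfig
    n_models: int
    train_episodes: int  # episodes of the corpus used per pass


FULL = Preset(
    name="full",
    corpus=CorpusConfig(n_episodes=400_000),
    training=TrainingConfig(n_passes=5, n_streams=1, dtype="float64"),
    experiment=ExperimentConfig(reps_per_model=20, n_lesions=20,
                                reps_per_lesion=1,
                                representation_repeats=50),
    n_models=10,
    train_episodes=400_000,
)

SCALED = Preset(
    name="scaled",
    corpus=CorpusConfig(n_episodes=400_000),
    training=TrainingConfig(n_passes=1, n_streams=100, dtype="float32"),
    experiment=ExperimentConfig(reps_per_model=100, n_lesions=40,
                                reps_per_lesion=5,
                                representation_repeats=10),
    n_models=2,
    train_episodes=250_000,
)


def get_preset(name: str) -> Preset:
    try:
        return {"full": FULL, "scaled": SCALED}[name]
    except KeyError:
        raise ValueError(f"unknown preset {name!r}") from None
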