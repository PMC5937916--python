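"""Damage models.

Semantic dementia (representational damage) is modelled by removing a
random subset of the connections projecting in and out of the hub layer -
including context->hub and the hub's self-connections; the hub->context
copy is a function, not a set of connections, and is never lesioned.
Lesions are mask-based and reversible: the underlying weights are never
modified.

Semantic aphasia (control damage) is modelled without touching the
weights: the controlled-retrieval mechanism is switched off and the
response-selection noise is raised (sd 0.045 for the homonym task, 0.04
for the synonym-judgment tasks).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .control import RetrievalConfig, SelectionConfig
from .network import WeightSet

__all__ = ["LesionSpec", "lesion_hub_links", "make_sa_damage",
           "intact_spec", "lesion_ensemble", "HUB_KEYS"]

# connections whose source or destination is the hub pool
HUB_KEYS = ("vh", "ch", "sh", "hh", "hs", "hp")


@dataclass(frozen=True)
class LesionSpec:
    kind: str  # "hub_links" | "control" | "intact"
    hub_fraction: float = 0.0
    retrieval: RetrievalConfig = RetrievalConfig()
    selection: SelectionConfig = SelectionConfig()

    def __post_init__(self):
        if not 0.0 <= self.hub_fraction <= 1.0:
            raise ValueError("hub fraction must lie in [0, 1]")


def intact_spec() -> LesionSpec:
    return LesionSpec("intact", retrieval=RetrievalConfig("controlled"),
                      selection=SelectionConfig(0.01))


def make_sa_damage(sim: int) -> LesionSpec:
    """Control-process damage: no controlled retrieval plus extra noise."""
    if sim not in (1, 2, 3):
        raise ValueError("sim must be 1, 2 or 3")
    sd = 0.045 if sim == 1 else 0.04
    return LesionSpec("control", retrieval=RetrievalConfig("none"),
                      selection=SelectionConfig(sd))


def lesion_hub_links(weights: WeightSet, fraction: float,
                     rng: np.random.Generator) -> WeightSet:
    """Mask a uniformly random ``fraction`` of all hub-adjacent links.

    Exactly round(fraction * n_eligible) links are removed, sampled without
    replacement across all six hub-adjacent matrices.  Returns a new
    WeightSet sharing weight arrays but carrying fresh masks.
    """
    if not 0.0 <= fraction <= 1.0:
        raise ValueError("fraction must lie in [0, 1]")
    sizes = [weights.w[k].size for k in HUB_KEYS]
    total = int(sum(sizes))
    n_remove = int(round(fraction * total))
    flat = np.ones(total, dtype=bool)
    if n_remove:
        kill = rng.choice(total, size=n_remove, replace=False)
        flat[kill] = False
    masks = dict(weights.masks)
    offset = 0
    for k, sz in zip(HUB_KEYS, sizes):
        m = flat[offset:offset + sz].reshape(weights.w[k].shape)
        prior = weights.masks.get(k)
        masks[k] = (m & (prior.astype(bool) if prior is not None else True)
                    ).astype(weights.w[k].dtype)
        offset += sz
    return WeightSet(weights.arch, weights.w, masks)


def lesion_ensemble(models: list[WeightSet], fraction: float,
                    n_lesions: int, rng: np.random.Generator,
                    ) -> list[WeightSet]:
    """Independent lesion masks per (model, lesion) pair."""
    if n_lesions < 1:
        raise ValueError("n_lesions must be >= 1")
    return [lesion_hub_links(m, fraction, rng)
            for m in models for _ in range(n_lesions)]
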