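"""Artificial vocabulary of the model's training environment.

The environment contains 64 noun concepts: 22 concrete items organised into
six taxonomic categories, 32 abstract items organised into 16 related pairs,
and 10 homonyms, each with two concrete senses tied to different categories.
Concrete items (and each homonym sense) carry sensory-motor (S-M) feature
sets: six features shared with the category and three unique to the item.
Abstract items carry no S-M features.
"""

from __future__ import annotations

from dataclasses import dataclass, field

__all__ = [
    "Concept",
    "Sense",
    "SMFeatureMap",
    "VocabConfig",
    "build_vocabulary",
    "assign_sm_features",
    "N_SM_FEATURES",
]

N_SM_FEATURES = 162
SHARED_PER_CATEGORY = 6
UNIQUE_PER_ITEM = 3

CONCRETE = "concrete"
ABSTRACT = "abstract"
HOMONYM = "homonym"

# Default category layout: name -> member labels (22 concrete words).
_DEFAULT_CATEGORIES = {
    "vehicles": ["lorry", "bus", "car", "tram"],
    "animals": ["deer", "horse", "trout", "bee"],
    "plants": ["apple", "oak", "fern", "rose"],
    "tools": ["hammer", "saw", "rope", "net"],
    "clothing": ["boot", "scarf", "glove"],
    "people": ["hunter", "cashier", "duchess"],
}

# Homonyms: label -> (dominant-sense category, subordinate-sense category).
_DEFAULT_HOMONYMS = {
    "pump": ("vehicles", "clothing"),
    "bank": ("people", "plants"),
    "seal": ("animals", "tools"),
    "bark": ("plants", "animals"),
    "jack": ("tools", "vehicles"),
    "mole": ("animals", "people"),
    "ruler": ("tools", "people"),
    "cap": ("clothing", "tools"),
    "mouse": ("animals", "tools"),
    "dart": ("tools", "clothing"),
}

# Abstract pairs (16 pairs, 32 words).
_DEFAULT_ABSTRACT_PAIRS = [
    ("journey", "distance"),
    ("price", "profit"),
    ("season", "harvest"),
    ("repair", "effort"),
    ("fashion", "style"),
    ("wealth", "estate"),
    ("speed", "traffic"),
    ("instinct", "hunger"),
    ("growth", "decay"),
    ("skill", "trade"),
    ("comfort", "warmth"),
    ("duty", "honor"),
    ("election", "policy"),
    ("debate", "reform"),
    ("luck", "chance"),
    ("team", "contest"),
]


class ConfigurationError(ValueError):
    """Raised when a vocabulary/feature configuration violates its invariants."""


@dataclass(frozen=True)
class Sense:
    """One meaning of a homonym: a category plus (later) its own feature set."""

    category: int
    dominant: bool


@dataclass(frozen=True)
class Concept:
    id: int
    label: str
    cls: str  # concrete | abstract | homonym
    category: int | None = None  # concrete only
    pair_id: int | None = None  # abstract only
    senses: tuple[Sense, Sense] | None = None  # homonyms only


@dataclass(frozen=True)
class VocabConfig:
    categories: dict[str, list[str]] = field(
        default_factory=lambda: {k: list(v) for k, v in _DEFAULT_CATEGORIES.items()}
    )
    homonyms: dict[str, tuple[str, str]] = field(
        default_factory=lambda: dict(_DEFAULT_HOMONYMS)
    )
    abstract_pairs: list[tuple[str, str]] = field(
        default_factory=lambda: list(_DEFAULT_ABSTRACT_PAIRS)
    )


def build_vocabulary(config: VocabConfig | None = None) -> list[Concept]:
    """Construct the 64-concept vocabulary.

    Ordering is deterministic: concrete items (category by category), then
    abstract pairs, then homonyms.  Raises :class:`ConfigurationError` if the
    class counts are not 22/32/10 or a category reference is dangling.
    """
    config = config or VocabConfig()
    cat_names = list(config.categories)
    if len(cat_names) != 6:
        raise ConfigurationError(f"expected 6 categories, got {len(cat_names)}")
    n_concrete = sum(len(v) for v in config.categories.values())
    if n_concrete != 22:
        raise ConfigurationError(f"concrete count {n_concrete} != 22")
    if len(config.abstract_pairs) != 16:
        raise ConfigurationError(
            f"abstract pair count {len(config.abstract_pairs)} != 16"
        )
    if len(config.homonyms) != 10:
        raise ConfigurationError(f"homonym count {len(config.homonyms)} != 10")

    cat_index = {name: i for i, name in enumerate(cat_names)}
    concepts: list[Concept] = []
    for name in cat_names:
        for label in config.categories[name]:
            concepts.append(
                Concept(len(concepts), label, CONCRETE, category=cat_index[name])
            )
    for pair_id, (a, b) in enumerate(config.abstract_pairs):
        for label in (a, b):
            concepts.append(Concept(len(concepts), label, ABSTRACT, pair_id=pair_id))
    for label, (dom_cat, sub_cat) in config.homonyms.items():
        for cat in (dom_cat, sub_cat):
            if cat not in cat_index:
                raise ConfigurationError(f"homonym {label!r}: unknown category {cat!r}")
        senses = (
            Sense(cat_index[dom_cat], dominant=True),
            Sense(cat_index[sub_cat], dominant=False),
        )
        concepts.append(Concept(len(concepts), label, HOMONYM, senses=senses))

    labels = [c.label for c in concepts]
    if len(set(labels)) != len(labels):
        raise ConfigurationError("duplicate labels in vocabulary")
    return concepts


@dataclass(frozen=True)
class SMFeatureMap:
    """Assignment of the 162 S-M feature indices.

    ``shared[c]`` is the 6-feature set of category ``c``; ``features[(cid,
    sense)]`` is the full 9-feature set of a concrete concept (``sense=0``) or
    a homonym sense (0 dominant, 1 subordinate).
    """

    shared: dict[int, frozenset[int]]
    unique: dict[tuple[int, int], frozenset[int]]

    def features(self, concept_id: int, sense: int = 0) -> frozenset[int]:
        return self.unique[(concept_id, sense)] | self._shared_for(concept_id, sense)

    def _shared_for(self, concept_id: int, sense: int) -> frozenset[int]:
        return self.shared[self._category[(concept_id, sense)]]

    # category lookup filled in by assign_sm_features
    _category: dict[tuple[int, int], int] = field(default_factory=dict)


def assign_sm_features(vocab: list[Concept]) -> SMFeatureMap:
    """Deterministically lay out the 162 S-M feature slots.

    First the 6 x 6 category-shared blocks, then 3 unique features for each
    concrete concept and each homonym sense, in vocabulary order.  With the
    default vocabulary this uses exactly 162 slots; any configuration needing
    more raises :class:`ConfigurationError`.
    """
    categories = sorted({c.category for c in vocab if c.cls == CONCRETE})
    cursor = 0
    shared: dict[int, frozenset[int]] = {}
    for cat in categories:
        shared[cat] = frozenset(range(cursor, cursor + SHARED_PER_CATEGORY))
        cursor += SHARED_PER_CATEGORY

    unique: dict[tuple[int, int], frozenset[int]] = {}
    category_of: dict[tuple[int, int], int] = {}
    holders: list[tuple[int, int, int]] = []  # (concept id, sense, category)
    for c in vocab:
        if c.cls == CONCRETE:
            holders.append((c.id, 0, c.category))
        elif c.cls == HOMONYM:
            holders.append((c.id, 0, c.senses[0].category))
            holders.append((c.id, 1, c.senses[1].category))
    for cid, sense, cat in holders:
        if cursor + UNIQUE_PER_ITEM > N_SM_FEATURES:
            raise ConfigurationError("S-M feature budget (162) exhausted")
        unique[(cid, sense)] = frozenset(range(cursor, cursor + UNIQUE_PER_ITEM))
        category_of[(cid, sense)] = cat
        cursor += UNIQUE_PER_ITEM

    fmap = SMFeatureMap(shared=shared, unique=unique)
    object.__setattr__(fmap, "_category", category_of)
    return fmap
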