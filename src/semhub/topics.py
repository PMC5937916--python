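"""Topic-based generative environment.

Episodes are sampled from 35 artificial "topics": probability distributions
over 10-19 vocabulary items that plausibly occur in the same situational
context.  The design table below fixes topic membership; within-topic
probabilities come from role weights (core / regular / occasional) combined
with per-word masses.  A deterministic calibration loop then nudges the
masses and a few targeted link weights so that the sampled corpus exhibits
the intended statistics:

* a ~17:1 spread between the most and least frequent words (eight "heavy"
  topics are sampled 5 or 10 times more often than the rest),
* dominant-sense homonym probe->target co-occurrence rates around .077 and
  subordinate rates around .033,
* related abstract pairs sharing several (but not all) topics,
* same-category concrete words clustering in topics, with designated
  cross-category associates (the deer/hunter pattern).

Everything here is deterministic given the configuration: randomness enters
only when episodes are sampled from the finished topics.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .vocabulary import ABSTRACT, HOMONYM, Concept

__all__ = ["Topic", "TopicConfig", "build_topics", "expected_frequencies",
           "expected_cooccurrence_rate", "HOMONYM_TRIALS", "ASSOCIATE_PAIRS"]

_CORE, _REG, _OCC = 3.0, 1.0, 0.45

# ---------------------------------------------------------------------------
# Design table.  Each entry: (name, base_weight, {label: role}, {homonym: sense})
# role is "core" / "reg" / "occ"; sense 0 = dominant, 1 = subordinate.
# ---------------------------------------------------------------------------
_T = [
    # --- vehicles cluster ---
    ("road", 10, dict(lorry="core", bus="reg", car="reg", tram="occ",
                      journey="core", distance="reg", speed="reg", traffic="reg",
                      pump="reg", jack="occ"), dict(pump=0, jack=1)),
    ("garage", 1, dict(lorry="reg", car="reg", pump="core", jack="occ",
                       repair="reg", journey="occ", speed="occ", price="occ",
                       hammer="occ", effort="occ"), dict(pump=0, jack=1)),
    ("highway", 1, dict(bus="reg", tram="core", lorry="reg", car="reg",
                        traffic="core", speed="reg", distance="reg",
                        journey="reg", pump="occ", price="occ"), dict(pump=0)),
    # --- animals cluster ---
    ("forest", 1, dict(deer="core", horse="occ", hunter="occ", bark="reg",
                       mole="reg", mouse="reg", oak="reg", fern="reg",
                       instinct="reg", hunger="reg", growth="occ", decay="occ"),
     dict(bark=1, mole=0, mouse=0)),
    ("meadow", 1, dict(horse="core", bee="core", deer="reg", mole="reg",
                       mouse="reg", seal="occ", rose="reg", fern="occ",
                       instinct="reg", hunger="reg", warmth="occ"),
     dict(mole=0, mouse=0, seal=0)),
    ("riverbank", 5, dict(trout="core", seal="reg", bank="reg", net="reg",
                          fern="reg", oak="occ", hunger="occ", mouse="occ",
                          horse="occ", growth="occ"),
     dict(seal=0, bank=1, mouse=0)),
    ("hunting", 1, dict(deer="core", hunter="core", net="reg", fern="occ",
                        instinct="reg", hunger="reg", skill="reg", bark="occ",
                        horse="occ", mole="occ", honor="occ"),
     dict(bark=1, mole=0)),
    # --- plants cluster ---
    ("orchard", 5, dict(apple="core", oak="reg", rose="occ", bee="reg",
                        season="reg", harvest="reg", growth="reg", price="occ",
                        bark="occ", trade="occ"), dict(bark=0)),
    ("garden", 1, dict(rose="core", fern="reg", oak="reg", apple="reg",
                       bee="reg", growth="reg", decay="reg", season="reg",
                       harvest="occ", bark="occ"), dict(bark=0)),
    ("woodland", 1, dict(oak="core", fern="reg", bark="reg", mole="occ",
                         season="occ", growth="reg", decay="reg", instinct="occ",
                         journey="occ", saw="reg"), dict(bark=0, mole=0)),
    # --- tools cluster ---
    ("workshop", 10, dict(hammer="reg", saw="reg", rope="reg", jack="reg",
                          ruler="reg", dart="occ", repair="core", effort="reg",
                          skill="reg", trade="reg"), dict(jack=0, ruler=0, dart=0)),
    ("toolshed", 1, dict(hammer="reg", saw="reg", net="core", rope="reg",
                         jack="reg", ruler="reg", dart="occ", repair="reg",
                         effort="reg", skill="occ", trade="occ"),
     dict(jack=0, ruler=0, dart=0)),
    ("office", 1, dict(ruler="reg", seal="occ", cap="occ",
                       price="reg", profit="reg", trade="core", wealth="occ",
                       duty="occ", cashier="reg", policy="reg", debate="reg"),
     dict(ruler=0, seal=1, cap=1)),
    ("darts", 1, dict(dart="core", net="occ", mouse="occ", skill="core",
                      effort="reg", hammer="occ", ruler="occ",
                      honor="occ", saw="occ", trade="occ"),
     dict(dart=0, ruler=0, mouse=1)),
    # --- clothing cluster ---
    ("wardrobe", 5, dict(boot="core", scarf="reg", glove="reg", cap="reg",
                         pump="occ", fashion="reg", style="reg", comfort="reg",
                         warmth="reg", price="occ"), dict(cap=0, pump=1)),
    ("tailor", 1, dict(scarf="reg", glove="reg", dart="occ", cap="reg",
                       fashion="reg", style="core", skill="reg", repair="occ",
                       boot="reg", price="occ"), dict(dart=1, cap=0)),
    ("winter", 1, dict(boot="reg", scarf="core", glove="reg", cap="reg",
                       pump="occ", comfort="reg", warmth="core", style="occ",
                       fashion="reg", journey="occ"), dict(cap=0, pump=1)),
    # --- people / finance cluster ---
    ("market", 10, dict(cashier="reg", apple="core", trout="occ", price="core",
                        profit="reg", trade="reg", bank="occ", harvest="reg",
                        wealth="occ", hunger="occ", lorry="occ"), dict(bank=0)),
    ("banking", 5, dict(bank="core", cashier="reg", price="reg", profit="reg",
                        wealth="reg", estate="reg", trade="reg", chance="occ",
                        growth="occ", harvest="occ", debate="occ"),
     dict(bank=0)),
    ("palace", 1, dict(duchess="core", ruler="occ", mole="occ", honor="reg",
                       duty="reg", wealth="reg", estate="reg", fashion="reg",
                       style="occ", comfort="occ", scarf="core", rose="reg",
                       hunter="reg"),
     dict(ruler=1, mole=1)),
    ("espionage", 1, dict(mole="reg", duchess="reg", honor="occ", duty="reg",
                          chance="reg", luck="occ", reform="reg", debate="reg",
                          election="occ", contest="occ", team="occ",
                          policy="occ", instinct="occ", decay="occ"),
     dict(mole=1)),
    # --- abstract-only topics (political cluster) ---
    ("election", 1, dict(election="core", policy="core", debate="reg",
                         reform="reg", duty="reg", honor="occ", profit="occ",
                         wealth="occ", contest="occ", luck="occ",
                         team="occ"), {}),
    ("referendum", 1, dict(election="reg", policy="reg", debate="core",
                           reform="core", duty="occ", price="occ", trade="occ",
                           chance="occ", luck="occ", team="reg", contest="reg"),
     {}),
    # --- cross-category event topics ---
    ("freight", 1, dict(lorry="core", hammer="reg", rope="reg", trade="reg",
                        distance="reg", speed="reg", traffic="reg",
                        journey="reg", profit="occ", jack="occ"), dict(jack=1)),
    ("commute", 1, dict(bus="core", tram="reg", cashier="core", traffic="reg",
                        journey="reg", distance="reg", comfort="reg",
                        price="occ", car="reg", scarf="occ"), {}),
    ("rally", 1, dict(car="core", glove="reg", speed="reg", traffic="occ",
                      skill="reg", journey="occ", pump="occ", instinct="occ",
                      jack="occ", lorry="occ"), dict(pump=0, jack=1)),
    ("stable", 1, dict(horse="core", net="occ", instinct="reg", hunger="reg",
                       distance="occ", mole="occ", rope="reg", deer="occ",
                       hunter="occ", fern="occ"), dict(mole=0)),
    ("logging", 1, dict(oak="core", saw="core", rope="reg", bark="reg",
                        growth="reg", decay="reg", trade="occ", repair="occ",
                        lorry="occ", fern="occ"), dict(bark=0)),
    ("expedition", 1, dict(hunter="reg", boot="reg", net="occ", journey="core",
                           distance="reg", horse="reg", rope="occ", scarf="occ",
                           instinct="occ", effort="occ"), {}),
    ("touring", 10, dict(lorry="reg", bus="reg", car="core", tram="reg",
                         journey="core", distance="reg", comfort="reg",
                         speed="reg", boot="occ", season="occ",
                         price="occ"),
     {}),
    ("auction", 1, dict(duchess="core", cashier="reg", price="reg", profit="reg",
                        wealth="core", estate="reg", apple="occ", fashion="reg",
                        style="occ", car="occ", trade="reg", hammer="reg",
                        honor="occ"), {}),
    ("fair", 1, dict(apple="reg", bee="occ", trout="reg", harvest="core",
                     season="reg", price="reg", trade="reg", profit="occ",
                     hammer="reg", cashier="reg", duchess="occ", chance="occ"), {}),
    ("renovation", 1, dict(hammer="reg", saw="reg", jack="reg", repair="core",
                           effort="reg", price="occ", bank="occ", decay="occ",
                           trade="occ", ruler="occ", lorry="occ"),
     dict(jack=0, bank=0, ruler=0)),
    ("spring", 1, dict(rose="reg", fern="reg", bee="reg", season="core",
                       growth="reg", warmth="reg", fashion="occ", style="occ",
                       apple="occ", scarf="occ", oak="occ"), {}),
    ("commerce", 1, dict(bank="reg", lorry="reg", trade="reg", profit="core",
                         price="reg", traffic="occ", speed="occ", policy="reg",
                         reform="occ", estate="occ", wealth="reg"),
     dict(bank=0)),
]

# Homonym trial design: probe -> (dominant target, subordinate target).
HOMONYM_TRIALS = {
    "pump": ("journey", "boot"),
    "bank": ("cashier", "trout"),
    "seal": ("trout", "trade"),
    "bark": ("oak", "deer"),
    "jack": ("repair", "car"),
    "mole": ("instinct", "duchess"),
    "ruler": ("trade", "duchess"),
    "cap": ("scarf", "price"),
    "mouse": ("hunger", "skill"),
    "dart": ("hammer", "scarf"),
}

# Designated cross-category concrete associates (the deer/hunter pattern);
# used by the associative judgment task.  Pairs in ASSOCIATE_STRONG are
# calibrated to a high associative strength (the "strongly associated"
# tail above the A > 0.07 threshold); the rest sit near the mean.
ASSOCIATE_STRONG = frozenset({frozenset(p) for p in
                              [("deer", "hunter"), ("trout", "net"),
                               ("apple", "cashier")]})
ASSOCIATE_PAIRS = {
    "lorry": "hammer", "bus": "cashier", "car": "glove", "tram": "cashier",
    "deer": "hunter", "horse": "rope", "trout": "net", "bee": "rose",
    "apple": "cashier", "oak": "saw", "fern": "trout", "rose": "duchess",
    "hammer": "lorry", "saw": "oak", "rope": "horse", "net": "trout",
    "boot": "hunter", "scarf": "duchess", "glove": "car",
    "hunter": "deer", "cashier": "apple", "duchess": "scarf",
}


class TopicGenerationError(RuntimeError):
    """Raised when the topic constructor cannot satisfy its constraints."""


@dataclass(frozen=True)
class Topic:
    id: int
    name: str
    members: np.ndarray  # concept ids, shape (m,)
    probs: np.ndarray  # selection probabilities, shape (m,), sums to 1
    homonym_sense: dict[int, int]  # concept id -> 0 (dominant) / 1 (subordinate)
    base_weight: float


@dataclass(frozen=True)
class TopicConfig:
    freq_ratio: float = 17.0  # target max/min word frequency ratio
    rate_dominant: float = 0.077  # target probe->target co-occurrence, dominant
    rate_subordinate: float = 0.033  # ... subordinate
    associate_strength: float = 0.028  # target A for designated associate pairs
    associate_strength_strong: float = 0.085  # ... for the strong tail
    subordinate_share: float = 0.25  # homonym exposure share of subordinate sense
    calibration_rounds: int = 24
    heavy_weights: tuple[float, ...] = (10.0, 10.0, 10.0, 10.0, 5.0, 5.0, 5.0, 5.0)


def _role_weight(role: str) -> float:
    return {"core": _CORE, "reg": _REG, "occ": _OCC}[role]


def build_topics(vocab: list[Concept], config: TopicConfig | None = None,
                 rng: np.random.Generator | None = None) -> list[Topic]:
    """Build and calibrate the 35 topics.

    The constructor is deterministic; ``rng`` is accepted for interface
    symmetry but not consumed.  Raises :class:`TopicGenerationError` if any
    structural invariant fails after calibration.
    """
    config = config or TopicConfig()
    by_label = {c.label: c for c in vocab}
    n_words = len(vocab)

    names, weights, member_ids, role_mats, sense_maps = [], [], [], [], []
    for name, w, roles, senses in _T:
        ids = np.array([by_label[lbl].id for lbl in roles], dtype=np.int64)
        rw = np.array([_role_weight(r) for r in roles.values()], dtype=float)
        names.append(name)
        weights.append(float(w))
        member_ids.append(ids)
        role_mats.append(rw)
        sense_maps.append({by_label[h].id: s for h, s in senses.items()})

    # boosts adjusted during calibration: link_boost scales the designated
    # target's weight inside the probe's sense topics; share_boost scales the
    # probe's own weight inside its subordinate-sense topics
    link_boost = {lbl: [1.0, 1.0] for lbl in HOMONYM_TRIALS}
    share_boost = {lbl: 1.0 for lbl in HOMONYM_TRIALS}
    masses = np.ones(n_words)

    assoc_pairs = sorted({frozenset((by_label[a].id, by_label[b].id))
                          for a, b in ASSOCIATE_PAIRS.items()},
                         key=sorted)
    assoc_boost = {p: 1.0 for p in assoc_pairs}

    def current_probs() -> list[np.ndarray]:
        out = []
        for t, ids in enumerate(member_ids):
            w = role_mats[t] * masses[ids]
            for probe_lbl, (dom_t, sub_t) in HOMONYM_TRIALS.items():
                pid = by_label[probe_lbl].id
                if pid in sense_maps[t]:
                    sense = sense_maps[t][pid]
                    tid = by_label[dom_t if sense == 0 else sub_t].id
                    sel = ids == tid
                    if sel.any():
                        w = np.where(sel, w * link_boost[probe_lbl][sense], w)
                    if sense == 1:
                        w = np.where(ids == pid, w * share_boost[probe_lbl], w)
            for pair in assoc_pairs:
                a, b = tuple(pair)
                if (ids == a).any() and (ids == b).any():
                    s = np.sqrt(assoc_boost[pair])
                    w = np.where((ids == a) | (ids == b), w * s, w)
            out.append(w / w.sum())
        return out

    wt = np.asarray(weights)
    wt_norm = wt / wt.sum()

    def freq_of(probs: list[np.ndarray]) -> np.ndarray:
        f = np.zeros(n_words)
        for t, ids in enumerate(member_ids):
            f[ids] += wt_norm[t] * probs[t]
        return f

    def coocc_rate(probs, probe: int, target: int) -> float:
        # denominator over *all* probe occurrences, as in the corpus statistic
        num = den = 0.0
        for t, ids in enumerate(member_ids):
            pos_p = np.nonzero(ids == probe)[0]
            if pos_p.size == 0:
                continue
            p_h = probs[t][pos_p[0]]
            den += wt_norm[t] * p_h
            pos_t = np.nonzero(ids == target)[0]
            if pos_t.size:
                num += wt_norm[t] * p_h * probs[t][pos_t[0]]
        return 0.8 * num / den if den > 0 else 0.0

    def sub_share(probs, probe: int) -> float:
        tot = sub = 0.0
        for t, ids in enumerate(member_ids):
            pos_p = np.nonzero(ids == probe)[0]
            if pos_p.size == 0:
                continue
            contrib = wt_norm[t] * probs[t][pos_p[0]]
            tot += contrib
            if sense_maps[t].get(probe) == 1:
                sub += contrib
        return sub / tot if tot > 0 else 0.0

    # --- calibration: word masses toward the target frequency spread, link
    # boosts toward the target homonym co-occurrence rates -------------------
    for _ in range(config.calibration_rounds):
        probs = current_probs()
        f = freq_of(probs)
        ratio = f.max() / f.min()
        alpha = np.log(config.freq_ratio) / np.log(ratio)
        target = np.exp(alpha * (np.log(f) - np.log(f.max()))) * f.max()
        masses *= (target / f) ** 0.6
        masses /= masses.mean()
        for probe_lbl, (dom_t, sub_t) in HOMONYM_TRIALS.items():
            pid = by_label[probe_lbl].id
            share = sub_share(probs, pid)
            if share > 0:
                share_boost[probe_lbl] = float(np.clip(
                    share_boost[probe_lbl]
                    * (config.subordinate_share / share) ** 0.6, 0.5, 30.0))
            for sense, (tgt_lbl, goal) in enumerate(
                [(dom_t, config.rate_dominant), (sub_t, config.rate_subordinate)]
            ):
                r = coocc_rate(probs, pid, by_label[tgt_lbl].id)
                if r > 0:
                    link_boost[probe_lbl][sense] = float(np.clip(
                        link_boost[probe_lbl][sense] * (goal / r) ** 0.6,
                        0.5, 10.0))
        strong_ids = {frozenset(by_label[l].id for l in p)
                      for p in ASSOCIATE_STRONG}
        for pair in assoc_pairs:
            a, b = tuple(pair)
            A = 0.5 * (coocc_rate(probs, a, b) + coocc_rate(probs, b, a))
            goal = config.associate_strength_strong if pair in strong_ids \
                else config.associate_strength
            if A > 0:
                assoc_boost[pair] = float(np.clip(
                    assoc_boost[pair] * (goal / A) ** 0.4, 0.6, 3.0))

    probs = current_probs()
    topics = [
        Topic(t, names[t], member_ids[t], probs[t], sense_maps[t], weights[t])
        for t in range(len(names))
    ]
    _validate(topics, vocab, config)
    return topics


def _validate(topics: list[Topic], vocab: list[Concept], config: TopicConfig) -> None:
    if len(topics) != 35:
        raise TopicGenerationError(f"{len(topics)} topics != 35")
    heavy = sorted(t.base_weight for t in topics if t.base_weight > 1)
    if heavy != sorted(config.heavy_weights):
        raise TopicGenerationError(f"heavy-topic weights {heavy}")
    abstract_only = 0
    appearances: dict[int, int] = {c.id: 0 for c in vocab}
    sense_groups: dict[int, dict[int, set[int]]] = {
        c.id: {0: set(), 1: set()} for c in vocab if c.cls == HOMONYM
    }
    for t in topics:
        if not 10 <= len(t.members) <= 19:
            raise TopicGenerationError(f"topic {t.name}: {len(t.members)} members")
        if abs(t.probs.sum() - 1.0) > 1e-9:
            raise TopicGenerationError(f"topic {t.name}: probs sum {t.probs.sum()}")
        if all(vocab[m].cls == ABSTRACT for m in t.members):
            abstract_only += 1
        for m in t.members:
            appearances[int(m)] += 1
            if vocab[m].cls == HOMONYM:
                if int(m) not in t.homonym_sense:
                    raise TopicGenerationError(
                        f"topic {t.name}: homonym {vocab[m].label} lacks a sense"
                    )
                sense_groups[int(m)][t.homonym_sense[int(m)]].add(t.id)
    if abstract_only != 2:
        raise TopicGenerationError(f"{abstract_only} abstract-only topics != 2")
    lacking = [vocab[c].label for c, n in appearances.items() if n < 3]
    if lacking:
        raise TopicGenerationError(f"concepts in < 3 topics: {lacking}")
    for cid, groups in sense_groups.items():
        if groups[0] & groups[1]:
            raise TopicGenerationError(
                f"homonym {vocab[cid].label}: sense topic groups overlap"
            )
        if not groups[0] or not groups[1]:
            raise TopicGenerationError(
                f"homonym {vocab[cid].label}: missing a sense topic group"
            )


# --- analytic corpus statistics (no sampling) ------------------------------

def expected_frequencies(topics: list[Topic], n_words: int = 64) -> np.ndarray:
    """Expected per-stimulus selection probability of each word."""
    wt = np.array([t.base_weight for t in topics])
    wt = wt / wt.sum()
    f = np.zeros(n_words)
    for t, topic in enumerate(topics):
        f[topic.members] += wt[t] * topic.probs
    return f


def expected_cooccurrence_rate(topics: list[Topic], probe: int, target: int,
                               sense: int | None = None) -> float:
    """Expected P(next stimulus is ``target`` | current is ``probe``).

    Within an episode only 4 of 5 positions have a successor, hence the 0.8
    factor.  If ``sense`` is given, only topics using that sense of a homonym
    probe contribute.
    """
    wt = np.array([t.base_weight for t in topics])
    wt = wt / wt.sum()
    num = den = 0.0
    for t, topic in enumerate(topics):
        pos_p = np.nonzero(topic.members == probe)[0]
        if pos_p.size == 0:
            continue
        if sense is not None and topic.homonym_sense.get(probe) != sense:
            continue
        p_h = topic.probs[pos_p[0]]
        den += wt[t] * p_h
        pos_t = np.nonzero(topic.members == target)[0]
        if pos_t.size:
            num += wt[t] * p_h * topic.probs[pos_t[0]]
    return 0.8 * num / den if den > 0 else 0.0
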