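"""The three neuropsychological simulations and the representational
analyses of the trained network.

* Homonym comprehension (2 dominance x 3 cue forced choice, intact vs.
  control-damaged, plus the alternative-damage grid and the static-weight
  ablation of the controlled-retrieval mechanism).
* Synonym judgment over all 54 non-homonym words, with regressions of
  per-trial accuracy on frequency, imageability and semantic diversity
  under representational (hub-lesion) vs. control damage.
* Taxonomic vs. associative matching over the concrete vocabulary.
* Context-averaged hub representations, representational consistency,
  acquired embodiment of abstract words, and context-sensitivity probes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .control import (RetrievalConfig, SelectionConfig, Trial,
                      run_trials_batch, set_context_from_cue)
from .corpus_stats import CorpusStats, cooccurrence_rate
from .lesion import LesionSpec, intact_spec, lesion_hub_links, make_sa_damage
from .network import (StimulusFrame, WeightSet, copy_context, random_context,
                      settle)
from .stats import hierarchical_step, ols_standardized, rm_anova
from .topics import ASSOCIATE_PAIRS, HOMONYM_TRIALS, Topic
from .vocabulary import ABSTRACT, CONCRETE, HOMONYM, Concept, SMFeatureMap

__all__ = ["ExperimentConfig", "build_sim1_trials", "build_sim2_trials",
           "build_sim3_trials", "run_sim1", "run_sim2", "run_sim3",
           "context_averaged_representations", "representational_consistency",
           "acquired_embodiment_probe", "context_sensitivity_demo",
           "RepresentationMatrix"]


class TrialConstructionError(RuntimeError):
    """No qualifying target/foil could be found on this corpus."""


@dataclass(frozen=True)
class ExperimentConfig:
    reps_per_model: int = 20  # presentations per trial per model (intact/SA)
    n_lesions: int = 20  # hub lesions per model (SD)
    reps_per_lesion: int = 1
    hub_fraction: float = 0.30
    representation_repeats: int = 50  # distance-matrix averaging


# ---------------------------------------------------------------------------
# trial construction
# ---------------------------------------------------------------------------

def _topic_membership(topics: list[Topic] | None) -> dict[int, set[int]]:
    out: dict[int, set[int]] = {}
    for t in topics or []:
        for m in t.members:
            out.setdefault(int(m), set()).add(t.id)
    return out


def _zero_coocc_foils(stats: CorpusStats, probe: int, n: int,
                      exclude: set[int], category_of: dict[int, int | None],
                      probe_category: int | None = None,
                      membership: dict[int, set[int]] | None = None,
                      target: int | None = None) -> list[int]:
    """Unrelated foils: never adjacent to the probe in the corpus (either
    direction), from a different category where one applies, and - when
    topic membership is supplied - sharing no topic with the probe, the
    target, or (where satisfiable) each other; mutually related foils
    would form a coalition during controlled retrieval.  Deterministic
    rotation so different probes draw different foils."""
    n_words = stats.freq.size
    membership = membership or {}
    probe_topics = membership.get(probe, set())
    target_topics = membership.get(target, set()) if target is not None \
        else set()

    def search(mutually_disjoint: bool) -> list[int]:
        cands: list[int] = []
        taken_topics: set[int] = set()
        for off in range(n_words):
            w = (probe * 7 + 11 + off) % n_words
            if w == probe or w in exclude:
                continue
            if stats.next_counts[probe, w] or stats.next_counts[w, probe]:
                continue
            if probe_category is not None \
                    and category_of.get(w) == probe_category:
                continue
            wt = membership.get(w, set())
            if wt & probe_topics or wt & target_topics:
                continue
            if mutually_disjoint and wt & taken_topics:
                continue
            cands.append(w)
            taken_topics |= wt
            if len(cands) == n:
                return cands
        return cands

    cands = search(mutually_disjoint=True)
    if len(cands) < n:  # relax the foil-foil constraint if unsatisfiable
        cands = search(mutually_disjoint=False)
    if len(cands) == n:
        return cands
    raise TrialConstructionError(
        f"only {len(cands)} qualifying foils for probe {probe}")


def _sense_topics(topics: list[Topic], probe: int, sense: int) -> list[Topic]:
    return [t for t in topics if t.homonym_sense.get(probe) == sense]


def _sense_associate(topics: list[Topic], probe: int, sense: int,
                     exclude: set[int]) -> int:
    """Strongest co-member of the probe's sense-specific topics."""
    score: dict[int, float] = {}
    for t in _sense_topics(topics, probe, sense):
        for m, p in zip(t.members, t.probs):
            m = int(m)
            if m != probe and m not in exclude:
                score[m] = score.get(m, 0.0) + t.base_weight * float(p)
    if not score:
        raise TrialConstructionError(f"no cue candidate for probe {probe}")
    return max(score, key=score.get)


def build_sim1_trials(vocab: list[Concept], stats: CorpusStats,
                      topics: list[Topic]) -> list[Trial]:
    """Two 4-option trials per homonym (dominant- and subordinate-sense
    targets, three zero-co-occurrence foils, cue and miscue words)."""
    by = {c.label: c.id for c in vocab}
    category_of = {c.id: c.category for c in vocab}
    trials = []
    for probe_lbl, (dom_lbl, sub_lbl) in HOMONYM_TRIALS.items():
        probe = by[probe_lbl]
        dom, sub = by[dom_lbl], by[sub_lbl]
        r_dom = cooccurrence_rate(stats, probe, dom)
        r_sub = cooccurrence_rate(stats, probe, sub)
        if not r_dom > r_sub > 0:
            raise TrialConstructionError(
                f"{probe_lbl}: dominance ordering violated "
                f"({r_dom:.3f} vs {r_sub:.3f}); regenerate the corpus")
        membership = _topic_membership(topics)
        for target, dominance in ((dom, "dominant"), (sub, "subordinate")):
            foils = _zero_coocc_foils(stats, probe, 3,
                                      exclude={dom, sub},
                                      category_of=category_of,
                                      membership=membership, target=target)
            options = (target, *foils)
            used = {probe, dom, sub, *foils}
            app_sense = 0 if dominance == "dominant" else 1
            cue = _sense_associate(topics, probe, app_sense, used)
            miscue = _sense_associate(topics, probe, 1 - app_sense,
                                      used | {cue})
            trials.append(Trial(probe, options, 0, dominance=dominance,
                                cue=cue, miscue=miscue))
    return trials


def build_sim2_trials(vocab: list[Concept], stats: CorpusStats,
                      topics: list[Topic] | None = None) -> list[Trial]:
    """One 3-option synonym-judgment trial per non-homonym word.

    Concrete probes take the same-category word with the highest forward
    co-occurrence as target; abstract probes take their pair partner.
    Foils never co-occur with the probe, come from other categories and
    (when topics are supplied) share no topic with probe or target.
    """
    category_of = {c.id: c.category for c in vocab}
    membership = _topic_membership(topics)
    trials = []
    for c in vocab:
        if c.cls == HOMONYM:
            continue
        if c.cls == CONCRETE:
            mates = [d.id for d in vocab
                     if d.cls == CONCRETE and d.category == c.category
                     and d.id != c.id]
            target = max(mates, key=lambda m: stats.next_counts[c.id, m]
                         + stats.next_counts[m, c.id])
            probe_cat = c.category
        else:
            target = next(d.id for d in vocab
                          if d.cls == ABSTRACT and d.pair_id == c.pair_id
                          and d.id != c.id)
            probe_cat = None
        foils = _zero_coocc_foils(stats, c.id, 2, exclude={target},
                                  category_of=category_of,
                                  probe_category=probe_cat,
                                  membership=membership, target=target)
        trials.append(Trial(c.id, (target, *foils), 0))
    if len(trials) != 54:
        raise TrialConstructionError(f"{len(trials)} trials != 54")
    return trials


def build_sim3_trials(vocab: list[Concept], stats: CorpusStats,
                      sim2_trials: list[Trial],
                      topics: list[Topic] | None = None,
                      ) -> tuple[list[Trial], list[Trial]]:
    """Taxonomic set (the 22 concrete synonym trials) and a 22-trial
    associative set whose 4-option targets are cross-category associates."""
    by = {c.label: c.id for c in vocab}
    concrete = {c.id for c in vocab if c.cls == CONCRETE}
    category_of = {c.id: c.category for c in vocab}
    membership = _topic_membership(topics)
    taxonomic = [t for t in sim2_trials if t.probe in concrete]
    for t in taxonomic:
        object.__setattr__(t, "relation", "taxonomic")
    associative = []
    for c in vocab:
        if c.cls != CONCRETE:
            continue
        target = by[ASSOCIATE_PAIRS[c.label]]
        if category_of[target] == c.category:
            raise TrialConstructionError(
                f"associate of {c.label} shares its category")
        foils = _zero_coocc_foils(stats, c.id, 3, exclude={target},
                                  category_of=category_of,
                                  probe_category=c.category,
                                  membership=membership, target=target)
        associative.append(Trial(c.id, (target, *foils), 0,
                                 relation="associative"))
    return taxonomic, associative


# ---------------------------------------------------------------------------
# running simulations
# ---------------------------------------------------------------------------

def _accuracy_by_trial(models: list[WeightSet], trials: list[Trial],
                       spec: LesionSpec, rng: np.random.Generator,
                       config: ExperimentConfig,
                       cue_attr: str | None = None) -> np.ndarray:
    """(n_models_or_instances, n_trials) accuracy array.

    For hub-lesion specs each model is lesioned ``config.n_lesions`` times
    and each instance contributes ``config.reps_per_lesion`` presentations;
    otherwise each model contributes ``config.reps_per_model``.
    ``cue_attr`` in {"cue", "miscue"} settles the cue word first and uses
    the copied hub state as context.
    """
    out = []
    for m in models:
        if spec.kind == "hub_links":
            instances = [lesion_hub_links(m, spec.hub_fraction, rng)
                         for _ in range(config.n_lesions)]
            reps = config.reps_per_lesion
        else:
            instances = [m]
            reps = config.reps_per_model
        accs = np.zeros(len(trials))
        total = 0
        for inst in instances:
            if cue_attr is None:
                ctx = None
            else:
                ctx_rows = []
                for t in trials:
                    cue = getattr(t, cue_attr)
                    ctx_rows.append(set_context_from_cue(inst, cue, rng,
                                                         batch=reps))
                ctx = np.concatenate(ctx_rows, axis=0)
            accs += run_trials_batch(inst, trials, spec.retrieval,
                                     spec.selection, rng, reps,
                                     contexts=ctx) * reps
            total += reps
        out.append(accs / total)
    return np.asarray(out)


def run_sim1(models: list[WeightSet], trials: list[Trial],
             rng: np.random.Generator,
             config: ExperimentConfig | None = None,
             with_anova: bool = True,
             extra_specs: dict[str, LesionSpec] | None = None,
             ) -> dict:
    """Homonym comprehension: intact vs. control damage across cue types.

    Returns {"cells": DataFrame(model, impairment, dominance, cue, accuracy),
    "anova": effect table or None, "extra": {name: DataFrame}} where
    ``extra_specs`` may add the alternative-damage grid / static ablation.
    """
    config = config or ExperimentConfig()
    specs = {"intact": intact_spec(), "damaged": make_sa_damage(1)}

    def _collect(name, spec):
        rows = []
        for cue_kind, attr in (("correct", "cue"), ("miscue", "miscue"),
                               ("none", None)):
            acc = _accuracy_by_trial(models, trials, spec, rng, config,
                                     cue_attr=attr)
            for mi in range(acc.shape[0]):
                for ti, t in enumerate(trials):
                    rows.append(dict(impairment=name, model=mi,
                                     dominance=t.dominance, cue=cue_kind,
                                     trial=ti, accuracy=acc[mi, ti]))
        return pd.DataFrame(rows)

    cells = pd.concat([_collect(name, spec)
                       for name, spec in specs.items()], ignore_index=True)

    anova = None
    if with_anova and len(models) >= 3:
        agg = (cells.groupby(["model", "impairment", "dominance", "cue"])
               ["accuracy"].mean().reset_index())
        anova = rm_anova(agg, "accuracy", "model",
                         ["impairment", "dominance", "cue"])

    extra = {name: _collect(name, spec)
             for name, spec in (extra_specs or {}).items()}
    return {"cells": cells, "anova": anova, "extra": extra}


def sim1_damage_grid() -> dict[str, LesionSpec]:
    """Alternative forms of damage: controlled retrieval removed only,
    selection noise raised only, hub links lesioned, and the static
    option-weighting ablation of the intact model."""
    return {
        "no_cr_only": LesionSpec("control",
                                 retrieval=RetrievalConfig("none"),
                                 selection=SelectionConfig(0.01)),
        "noise_only": LesionSpec("control",
                                 retrieval=RetrievalConfig("controlled"),
                                 selection=SelectionConfig(0.045)),
        "hub_lesion": LesionSpec("hub_links", hub_fraction=0.30,
                                 retrieval=RetrievalConfig("controlled"),
                                 selection=SelectionConfig(0.01)),
        "static_weights": LesionSpec("control",
                                     retrieval=RetrievalConfig("static"),
                                     selection=SelectionConfig(0.01)),
    }


def run_sim2(models: list[WeightSet], trials: list[Trial],
             stats: CorpusStats, vocab: list[Concept],
             rng: np.random.Generator,
             config: ExperimentConfig | None = None) -> dict:
    """Synonym judgment under intact, control-damage and hub-damage
    conditions, with the psycholinguistic regressions."""
    config = config or ExperimentConfig()
    specs = {
        "intact": intact_spec(),
        "SA": make_sa_damage(2),
        "SD": LesionSpec("hub_links", hub_fraction=config.hub_fraction,
                         retrieval=RetrievalConfig("controlled"),
                         selection=SelectionConfig(0.01)),
    }
    probes = np.array([t.probe for t in trials])
    logf = np.log(stats.freq[probes])
    image = np.array([vocab[p].cls == CONCRETE for p in probes], dtype=float)
    semd = stats.semd[probes]
    coocc = np.array([cooccurrence_rate(stats, t.probe,
                                        t.options[t.correct])
                      for t in trials])
    preds = {"frequency": logf, "imageability": image, "semd": semd}

    out = {"trial_props": pd.DataFrame({**preds, "coocc": coocc,
                                        "probe": probes})}
    acc_by = {}
    for name, spec in specs.items():
        acc = _accuracy_by_trial(models, trials, spec, rng, config)
        acc_by[name] = acc
        per_trial = acc.mean(axis=0)
        out[name] = {
            "per_trial": per_trial,
            "overall": float(per_trial.mean()),
        }
        if name != "intact":
            out[name]["regression"] = ols_standardized(per_trial, preds)
            out[name]["hierarchical"] = hierarchical_step(
                per_trial, preds, {"coocc": coocc})
    out["accuracy_arrays"] = acc_by
    return out


def run_sim3(models: list[WeightSet], taxonomic: list[Trial],
             associative: list[Trial], rng: np.random.Generator,
             config: ExperimentConfig | None = None) -> pd.DataFrame:
    """Accuracy per (damage condition x relation type)."""
    config = config or ExperimentConfig()
    specs = {
        "intact": intact_spec(),
        "SA": make_sa_damage(3),
        "SD": LesionSpec("hub_links", hub_fraction=config.hub_fraction,
                         retrieval=RetrievalConfig("controlled"),
                         selection=SelectionConfig(0.01)),
    }
    rows = []
    for name, spec in specs.items():
        for rel, trials in (("taxonomic", taxonomic),
                            ("associative", associative)):
            acc = _accuracy_by_trial(models, trials, spec, rng, config)
            rows.append(dict(condition=name, relation=rel,
                             accuracy=float(acc.mean())))
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# representational analyses
# ---------------------------------------------------------------------------

@dataclass
class RepresentationMatrix:
    vectors: np.ndarray  # (64, n_hub) context-averaged hub states
    similarity: np.ndarray  # (64, 64) mean pairwise correlation matrix
    consistency: np.ndarray  # (64,) mean pairwise r across contexts


def _corr_matrix(X: np.ndarray) -> np.ndarray:
    Xc = X - X.mean(axis=1, keepdims=True)
    norm = np.linalg.norm(Xc, axis=1)
    norm[norm == 0] = 1.0
    Xn = Xc / norm[:, None]
    return Xn @ Xn.T


def context_averaged_representations(weights: WeightSet,
                                     rng: np.random.Generator,
                                     repeats: int = 50,
                                     ) -> RepresentationMatrix:
    """Context-independent hub representations.

    Each word is presented after each of the 64 words of the vocabulary
    (the context word is settled from a random initial context and its hub
    state copied); hub states are averaged over the 64 contexts, a pairwise
    correlation matrix is computed, and the whole procedure is repeated
    with fresh random contexts, averaging the matrices.
    """
    arch = weights.arch
    n = arch.n_verbal
    sim_sum = np.zeros((n, n))
    vec_sum = np.zeros((n, arch.n_hub))
    cons_sum = np.zeros(n)
    all_words = np.arange(n)
    for _ in range(repeats):
        ctx_frame = StimulusFrame.word(arch, all_words,
                                       random_context(rng, arch, n))
        contexts = copy_context(settle(weights, ctx_frame))  # (64 ctx, hub)
        # rows: context index varies fastest within each target word
        targets = np.repeat(all_words, n)
        ctx_tiled = np.tile(contexts, (n, 1))
        frame = StimulusFrame.word(arch, targets, ctx_tiled)
        hub = settle(weights, frame).final_hub().reshape(n, n, arch.n_hub)
        mean_vecs = hub.mean(axis=1)
        vec_sum += mean_vecs
        sim_sum += _corr_matrix(mean_vecs)
        for w in range(n):
            c = _corr_matrix(hub[w])
            iu = np.triu_indices(n, 1)
            cons_sum[w] += c[iu].mean()
    return RepresentationMatrix(vec_sum / repeats, sim_sum / repeats,
                                cons_sum / repeats)


def representational_consistency(weights: WeightSet, word: int,
                                 rng: np.random.Generator,
                                 repeats: int = 1) -> float:
    """Mean pairwise correlation of one word's hub states across the 64
    single-word contexts."""
    arch = weights.arch
    n = arch.n_verbal
    vals = []
    for _ in range(repeats):
        ctx_frame = StimulusFrame.word(arch, np.arange(n),
                                       random_context(rng, arch, n))
        contexts = copy_context(settle(weights, ctx_frame))
        frame = StimulusFrame.word(arch, np.full(n, word), contexts)
        hub = settle(weights, frame).final_hub()
        c = _corr_matrix(hub)
        iu = np.triu_indices(n, 1)
        vals.append(c[iu].mean())
    return float(np.mean(vals))


def acquired_embodiment_probe(weights: WeightSet, word: int,
                              fmap: SMFeatureMap,
                              rng: np.random.Generator, reps: int = 50,
                              context_word: int | None = None) -> dict:
    """Mean S-M activation, summarized per category-shared feature group.

    With ``context_word`` the word is presented immediately after it;
    otherwise after ``reps`` random context patterns.
    """
    arch = weights.arch
    if context_word is None:
        ctx = random_context(rng, arch, reps)
    else:
        cf = StimulusFrame.word(arch, np.full(reps, context_word),
                                random_context(rng, arch, reps))
        ctx = copy_context(settle(weights, cf))
    frame = StimulusFrame.word(arch, np.full(reps, word), ctx)
    sm = settle(weights, frame).sm[-1].mean(axis=0)
    shared = {cat: sm[sorted(idx)].mean()
              for cat, idx in fmap.shared.items()}
    return {"profile": sm, "shared_by_category": shared}


def mds_embedding(similarity: np.ndarray, n_components: int = 2,
                  seed: int = 0) -> np.ndarray:
    """2-D embedding of a similarity matrix (plotting convenience only;
    analyses operate on the similarity/distance matrices themselves)."""
    from sklearn.manifold import MDS

    dist = 1.0 - similarity
    np.fill_diagonal(dist, 0.0)
    mds = MDS(n_components=n_components, dissimilarity="precomputed",
              random_state=seed, normalized_stress="auto")
    return mds.fit_transform(dist)


def context_sensitivity_demo(weights: WeightSet, probe: int,
                             context_words: list[int | None],
                             rng: np.random.Generator,
                             reps: int = 50) -> dict:
    """Mean prediction profile and hub state of ``probe`` after each
    context word (None = novel random context)."""
    arch = weights.arch
    out = {}
    for cw in context_words:
        if cw is None:
            ctx = random_context(rng, arch, reps)
        else:
            cf = StimulusFrame.word(arch, np.full(reps, cw),
                                    random_context(rng, arch, reps))
            ctx = copy_context(settle(weights, cf))
        traj = settle(weights, StimulusFrame.word(arch, np.full(reps, probe),
                                                  ctx))
        out[cw] = {"prediction": traj.final_prediction().mean(axis=0),
                   "hub": traj.final_hub().mean(axis=0)}
    return out
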