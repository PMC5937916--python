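"""Training: targets, losses, backpropagation through settling, and the
norm-bounded momentum optimizer.

After each stimulus the network is trained, during the final two time steps
(8 ticks), to predict the next word in the episode (Kullback-Leibler
divergence on the softmax prediction pool) and - for concrete or homonym
*word* inputs - to activate the item's sensory-motor features (cross-entropy
on the S-M pool).  Episode-final stimuli carry no prediction target;
abstract words and directly-presented S-M patterns carry no S-M target.

Gradients are exact, obtained by unrolling the 28 synchronous ticks in
reverse; the context copy between stimuli is a buffer, not a connection, so
backpropagation truncates at stimulus boundaries.  Error derivatives are
accumulated over 100 episodes; the pre-momentum weight step is scaled to a
Euclidean norm of at most one before the momentum term is added ("Doug's
momentum"), and a multiplicative decay of 1e-6 applies at every update.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .corpus import Corpus
from .network import (RESTING, Architecture, SettlingTrajectory, StimulusFrame,
                      WeightSet, copy_context, init_network, logistic, settle)
from .vocabulary import ABSTRACT, CONCRETE, HOMONYM, Concept, SMFeatureMap

__all__ = ["TargetFrame", "TrainingConfig", "OptimizerState", "make_targets",
           "loss", "backprop_through_settling", "apply_update", "train_model",
           "train_ensemble", "sm_patterns"]

_EPS = 1e-7  # cross-entropy clipping


@dataclass
class TargetFrame:
    """Batched targets for one stimulus presentation.

    ``prediction``: (B,) int word ids, -1 where absent (episode-final).
    ``sm``: (B, n_sm) feature patterns, used only where ``has_sm`` is True.
    """

    prediction: np.ndarray
    sm: np.ndarray | None = None
    has_sm: np.ndarray | None = None


@dataclass(frozen=True)
class TrainingConfig:
    learning_rate: float = 0.1
    momentum: float = 0.9
    step_norm_bound: float = 1.0  # pre-momentum step, global Euclidean norm
    weight_decay: float = 1e-6  # multiplicative, every update
    episodes_per_update: int = 100
    n_passes: int = 5
    n_streams: int = 1  # parallel continuous streams (1 = published schedule)
    dtype: str = "float64"


@dataclass
class OptimizerState:
    grads: dict[str, np.ndarray]
    prev_step: dict[str, np.ndarray]
    n_updates: int = 0
    episodes_accumulated: int = 0

    @classmethod
    def for_weights(cls, weights: WeightSet) -> "OptimizerState":
        return cls({k: np.zeros_like(v) for k, v in weights.w.items()},
                   {k: np.zeros_like(v) for k, v in weights.w.items()})


def sm_patterns(vocab: list[Concept], fmap: SMFeatureMap,
                dtype=np.float64) -> np.ndarray:
    """(64, 2, n_sm) binary S-M patterns per concept and sense.

    Abstract concepts map to all-zero rows (never used as clamps/targets);
    concrete concepts repeat their single pattern in both sense slots.
    """
    n_sm = 162
    out = np.zeros((len(vocab), 2, n_sm), dtype=dtype)
    for c in vocab:
        if c.cls == CONCRETE:
            idx = sorted(fmap.features(c.id, 0))
            out[c.id, 0, idx] = 1.0
            out[c.id, 1, idx] = 1.0
        elif c.cls == HOMONYM:
            for s in (0, 1):
                out[c.id, s, sorted(fmap.features(c.id, s))] = 1.0
    return out


def make_targets(episode, position: int, vocab: list[Concept],
                 patterns: np.ndarray) -> TargetFrame:
    """Targets for the stimulus at ``position`` (0-4) of a single episode."""
    if position >= 5:
        raise ValueError("position must be < 5")
    cid = int(episode.concepts[position])
    pred = -1 if position == 4 else int(episode.concepts[position + 1])
    c = vocab[cid]
    is_word = bool(episode.verbal[position])
    has_sm = is_word and c.cls in (CONCRETE, HOMONYM)
    sm = patterns[cid, int(episode.senses[position])][None, :] if has_sm else \
        np.zeros((1, patterns.shape[2]))
    return TargetFrame(np.array([pred]), sm, np.array([has_sm]))


def loss(trajectory: SettlingTrajectory, targets: TargetFrame,
         arch: Architecture | None = None) -> float:
    """Summed loss over the target window (the last 8 ticks)."""
    arch = arch or Architecture()
    per = _loss_per_row(trajectory, targets, arch)
    return float(per.sum())


def _loss_per_row(trajectory, targets, arch) -> np.ndarray:
    T = trajectory.n_ticks
    W = arch.target_ticks
    B = trajectory.hub.shape[1]
    out = np.zeros(B)
    has_pred = targets.prediction >= 0
    rows = np.nonzero(has_pred)[0]
    for k in range(T - W + 1, T + 1):
        if rows.size:
            p = trajectory.prediction[k][rows, targets.prediction[rows]]
            out[rows] += -np.log(np.clip(p, _EPS, None))
        if targets.has_sm is not None and targets.has_sm.any():
            srows = np.nonzero(targets.has_sm)[0]
            a = np.clip(trajectory.sm[k][srows], _EPS, 1 - _EPS)
            t = targets.sm[srows]
            out[srows] += -(t * np.log(a) + (1 - t) * np.log1p(-a)).sum(axis=1)
    return out


def backprop_through_settling(weights: WeightSet, frame: StimulusFrame,
                              targets: TargetFrame,
                              trajectory: SettlingTrajectory | None = None,
                              ) -> tuple[float, dict[str, np.ndarray]]:
    """Loss and exact gradients w.r.t. every unmasked weight.

    Unrolls all 28 ticks in reverse.  Clamped pools block gradient flow and
    the (constant-within-stimulus) context clamp contributes only through
    the context->hub weights.
    """
    arch = weights.arch
    dt = arch.dt
    T = arch.n_ticks
    if trajectory is None or trajectory.net_hub is None:
        trajectory = settle(weights, frame, record=True)
    hub, sm, pred = trajectory.hub, trajectory.sm, trajectory.prediction
    nh, ns = trajectory.net_hub, trajectory.net_sm
    B = frame.batch
    window_start = T - arch.target_ticks + 1

    Whh = weights.effective("hh")
    Whs = weights.effective("hs")
    Whp = weights.effective("hp")
    Wsh = weights.effective("sh")
    W_hub_out_T = np.concatenate([Whh, Whs, Whp], axis=1).T

    sm_free = np.ones(B, dtype=bool) if frame.sm_clamp is None \
        else ~frame.sm_clamp
    has_pred = targets.prediction >= 0
    prows = np.nonzero(has_pred)[0]
    srows = np.nonzero(targets.has_sm)[0] if targets.has_sm is not None \
        else np.array([], dtype=int)

    gH = np.zeros_like(hub[0])
    gS = np.zeros_like(sm[0])
    gz = np.zeros_like(pred[0])
    gnh_all = np.zeros((T, B, arch.n_hub), dtype=hub.dtype)
    gns_all = np.zeros((T, B, arch.n_sm), dtype=hub.dtype)
    gz_all = np.zeros((T, B, arch.n_prediction), dtype=hub.dtype)

    total_loss = 0.0
    for k in range(T, 0, -1):
        # direct loss terms at tick k
        if k >= window_start:
            if prows.size:
                p = pred[k][prows]
                tgt = targets.prediction[prows]
                total_loss += float(-np.log(
                    np.clip(p[np.arange(prows.size), tgt], _EPS, None)).sum())
                g = p.copy()
                g[np.arange(prows.size), tgt] -= 1.0
                gz[prows] += g
            if srows.size:
                a = sm[k][srows]
                t = targets.sm[srows]
                ac = np.clip(a, _EPS, 1 - _EPS)
                total_loss += float(
                    -(t * np.log(ac) + (1 - t) * np.log1p(-ac)).sum())
                gS[srows] += (ac - t) / (ac * (1 - ac))
        # recurrences: tick k quantities were produced at loop index k-1
        j = k - 1
        sig_h = logistic(nh[j])
        gnh = gH * (dt * sig_h * (1 - sig_h))
        sig_s = logistic(ns[j])
        gns = gS * (dt * sig_s * (1 - sig_s))
        gns[~sm_free] = 0.0
        gz_all[j] = gz
        gnh_all[j] = gnh
        gns_all[j] = gns
        # propagate to tick k-1 (single GEMM over all hub-outgoing blocks)
        gcat = np.concatenate([gnh, gns, dt * gz], axis=1)
        gH_new = (1 - dt) * gH + gcat @ W_hub_out_T
        gS_new = (1 - dt) * gS + gnh @ Wsh.T
        gS_new[~sm_free] = 0.0
        gH = gH_new
        gS = gS_new
        gz = (1 - dt) * gz

    flat_nh = gnh_all.reshape(T * B, -1)
    flat_ns = gns_all.reshape(T * B, -1)
    flat_gz = gz_all.reshape(T * B, -1)
    hub_prev = hub[:T].reshape(T * B, -1)
    sm_prev = sm[:T].reshape(T * B, -1)
    grads = {
        "vh": frame.verbal.T @ gnh_all.sum(axis=0),
        "ch": frame.context.T @ gnh_all.sum(axis=0),
        "sh": sm_prev.T @ flat_nh,
        "hh": hub_prev.T @ flat_nh,
        "hs": hub_prev.T @ flat_ns,
        "hp": dt * (hub_prev.T @ flat_gz),
    }
    for key, m in weights.masks.items():
        grads[key] = grads[key] * m
    return total_loss, grads


def apply_update(state: OptimizerState, weights: WeightSet,
                 config: TrainingConfig) -> None:
    """One weight update from the accumulated gradients (in place)."""
    keys = list(weights.w)
    p = {k: -config.learning_rate * state.grads[k] for k in keys}
    norm = float(np.sqrt(sum(float((v * v).sum()) for v in p.values())))
    if norm > config.step_norm_bound and norm > 0:
        scale = config.step_norm_bound / norm
        for k in keys:
            p[k] *= scale
    for k in keys:
        step = p[k] + config.momentum * state.prev_step[k]
        weights.w[k] *= (1.0 - config.weight_decay)
        weights.w[k] += step
        state.prev_step[k] = step
        state.grads[k][:] = 0.0
    state.n_updates += 1
    state.episodes_accumulated = 0


@dataclass
class TrainingLog:
    updates: list[int] = field(default_factory=list)
    mean_loss: list[float] = field(default_factory=list)


def _prepare_stream(corpus: Corpus, vocab: list[Concept],
                    patterns: np.ndarray):
    """Flattened per-stimulus arrays for the whole corpus."""
    n, L = corpus.concepts.shape
    concept = corpus.concepts.astype(np.int64)
    verbal = corpus.verbal
    sense = corpus.senses.astype(np.int64)
    is_cls = np.array([0 if c.cls == CONCRETE else 1 if c.cls == ABSTRACT else 2
                       for c in vocab])
    cls = is_cls[concept]
    pred_target = np.full((n, L), -1, dtype=np.int64)
    pred_target[:, :-1] = concept[:, 1:]
    has_sm_target = verbal & (cls != 1)
    sm_input = ~verbal  # S-M pattern presented instead of the word
    return concept, verbal, sense, pred_target, has_sm_target, sm_input


def train_model(corpus: Corpus, vocab: list[Concept], fmap: SMFeatureMap,
                config: TrainingConfig | None = None, seed: int = 0,
                arch: Architecture | None = None,
                ) -> tuple[WeightSet, TrainingLog]:
    """Train one network on the corpus stream.

    The corpus is presented as ``config.n_streams`` parallel continuous
    streams (episode boundaries are invisible: the hub->context copy crosses
    them).  Error derivatives accumulate over exactly
    ``config.episodes_per_update`` episodes regardless of the stream layout.
    """
    config = config or TrainingConfig()
    arch = arch or Architecture()
    dtype = np.dtype(config.dtype)
    rng = np.random.default_rng(seed)
    weights = init_network(arch, rng, dtype=dtype)
    state = OptimizerState.for_weights(weights)
    patterns = sm_patterns(vocab, fmap, dtype=dtype)
    concept, verbal, sense, pred_t, has_sm_t, sm_in = _prepare_stream(
        corpus, vocab, patterns)

    B = config.n_streams
    n = len(corpus)
    per_stream = n // B
    if per_stream < 1:
        raise ValueError("corpus smaller than the number of streams")
    order = np.arange(per_stream * B).reshape(B, per_stream)

    log = TrainingLog()
    update_every = max(1, config.episodes_per_update // B)
    loss_acc, loss_n = 0.0, 0

    for _ in range(config.n_passes):
        context = np.full((B, arch.n_context), RESTING, dtype=dtype)
        for step in range(per_stream):
            eps = order[:, step]
            for pos in range(5):
                cid = concept[eps, pos]
                sns = sense[eps, pos]
                is_word = verbal[eps, pos]
                v = np.zeros((B, arch.n_verbal), dtype=dtype)
                v[np.arange(B)[is_word], cid[is_word]] = 1.0
                sm_vals = patterns[cid, sns]
                frame = StimulusFrame(v, context, sm_values=sm_vals,
                                      sm_clamp=sm_in[eps, pos])
                targets = TargetFrame(pred_t[eps, pos],
                                      sm_vals, has_sm_t[eps, pos])
                traj = settle(weights, frame, record=True)
                l, grads = backprop_through_settling(weights, frame, targets,
                                                     traj)
                if not np.isfinite(l):
                    raise FloatingPointError("non-finite training loss")
                for k in grads:
                    state.grads[k] += grads[k]
                loss_acc += l
                loss_n += B
                context = copy_context(traj)
            state.episodes_accumulated += B
            if state.episodes_accumulated >= update_every * B:
                apply_update(state, weights, config)
                log.updates.append(state.n_updates)
                log.mean_loss.append(loss_acc / max(loss_n, 1))
                loss_acc, loss_n = 0.0, 0
    return weights, log


def train_ensemble(corpus: Corpus, vocab: list[Concept], fmap: SMFeatureMap,
                   config: TrainingConfig | None = None,
                   seeds: tuple[int, ...] = tuple(range(10)),
                   arch: Architecture | None = None,
                   ) -> list[WeightSet]:
    """Independently initialized models trained on the same corpus."""
    if len(set(seeds)) != len(seeds):
        raise ValueError("seeds must be distinct")
    return [train_model(corpus, vocab, fmap, config, seed=s, arch=arch)[0]
            for s in seeds]
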