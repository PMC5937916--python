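"""Controlled retrieval and stochastic response selection.

In a forced-choice trial the network is given a probe word and k response
options.  Under controlled retrieval the verbal input clamp carries the
probe at full strength plus a weighted combination of the options; the
option weights start at 1/k and are recomputed every tick as a softmax of
the options' prediction activations with sensitivity s (I_j =
exp(s*P_j) / sum_k exp(s*P_k), s = 200).  This iterative re-weighting lets
the network settle into a state compatible with the probe *and* the most
supported option, amplifying weak (e.g. subordinate-sense) relationships.

``mode="none"`` presents the probe alone (the mechanism removed, as in the
semantic-aphasia lesion); ``mode="static"`` clamps the options at a fixed
1/k without feedback (the ablation showing that adaptive weighting, not
mere option input, carries the effect).

At the end of settling, independent Gaussian noise is added to each
option's prediction activation and the argmax is taken as the response.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .network import (Architecture, SettlingTrajectory, StimulusFrame,
                      WeightSet, copy_context, random_context, settle)

__all__ = ["Trial", "RetrievalConfig", "SelectionConfig", "option_weights",
           "set_context_from_cue", "run_trial", "run_trials_batch",
           "record_trajectory"]


@dataclass(frozen=True)
class Trial:
    probe: int
    options: tuple[int, ...]  # k = 3 or 4 response options
    correct: int  # index into options
    dominance: str | None = None  # dominant | subordinate (homonym trials)
    relation: str | None = None  # taxonomic | associative
    cue: int | None = None  # correct-cue word id
    miscue: int | None = None  # miscue word id

    def __post_init__(self):
        if len(set(self.options)) != len(self.options):
            raise ValueError("options must be distinct")
        if not 0 <= self.correct < len(self.options):
            raise ValueError("correct index out of range")


@dataclass(frozen=True)
class RetrievalConfig:
    mode: str = "controlled"  # controlled | none | static
    sensitivity: float = 200.0
    reweight_every: int = 1  # ticks between weight updates
    reweight_onset: int = 12  # first tick at which weights are recomputed

    def __post_init__(self):
        if self.mode not in ("controlled", "none", "static"):
            raise ValueError(f"unknown retrieval mode {self.mode!r}")
        if self.sensitivity <= 0:
            raise ValueError("sensitivity must be positive")


@dataclass(frozen=True)
class SelectionConfig:
    noise_sd: float = 0.01

    def __post_init__(self):
        if self.noise_sd < 0:
            raise ValueError("noise sd must be non-negative")


def option_weights(prediction_acts: np.ndarray, s: float) -> np.ndarray:
    """Softmax re-weighting I_j = exp(s*P_j) / sum_k exp(s*P_k).

    ``prediction_acts``: (..., k) option prediction activations in [0, 1].
    Log-sum-exp stabilized; rows sum to one.
    """
    z = s * prediction_acts
    z = z - z.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def set_context_from_cue(weights: WeightSet, cue: int | None,
                         rng: np.random.Generator, batch: int = 1,
                         ) -> np.ndarray:
    """Context vector(s) for a trial: settle on the cue word, or random.

    With a cue the network processes the cue word starting from a random
    context and the resulting hub state is copied; with no cue a uniform
    random pattern is returned.
    """
    arch = weights.arch
    if cue is None:
        return random_context(rng, arch, batch)
    frame = StimulusFrame.word(arch, np.full(batch, cue),
                               random_context(rng, arch, batch))
    return copy_context(settle(weights, frame))


def _option_clamp(arch: Architecture, probes: np.ndarray,
                  options: np.ndarray, w: np.ndarray,
                  dtype=np.float64) -> np.ndarray:
    """Verbal clamp = probe at 1 plus options at their current weights."""
    B, k = options.shape
    v = np.zeros((B, arch.n_verbal), dtype=dtype)
    v[np.arange(B), probes] = 1.0
    np.add.at(v, (np.repeat(np.arange(B), k), options.ravel()), w.ravel())
    return v


def _settle_trial(weights: WeightSet, probes: np.ndarray,
                  options: np.ndarray, retrieval: RetrievalConfig,
                  context: np.ndarray, record: bool = False,
                  ) -> SettlingTrajectory:
    arch = weights.arch
    B, k = options.shape
    dtype = weights.w["hh"].dtype
    if retrieval.mode == "none":
        v = np.zeros((B, arch.n_verbal), dtype=dtype)
        v[np.arange(B), probes] = 1.0
        frame = StimulusFrame(v, context)
        return settle(weights, frame, record=record)
    if retrieval.mode == "static":
        v = _option_clamp(arch, probes, options,
                          np.full((B, k), 1.0 / k), dtype)
        frame = StimulusFrame(v, context)
        return settle(weights, frame, record=record)

    state = {"w": np.full((B, k), 1.0 / k)}
    rows = np.arange(B)[:, None]

    def callback(tick: int, pred: np.ndarray) -> np.ndarray:
        if (tick >= retrieval.reweight_onset
                and (tick - retrieval.reweight_onset)
                % retrieval.reweight_every == 0):
            state["w"] = option_weights(pred[rows, options],
                                        retrieval.sensitivity)
        return _option_clamp(arch, probes, options, state["w"], dtype)

    frame = StimulusFrame(np.zeros((B, arch.n_verbal), dtype=dtype), context)
    return settle(weights, frame, record=record, verbal_callback=callback)


@dataclass
class TrialResult:
    activations: np.ndarray  # (reps, k) final option prediction activations
    noisy: np.ndarray  # (reps, k) after Gaussian perturbation
    choices: np.ndarray  # (reps,) argmax indices
    correct: np.ndarray  # (reps,) bool

    @property
    def accuracy(self) -> float:
        return float(self.correct.mean())


def run_trial(weights: WeightSet, trial: Trial,
              retrieval: RetrievalConfig | None = None,
              selection: SelectionConfig | None = None,
              context: np.ndarray | None = None,
              rng: np.random.Generator | None = None,
              reps: int = 1) -> TrialResult:
    """Run one trial ``reps`` times (fresh random context per repetition
    unless an explicit ``context`` of matching batch size is supplied)."""
    retrieval = retrieval or RetrievalConfig()
    selection = selection or SelectionConfig()
    rng = rng or np.random.default_rng(0)
    if context is None:
        context = random_context(rng, weights.arch, reps)
    probes = np.full(context.shape[0], trial.probe)
    options = np.tile(np.asarray(trial.options), (context.shape[0], 1))
    traj = _settle_trial(weights, probes, options, retrieval, context)
    acts = traj.final_prediction()[np.arange(options.shape[0])[:, None],
                                   options]
    noisy = acts + rng.normal(0.0, selection.noise_sd, size=acts.shape)
    choices = noisy.argmax(axis=1)
    return TrialResult(acts, noisy, choices, choices == trial.correct)


def run_trials_batch(weights: WeightSet, trials: list[Trial],
                     retrieval: RetrievalConfig, selection: SelectionConfig,
                     rng: np.random.Generator, reps: int,
                     contexts: np.ndarray | None = None) -> np.ndarray:
    """Per-trial accuracy over ``reps`` presentations, all settled in one
    batch of size len(trials) * reps.

    All trials must have the same option count.  ``contexts`` may supply
    (len(trials)*reps, n_context) patterns; otherwise fresh random contexts
    are drawn.  Returns (len(trials),) accuracies.
    """
    k = len(trials[0].options)
    if any(len(t.options) != k for t in trials):
        raise ValueError("all trials in a batch need the same option count")
    n = len(trials)
    B = n * reps
    if contexts is None:
        contexts = random_context(rng, weights.arch, B)
    probes = np.repeat([t.probe for t in trials], reps)
    options = np.repeat(np.array([t.options for t in trials]), reps, axis=0)
    traj = _settle_trial(weights, probes, options, retrieval, contexts)
    acts = traj.final_prediction()[np.arange(B)[:, None], options]
    noisy = acts + rng.normal(0.0, selection.noise_sd, size=acts.shape)
    choices = noisy.argmax(axis=1)
    correct = choices == np.repeat([t.correct for t in trials], reps)
    return correct.reshape(n, reps).mean(axis=1)


def record_trajectory(weights: WeightSet, trial: Trial,
                      retrieval: RetrievalConfig,
                      context: np.ndarray) -> np.ndarray:
    """Hub state at every tick while the trial settles ((ticks+1, n_hub))."""
    probes = np.array([trial.probe])
    options = np.asarray(trial.options)[None, :]
    traj = _settle_trial(weights, probes, options, retrieval, context,
                         record=True)
    return traj.hub[:, 0, :]
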