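"""The 590-unit recurrent hub-and-spoke network.

Five pools: 64 verbal input units (clamped by the environment), 64 verbal
prediction units (softmax; the model's expectation about the next word),
162 sensory-motor (S-M) units, a 150-unit transmodal hub, and 150 context
units holding a copy of the hub state elicited by the previous stimulus.

Each stimulus is processed for 7 time steps with activations updated 4 times
per step (28 ticks).  Hub and S-M units are logistic with output integration
a <- (1-dt)*a + dt*sigmoid(net), dt = 1/4; the prediction pool integrates
its net input and applies a softmax so its activity always sums to one.
All units carry a fixed, untrainable bias of -2, keeping them near their
minimum activation absent other input.  Updates are synchronous from the
previous tick's values.

All operations are batched: activation arrays have shape (batch, units).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = ["Architecture", "WeightSet", "StimulusFrame", "SettlingTrajectory",
           "init_network", "settle", "copy_context", "random_context",
           "logistic", "RESTING"]

# connection key -> (source pool, destination pool)
_CONNECTIONS = {
    "vh": ("verbal", "hub"),
    "ch": ("context", "hub"),
    "sh": ("sm", "hub"),
    "hh": ("hub", "hub"),
    "hs": ("hub", "sm"),
    "hp": ("hub", "prediction"),
}


def logistic(x: np.ndarray) -> np.ndarray:
    # saturates exactly at large |x|; overflow in exp is benign (-> 0)
    with np.errstate(over="ignore"):
        return 1.0 / (1.0 + np.exp(-x))


@dataclass(frozen=True)
class Architecture:
    n_verbal: int = 64
    n_sm: int = 162
    n_hub: int = 150
    n_context: int = 150
    n_prediction: int = 64
    intervals_per_stimulus: int = 7
    updates_per_interval: int = 4
    bias: float = -2.0
    target_intervals: int = 2  # targets on the final two time steps
    connections: tuple[str, ...] = tuple(_CONNECTIONS)

    @property
    def n_units(self) -> int:
        return (self.n_verbal + self.n_sm + self.n_hub + self.n_context
                + self.n_prediction)

    @property
    def n_ticks(self) -> int:
        return self.intervals_per_stimulus * self.updates_per_interval

    @property
    def target_ticks(self) -> int:
        return self.target_intervals * self.updates_per_interval

    @property
    def dt(self) -> float:
        return 1.0 / self.updates_per_interval

    def pool_size(self, pool: str) -> int:
        return {"verbal": self.n_verbal, "sm": self.n_sm, "hub": self.n_hub,
                "context": self.n_context, "prediction": self.n_prediction}[pool]

    def shape(self, key: str) -> tuple[int, int]:
        src, dst = _CONNECTIONS[key]
        return self.pool_size(src), self.pool_size(dst)


# Resting activation of free logistic units: sigmoid(bias).
RESTING = float(logistic(np.array(-2.0)))


@dataclass
class WeightSet:
    """Trainable connection matrices plus (lesion) masks.

    Masked entries contribute zero to every net input and receive zero
    gradient.  ``effective()`` returns the masked matrices actually used by
    the dynamics.
    """

    arch: Architecture
    w: dict[str, np.ndarray]
    masks: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self):
        for key in self.arch.connections:
            if self.w[key].shape != self.arch.shape(key):
                raise ValueError(f"weight {key}: shape {self.w[key].shape} "
                                 f"!= {self.arch.shape(key)}")

    def effective(self, key: str) -> np.ndarray:
        m = self.masks.get(key)
        return self.w[key] if m is None else self.w[key] * m

    def copy(self) -> "WeightSet":
        return WeightSet(self.arch, {k: v.copy() for k, v in self.w.items()},
                         {k: v.copy() for k, v in self.masks.items()})

    # -- serialization (NPZ + JSON manifest) --------------------------------
    def save(self, path: str | Path) -> None:
        path = Path(path)
        arrays = {f"w_{k}": v for k, v in self.w.items()}
        arrays.update({f"mask_{k}": v for k, v in self.masks.items()})
        manifest = {
            "n_verbal": self.arch.n_verbal, "n_sm": self.arch.n_sm,
            "n_hub": self.arch.n_hub, "n_context": self.arch.n_context,
            "n_prediction": self.arch.n_prediction,
            "intervals_per_stimulus": self.arch.intervals_per_stimulus,
            "updates_per_interval": self.arch.updates_per_interval,
            "bias": self.arch.bias,
        }
        np.savez(path, manifest=json.dumps(manifest), **arrays)

    @classmethod
    def load(cls, path: str | Path) -> "WeightSet":
        data = np.load(path, allow_pickle=False)
        manifest = json.loads(str(data["manifest"]))
        arch = Architecture(**manifest)
        w = {k[2:]: data[k] for k in data.files if k.startswith("w_")}
        masks = {k[5:]: data[k] for k in data.files if k.startswith("mask_")}
        return cls(arch, w, masks)


def init_network(arch: Architecture | None = None,
                 seed: int | np.random.Generator = 0,
                 dtype=np.float64) -> WeightSet:
    """Initialize weights uniformly in [-0.2, 0.2]."""
    arch = arch or Architecture()
    rng = seed if isinstance(seed, np.random.Generator) \
        else np.random.default_rng(seed)
    w = {k: rng.uniform(-0.2, 0.2, size=arch.shape(k)).astype(dtype)
         for k in arch.connections}
    return WeightSet(arch, w)


@dataclass
class StimulusFrame:
    """Clamp specification for one settling run (batched).

    ``verbal``: (B, n_verbal) clamp for the verbal input pool (one-hot word,
    all-zero for an S-M stimulus, or a weighted multi-hot during controlled
    retrieval).  ``context``: (B, n_context) clamp (always clamped).
    ``sm_clamp``: (B,) bool - rows whose S-M pool is clamped to ``sm_values``
    rather than free.
    """

    verbal: np.ndarray
    context: np.ndarray
    sm_values: np.ndarray | None = None
    sm_clamp: np.ndarray | None = None

    @property
    def batch(self) -> int:
        return self.verbal.shape[0]

    @classmethod
    def word(cls, arch: Architecture, word_ids, context: np.ndarray,
             dtype=np.float64) -> "StimulusFrame":
        word_ids = np.atleast_1d(np.asarray(word_ids))
        v = np.zeros((word_ids.size, arch.n_verbal), dtype=dtype)
        v[np.arange(word_ids.size), word_ids] = 1.0
        return cls(v, np.atleast_2d(context).astype(dtype))


@dataclass
class SettlingTrajectory:
    """Per-tick activations over one settling run; arrays (ticks+1, B, n)."""

    hub: np.ndarray
    sm: np.ndarray
    prediction: np.ndarray
    net_hub: np.ndarray | None = None  # (ticks, B, n) pre-activation records
    net_sm: np.ndarray | None = None
    zp: np.ndarray | None = None  # integrated prediction net input

    @property
    def n_ticks(self) -> int:
        return self.hub.shape[0] - 1

    def final_hub(self) -> np.ndarray:
        return self.hub[-1]

    def final_prediction(self) -> np.ndarray:
        return self.prediction[-1]


def settle(weights: WeightSet, frame: StimulusFrame, record: bool = False,
           verbal_callback=None) -> SettlingTrajectory:
    """Run the settling dynamics for one stimulus (28 ticks by default).

    Free units start from their resting state (sigmoid(bias); uniform for
    the prediction pool); only the clamped context pool carries history.
    ``verbal_callback(tick, prediction)`` may return a replacement verbal
    clamp each tick (used by controlled retrieval).  With ``record=True``
    the pre-activation quantities needed for backpropagation are kept.

    Raises ``FloatingPointError`` if activations go non-finite.
    """
    arch = weights.arch
    dt = arch.dt
    T = arch.n_ticks
    B = frame.batch

    Wvh = weights.effective("vh")
    Wch = weights.effective("ch")
    Wsh = weights.effective("sh")
    Whh = weights.effective("hh")
    Whs = weights.effective("hs")
    Whp = weights.effective("hp")
    # one GEMM per tick for all hub-outgoing projections
    W_hub_out = np.concatenate([Whh, Whs, Whp], axis=1)
    n_hub, n_sm = arch.n_hub, arch.n_sm

    V = frame.verbal.astype(Wvh.dtype, copy=False)
    C = frame.context.astype(Wvh.dtype, copy=False)
    ctx_in = C @ Wch  # context clamp is constant within a trajectory

    hub = np.empty((T + 1, B, arch.n_hub), dtype=Wvh.dtype)
    sm = np.empty((T + 1, B, arch.n_sm), dtype=Wvh.dtype)
    pred = np.empty((T + 1, B, arch.n_prediction), dtype=Wvh.dtype)
    hub[0] = RESTING
    sm[0] = RESTING
    if frame.sm_clamp is not None:
        sm[0][frame.sm_clamp] = frame.sm_values[frame.sm_clamp]
    pred[0] = 1.0 / arch.n_prediction
    zp = np.full((T + 1, B, arch.n_prediction), arch.bias, dtype=Wvh.dtype)

    net_hub = np.empty((T, B, arch.n_hub), dtype=Wvh.dtype) if record else None
    net_sm = np.empty((T, B, arch.n_sm), dtype=Wvh.dtype) if record else None

    v_in = None if verbal_callback is not None else V @ Wvh
    for k in range(T):
        if verbal_callback is not None:
            V = verbal_callback(k, pred[k]).astype(Wvh.dtype, copy=False)
            v_in = V @ Wvh
        hub_out = hub[k] @ W_hub_out
        nh = v_in + ctx_in + sm[k] @ Wsh + hub_out[:, :n_hub] + arch.bias
        ns = hub_out[:, n_hub:n_hub + n_sm] + arch.bias
        zp[k + 1] = (1 - dt) * zp[k] \
            + dt * (hub_out[:, n_hub + n_sm:] + arch.bias)
        hub[k + 1] = (1 - dt) * hub[k] + dt * logistic(nh)
        if frame.sm_clamp is None:
            sm[k + 1] = (1 - dt) * sm[k] + dt * logistic(ns)
        else:
            sm[k + 1] = np.where(frame.sm_clamp[:, None], sm[k],
                                 (1 - dt) * sm[k] + dt * logistic(ns))
        z = zp[k + 1] - zp[k + 1].max(axis=1, keepdims=True)
        e = np.exp(z)
        pred[k + 1] = e / e.sum(axis=1, keepdims=True)
        if record:
            net_hub[k] = nh
            net_sm[k] = ns
    if not np.isfinite(hub[T]).all():
        raise FloatingPointError("non-finite activation during settling")
    return SettlingTrajectory(hub, sm, pred, net_hub, net_sm,
                              zp if record else None)


def copy_context(trajectory: SettlingTrajectory) -> np.ndarray:
    """Final-tick hub state, to be clamped as context for the next stimulus.

    The copy is a function, not a connection: no gradient flows through it.
    """
    return trajectory.final_hub().copy()


def random_context(rng: np.random.Generator, arch: Architecture | None = None,
                   batch: int = 1) -> np.ndarray:
    """Random context pattern: i.i.d. random activity per context unit.

    Context units hold copies of hub states, so a "random pattern of
    activity" is drawn in those units' operating regime: each value is
    sigmoid(bias + u) with u ~ uniform(-2, 2), i.e. random net input around
    the fixed bias of -2.  (Uniform values on (0, 1) would have roughly
    five times the drive of any state the buffer can actually hold.)
    """
    arch = arch or Architecture()
    u = rng.uniform(-2.0, 2.0, (batch, arch.n_context))
    return logistic(arch.bias + u)
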