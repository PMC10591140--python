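"""Layered noisy spiking networks: rollout, joint spike probability, heads.

A network is an ordered stack of affine-drive spiking layers followed by a
predictive head.  Within one time step layers are evaluated in order
1..L, each consuming the *same-step* spikes of the layer below (layer 1
consumes the real-valued input); the only unit delay is the membrane
recurrence ``u_t = tau * u_{t-1} + drive_t``.  Because every neuron codes a
Bernoulli variable conditioned on its parents, the collection of all spike
states over a rollout forms a directed (Bayesian-network) factorisation
whose log-probability :func:`joint_log_prob` evaluates.

Time steps are 1..T in prose and 0-based in storage.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .neuron import NeuronParams, NoiseModel, noise_cdf

__all__ = [
    "Affine",
    "LayerSpec",
    "SoftmaxHead",
    "SpikeFunctionHead",
    "LinearSpikeLoss",
    "MultilinearSpikeLoss",
    "NetworkSpec",
    "RolloutRecord",
    "rollout",
    "joint_log_prob",
    "predict",
    "save_network",
    "load_network",
]


@dataclass
class Affine:
    """y = x @ W.T + b with W of shape (out, in)."""

    W: np.ndarray
    b: np.ndarray

    def __post_init__(self) -> None:
        self.W = np.asarray(self.W, dtype=float)
        self.b = np.asarray(self.b, dtype=float)
        if self.W.ndim != 2 or self.b.shape != (self.W.shape[0],):
            raise ValueError("inconsistent affine shapes")
        if not (np.all(np.isfinite(self.W)) and np.all(np.isfinite(self.b))):
            raise ValueError("non-finite affine parameters")

    def __call__(self, x: np.ndarray) -> np.ndarray:
        return x @ self.W.T + self.b

    @property
    def n_out(self) -> int:
        return self.W.shape[0]

    @property
    def n_in(self) -> int:
        return self.W.shape[1]


@dataclass
class LayerSpec:
    """One spiking layer: affine input transform + LIF constants + noise."""

    transform: Affine
    params: NeuronParams = field(default_factory=NeuronParams)
    noise: NoiseModel = field(default_factory=NoiseModel)

    @property
    def size(self) -> int:
        return self.transform.n_out


class SoftmaxHead:
    """Affine map to class scores, softmax readout, cross-entropy loss."""

    def __init__(self, W: np.ndarray, b: np.ndarray):
        self.affine = Affine(W, b)

    @property
    def n_class(self) -> int:
        return self.affine.n_out

    def scores(self, o: np.ndarray) -> np.ndarray:
        return self.affine(o)

    def probs(self, o: np.ndarray) -> np.ndarray:
        s = self.scores(o)
        s = s - s.max(axis=-1, keepdims=True)
        e = np.exp(s)
        return e / e.sum(axis=-1, keepdims=True)

    def step_loss(self, o: np.ndarray, target: np.ndarray) -> np.ndarray:
        """Instantaneous cross-entropy; target is an integer label array."""
        p = self.probs(o)
        t = np.asarray(target, dtype=int)
        return -np.log(np.take_along_axis(p, t[..., None], axis=-1)[..., 0] + 1e-300)

    def _delta(self, o: np.ndarray, target: np.ndarray) -> np.ndarray:
        """softmax(scores) minus the one-hot target (d loss / d scores)."""
        delta = self.probs(o)
        t = np.asarray(target, dtype=int)
        np.put_along_axis(
            delta, t[..., None], np.take_along_axis(delta, t[..., None], -1) - 1.0, -1
        )
        return delta

    def grad_o(self, o: np.ndarray, target: np.ndarray) -> np.ndarray:
        return self._delta(o, target) @ self.affine.W

    def grad_params(self, o: np.ndarray, target: np.ndarray):
        """Per-sample head-parameter gradients of the instantaneous loss."""
        delta = self._delta(o, target)
        gW = delta[..., :, None] * o[..., None, :]
        return {"head.W": gW, "head.b": delta}

    def param_arrays(self):
        return {"head.W": self.affine.W, "head.b": self.affine.b}


class LinearSpikeLoss:
    """Parameter-free loss f(o) = c . o (multilinear of degree one)."""

    def __init__(self, c: np.ndarray):
        self.c = np.asarray(c, dtype=float)

    def step_loss(self, o: np.ndarray, target=None) -> np.ndarray:
        return o @ self.c

    def grad_o(self, o: np.ndarray, target=None) -> np.ndarray:
        return np.broadcast_to(self.c, o.shape).copy()

    def grad_params(self, o, target=None):
        return {}

    def param_arrays(self):
        return {}


class MultilinearSpikeLoss:
    """f(o) = c . o + o^T A o with A strictly upper triangular.

    Multilinear in each coordinate (no squared terms), so a first-order
    loss-difference expansion in any single spike variable is exact.
    """

    def __init__(self, c: np.ndarray, A: np.ndarray):
        self.c = np.asarray(c, dtype=float)
        self.A = np.triu(np.asarray(A, dtype=float), k=1)

    def step_loss(self, o: np.ndarray, target=None) -> np.ndarray:
        return o @ self.c + np.einsum("...i,ij,...j->...", o, self.A, o)

    def grad_o(self, o: np.ndarray, target=None) -> np.ndarray:
        return self.c + o @ self.A.T + o @ self.A

    def grad_params(self, o, target=None):
        return {}

    def param_arrays(self):
        return {}


class SpikeFunctionHead:
    """Adapter giving an arbitrary spike-space loss the head interface."""

    def __init__(self, loss):
        self._loss = loss

    def __getattr__(self, name):
        return getattr(self._loss, name)


@dataclass
class NetworkSpec:
    """Spiking layer stack plus predictive head."""

    layers: list
    head: object

    def __post_init__(self) -> None:
        for i in range(1, len(self.layers)):
            if self.layers[i].transform.n_in != self.layers[i - 1].size:
                raise ValueError(
                    f"layer {i + 1} expects {self.layers[i].transform.n_in} inputs "
                    f"but layer {i} has {self.layers[i - 1].size} neurons"
                )

    @property
    def n_layers(self) -> int:
        return len(self.layers)

    @property
    def n_in(self) -> int:
        return self.layers[0].transform.n_in

    @property
    def sizes(self) -> list:
        return [l.size for l in self.layers]

    def param_arrays(self):
        out = {}
        for i, l in enumerate(self.layers):
            out[f"layer{i}.W"] = l.transform.W
            out[f"layer{i}.b"] = l.transform.b
        out.update(self.head.param_arrays() if hasattr(self.head, "param_arrays") else {})
        return out


@dataclass
class RolloutRecord:
    """Complete trajectory of a batched T-step rollout.

    All per-layer arrays have shape (B, T, n_l); ``u`` is the pre-reset
    membrane so that ``p == F_eps(u - v_th)`` holds elementwise.  ``xi``
    stores the uniform draws that realised the spikes (common random
    numbers), which the flip-based oracle estimators reuse.  ``o`` holds the
    spikes consumed downstream; ``o_sampled`` differs from it only in
    spike-flip perturbation mode.
    """

    x: np.ndarray
    drive: list
    u: list
    p: list
    o: list
    o_sampled: list
    xi: list
    squeezed: bool = False

    @property
    def n_steps(self) -> int:
        return self.x.shape[1]

    @property
    def n_batch(self) -> int:
        return self.x.shape[0]


def _as_batch(x_seq: np.ndarray) -> tuple[np.ndarray, bool]:
    x = np.asarray(x_seq, dtype=float)
    if x.ndim == 2:
        return x[None, :, :], True
    if x.ndim == 3:
        return x, False
    raise ValueError("x_seq must have shape (T, d) or (B, T, d)")


def rollout(
    net: NetworkSpec,
    x_seq: np.ndarray,
    seed: int | np.random.Generator = 0,
    *,
    flip_prob: float = 0.0,
    flip_last_layer: bool = True,
) -> RolloutRecord:
    """Run the network for T steps and record the full trajectory.

    ``flip_prob`` enables the spike-state perturbation mode: each sampled
    hidden spike is flipped independently with that probability and the
    flipped value is consumed by the reset, the membrane recurrence and all
    downstream layers.  ``flip_last_layer`` controls whether the final
    spiking layer (the layer feeding the head) is also perturbed.
    """
    X, squeezed = _as_batch(x_seq)
    if X.shape[2] != net.n_in:
        raise ValueError(
            f"input dimension {X.shape[2]} does not match layer 1 "
            f"({net.n_in} inputs expected)"
        )
    if not np.all(np.isfinite(X)):
        raise ValueError("non-finite input sequence")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    B, T, _ = X.shape
    L = net.n_layers

    drive = [np.empty((B, T, l.size)) for l in net.layers]
    u_rec = [np.empty((B, T, l.size)) for l in net.layers]
    p_rec = [np.empty((B, T, l.size)) for l in net.layers]
    o_rec = [np.empty((B, T, l.size)) for l in net.layers]
    o_raw = [np.empty((B, T, l.size)) for l in net.layers]
    xi = [rng.random((B, T, l.size)) for l in net.layers]

    u_prev = [np.full((B, l.size), l.params.u_reset) for l in net.layers]
    for t in range(T):
        inp = X[:, t, :]
        for li, layer in enumerate(net.layers):
            d = layer.transform(inp)
            u = layer.params.tau * u_prev[li] + d
            p = noise_cdf(u - layer.params.v_th, layer.noise)
            if layer.noise.is_deterministic:
                o = p.copy()
            else:
                o = (xi[li][:, t, :] < p).astype(float)
            o_used = o
            if flip_prob > 0.0 and (flip_last_layer or li < L - 1):
                flips = (rng.random(o.shape) < flip_prob).astype(float)
                o_used = np.abs(o - flips)
            drive[li][:, t] = d
            u_rec[li][:, t] = u
            p_rec[li][:, t] = p
            o_raw[li][:, t] = o
            o_rec[li][:, t] = o_used
            u_prev[li] = np.where(o_used == 1.0, layer.params.u_reset, u)
            inp = o_used
    return RolloutRecord(
        x=X, drive=drive, u=u_rec, p=p_rec, o=o_rec, o_sampled=o_raw, xi=xi,
        squeezed=squeezed,
    )


def joint_log_prob(net: NetworkSpec, record: RolloutRecord) -> np.ndarray:
    """Log of the Bayesian-network joint probability of the sampled spikes.

    Sums ``log Bernoulli(o; p)`` over layers, neurons and steps.  A firing
    probability of exactly 0 or 1 that contradicts the sampled spike yields
    -inf (reported, not raised).  Returns a scalar for an unbatched record.
    """
    B = record.n_batch
    total = np.zeros(B)
    with np.errstate(divide="ignore"):
        for li in range(net.n_layers):
            p = record.p[li]
            o = record.o_sampled[li]
            lp = np.where(o == 1.0, np.log(p), np.log1p(-p))
            total += lp.sum(axis=(1, 2))
    return float(total[0]) if record.squeezed else total


def predict(net: NetworkSpec, record: RolloutRecord):
    """Per-step softmax class probabilities and their time average.

    Returns ``(per_step, averaged)`` with shapes (B, T, C) and (B, C)
    (leading batch axis dropped for unbatched records).
    """
    oL = record.o[-1]
    per_step = net.head.probs(oL)
    avg = per_step.mean(axis=1)
    if record.squeezed:
        return per_step[0], avg[0]
    return per_step, avg


def make_mlp(
    n_in: int,
    hidden: list,
    n_class: int,
    *,
    noise: NoiseModel | None = None,
    params: NeuronParams | None = None,
    seed: int = 0,
    weight_scale: float = 1.0,
    head_loss=None,
) -> NetworkSpec:
    """Fully connected spiking stack with random Gaussian init.

    Weights are drawn N(0, weight_scale/sqrt(fan_in)) so early drives sit
    near the firing threshold; biases start at zero.  ``head_loss`` swaps
    the softmax head for a custom spike-space loss (then ``n_class`` is
    ignored).
    """
    noise = noise if noise is not None else NoiseModel()
    params = params if params is not None else NeuronParams()
    rng = np.random.default_rng(seed)
    layers = []
    fan = n_in
    for n in hidden:
        W = rng.normal(0.0, weight_scale / np.sqrt(fan), (n, fan))
        layers.append(LayerSpec(Affine(W, np.zeros(n)), params=params, noise=noise))
        fan = n
    if head_loss is not None:
        head = SpikeFunctionHead(head_loss)
    else:
        Wh = rng.normal(0.0, weight_scale / np.sqrt(fan), (n_class, fan))
        head = SoftmaxHead(Wh, np.zeros(n_class))
    return NetworkSpec(layers=layers, head=head)


def save_network(net: NetworkSpec, path: str, metadata: dict | None = None) -> None:
    """Checkpoint: .npz array container plus a JSON metadata sidecar."""
    arrays = dict(net.param_arrays())
    np.savez(path if path.endswith(".npz") else path + ".npz", **arrays)
    meta = {
        "sizes": net.sizes,
        "n_in": net.n_in,
        "layers": [
            {
                "tau": l.params.tau,
                "v_th": l.params.v_th,
                "u_reset": l.params.u_reset,
                "noise_family": l.noise.family.value,
                "noise_scale": l.noise.scale,
            }
            for l in net.layers
        ],
        "head": "softmax" if isinstance(net.head, SoftmaxHead) else "custom",
    }
    if metadata:
        meta["extra"] = metadata
    side = (path[:-4] if path.endswith(".npz") else path) + ".json"
    with open(side, "w") as fh:
        json.dump(meta, fh, indent=1)


def load_network(path: str) -> NetworkSpec:
    base = path[:-4] if path.endswith(".npz") else path
    with open(base + ".json") as fh:
        meta = json.load(fh)
    arrays = np.load(base + ".npz")
    layers = []
    for i, lm in enumerate(meta["layers"]):
        layers.append(
            LayerSpec(
                transform=Affine(arrays[f"layer{i}.W"], arrays[f"layer{i}.b"]),
                params=NeuronParams(lm["tau"], lm["v_th"], lm["u_reset"]),
                noise=NoiseModel(lm["noise_family"], lm["noise_scale"]),
            )
        )
    if meta["head"] != "softmax":
        raise ValueError("only softmax-head checkpoints can be reloaded")
    head = SoftmaxHead(arrays["head.W"], arrays["head.b"])
    return NetworkSpec(layers=layers, head=head)
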