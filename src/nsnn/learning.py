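"""Noise-driven learning (NDL) and its surrogate-gradient correspondence.

NDL is a three-factor rule: the gradient of the loss with respect to a
layer's parameters is assembled from a pre-synaptic factor (the parameter
gradient of the membrane potential), a post-synaptic factor (the
membrane-noise density F_eps'(u - v_th), which stands in for the
non-existent spike derivative), and a global learning signal (the loss
gradient with respect to the spike, chained backwards through time and
layers).  Surrogate-gradient learning is the special case in which the
post-synaptic factor is an arbitrary bump function: for every symmetric
noise family the matched surrogate is its density, and conversely every
integrable surrogate shape is the density of some membrane noise up to a
scale constant that can be absorbed into the learning rate.

The backward pass is ordinary backpropagation through time with two
deliberate choices: the spike derivative is replaced by the post-synaptic
factor, and the reset path is blocked (a spike's effect on later membranes
through the hard reset is not differentiated; temporal credit flows only
through the leak term tau * (1 - o_t)).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

import numpy as np
import pandas as pd
from scipy.special import expit

from .network import NetworkSpec, RolloutRecord, SoftmaxHead, rollout, predict
from .neuron import NoiseFamily, NoiseModel

__all__ = [
    "GradientReport",
    "SurrogateShape",
    "SurrogateSpec",
    "erf_surrogate",
    "surrogate_from_noise",
    "noise_from_surrogate",
    "ndl_backward",
    "backward_from_signal",
    "input_gradient",
    "TrainConfig",
    "train",
]


@dataclass
class GradientReport:
    """Per-parameter-block gradient estimates with provenance."""

    grads: dict
    estimator: str
    n_samples: int
    se: dict | None = None
    extra: dict = field(default_factory=dict)


class SurrogateShape(str, Enum):
    ERF_LIKE = "erf_like"
    SIGMOID_DERIVATIVE = "sigmoid_derivative"
    RECTANGULAR = "rectangular"


@dataclass(frozen=True)
class SurrogateSpec:
    """Symmetric bump replacing the spike derivative in the backward pass.

    ``width`` sets the horizontal scale, ``amplitude`` the value at 0.  With
    ``amplitude=None`` the bump is normalised to integrate to one, i.e. it
    is exactly the density of the matched noise family.
    """

    shape: SurrogateShape
    width: float
    amplitude: float | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "shape", SurrogateShape(self.shape))
        if not self.width > 0:
            raise ValueError("surrogate width must be positive")

    @property
    def peak(self) -> float:
        if self.amplitude is not None:
            return self.amplitude
        if self.shape is SurrogateShape.ERF_LIKE:
            return 1.0 / (self.width * np.sqrt(2.0 * np.pi))
        if self.shape is SurrogateShape.SIGMOID_DERIVATIVE:
            return 1.0 / (4.0 * self.width)
        return 1.0 / (2.0 * self.width)

    def __call__(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        if self.shape is SurrogateShape.ERF_LIKE:
            return self.peak * np.exp(-0.5 * (x / self.width) ** 2)
        if self.shape is SurrogateShape.SIGMOID_DERIVATIVE:
            s = expit(x / self.width)
            return self.peak * 4.0 * s * (1.0 - s)
        return np.where(np.abs(x) <= self.width, self.peak, 0.0)


def erf_surrogate() -> SurrogateSpec:
    """The ERF surrogate SG(x) = (1/pi) exp(-x^2) used for deterministic SNNs."""
    return SurrogateSpec(SurrogateShape.ERF_LIKE, width=1.0 / np.sqrt(2.0), amplitude=1.0 / np.pi)


def surrogate_from_noise(nm: NoiseModel) -> SurrogateSpec:
    """Matched surrogate: the membrane-noise density as a bump function."""
    if nm.is_deterministic:
        raise ValueError("deterministic neurons have no matched surrogate")
    shape = {
        NoiseFamily.GAUSSIAN: SurrogateShape.ERF_LIKE,
        NoiseFamily.LOGISTIC: SurrogateShape.SIGMOID_DERIVATIVE,
        NoiseFamily.UNIFORM: SurrogateShape.RECTANGULAR,
    }[nm.family]
    return SurrogateSpec(shape=shape, width=nm.scale, amplitude=nm.pdf_peak())


def noise_from_surrogate(sg: SurrogateSpec) -> tuple[NoiseModel, float]:
    """Noise family whose density is proportional to the surrogate.

    Returns ``(noise_model, multiplier)`` where multiplier is the constant
    by which the surrogate exceeds the matched density (absorb it into the
    learning rate to make surrogate training literally noise-driven).
    """
    family = {
        SurrogateShape.ERF_LIKE: NoiseFamily.GAUSSIAN,
        SurrogateShape.SIGMOID_DERIVATIVE: NoiseFamily.LOGISTIC,
        SurrogateShape.RECTANGULAR: NoiseFamily.UNIFORM,
    }[sg.shape]
    nm = NoiseModel(family=family, scale=sg.width)
    return nm, sg.peak / nm.pdf_peak()


def _step_weights(T: int, loss_mode: str) -> np.ndarray:
    if loss_mode == "mean":
        return np.full(T, 1.0 / T)
    if loss_mode == "sum":
        return np.ones(T)
    if loss_mode == "last":
        w = np.zeros(T)
        w[-1] = 1.0
        return w
    raise ValueError(f"unknown loss_mode {loss_mode!r}")


def _post_factor(layer, u: np.ndarray, surrogate):
    if surrogate is not None:
        return surrogate(u - layer.params.v_th)
    if layer.noise.is_deterministic:
        raise ValueError(
            "deterministic layer has no noise density; pass a SurrogateSpec"
        )
    return layer.noise.pdf(u - layer.params.v_th)


def backward_from_signal(
    net: NetworkSpec,
    record: RolloutRecord,
    g_oL: np.ndarray,
    *,
    surrogate=None,
    reduce: bool = True,
    compute_input_grad: bool = False,
):
    """BPTT given a global learning signal g_oL of shape (B, T, n_L).

    Returns ``(grads, g_x)`` where grads maps ``layer{i}.W`` / ``layer{i}.b``
    to (averaged, or per-sample with ``reduce=False``) gradients and ``g_x``
    is the loss gradient with respect to the input sequence (or None).
    """
    B, T = record.n_batch, record.n_steps
    L = net.n_layers
    sgs = surrogate if isinstance(surrogate, (list, tuple)) else [surrogate] * L

    gW = [np.zeros((B,) + net.layers[li].transform.W.shape) for li in range(L)]
    gb = [np.zeros((B, net.layers[li].size)) for li in range(L)]
    g_x = np.zeros_like(record.x) if compute_input_grad else None
    g_u_next = [np.zeros((B, net.layers[li].size)) for li in range(L)]

    for t in range(T - 1, -1, -1):
        g_u_t = [None] * L
        for li in range(L - 1, -1, -1):
            layer = net.layers[li]
            g_o = g_oL[:, t, :].copy() if li == L - 1 else np.zeros((B, layer.size))
            if li < L - 1:
                g_o += g_u_t[li + 1] @ net.layers[li + 1].transform.W
            fac = _post_factor(layer, record.u[li][:, t, :], sgs[li])
            g_u = g_o * fac + layer.params.tau * (1.0 - record.o[li][:, t, :]) * g_u_next[li]
            g_u_t[li] = g_u
            inp = record.x[:, t, :] if li == 0 else record.o[li - 1][:, t, :]
            gW[li] += g_u[:, :, None] * inp[:, None, :]
            gb[li] += g_u
        if compute_input_grad:
            g_x[:, t, :] = g_u_t[0] @ net.layers[0].transform.W
        g_u_next = g_u_t

    grads = {}
    for li in range(L):
        if reduce:
            grads[f"layer{li}.W"] = gW[li].mean(axis=0)
            grads[f"layer{li}.b"] = gb[li].mean(axis=0)
        else:
            grads[f"layer{li}.W"] = gW[li]
            grads[f"layer{li}.b"] = gb[li]
    return grads, g_x


def _head_signal(net, record, target, loss_mode):
    """Step-weighted loss gradient w.r.t. the last layer's spikes + head grads."""
    B, T = record.n_batch, record.n_steps
    w = _step_weights(T, loss_mode)
    oL = record.o[-1]
    if isinstance(net.head, SoftmaxHead):
        tt = np.broadcast_to(np.asarray(target, dtype=int).reshape(B, 1), (B, T))
        g_oL = net.head.grad_o(oL, tt) * w[None, :, None]
        hp = net.head.grad_params(oL, tt)
        head_grads = {k: np.einsum("bt...,t->b...", v, w) for k, v in hp.items()}
    else:
        g_oL = net.head.grad_o(oL, target) * w[None, :, None]
        head_grads = {}
    return g_oL, head_grads


def ndl_backward(
    net: NetworkSpec,
    record: RolloutRecord,
    target,
    *,
    loss_mode: str = "mean",
    surrogate=None,
    reduce: bool = True,
    compute_input_grad: bool = False,
) -> GradientReport:
    """Noise-driven gradient estimate for one (batched) rollout.

    With ``surrogate=None`` each layer uses its own noise density as the
    post-synaptic factor (plain NDL); passing a :class:`SurrogateSpec` (or a
    per-layer list) replaces the factor, which is surrogate-gradient mode.
    """
    g_oL, head_grads = _head_signal(net, record, target, loss_mode)
    grads, g_x = backward_from_signal(
        net, record, g_oL, surrogate=surrogate, reduce=reduce,
        compute_input_grad=compute_input_grad,
    )
    for k, v in head_grads.items():
        grads[k] = v.mean(axis=0) if reduce else v
    tag = "ndl" if surrogate is None else "surrogate"
    rep = GradientReport(grads=grads, estimator=tag, n_samples=record.n_batch)
    if compute_input_grad:
        rep.extra["input_grad"] = g_x
    return rep


def rollout_loss(net, record, target, loss_mode: str = "mean") -> np.ndarray:
    """Step-weighted loss of a recorded rollout, per batch element."""
    B, T = record.n_batch, record.n_steps
    w = _step_weights(T, loss_mode)
    oL = record.o[-1]
    if isinstance(net.head, SoftmaxHead):
        tt = np.broadcast_to(np.asarray(target, dtype=int).reshape(B, 1), (B, T))
        per_step = net.head.step_loss(oL, tt)
    else:
        per_step = net.head.step_loss(oL, target)
    return per_step @ w


def input_gradient(net, x_seq, target, seed=0, *, loss_mode="mean", surrogate=None):
    """Gradient of the rollout loss with respect to the input sequence."""
    record = rollout(net, x_seq, seed)
    rep = ndl_backward(
        net, record, target, loss_mode=loss_mode, surrogate=surrogate,
        compute_input_grad=True,
    )
    g = rep.extra["input_grad"]
    return g[0] if record.squeezed else g


@dataclass
class TrainConfig:
    epochs: int = 50
    lr: float = 0.5
    batch: int = 40
    seed: int = 0
    loss_mode: str = "mean"
    momentum: float = 0.0
    surrogate: object = None  # None => NDL; SurrogateSpec => SGL


def train(net: NetworkSpec, X: np.ndarray, y: np.ndarray, config: TrainConfig):
    """Plain-SGD trainer: rollout + NDL backward + parameter update.

    ``X`` has shape (N, T, d) and ``y`` integer labels (N,).  Returns the
    trained network (modified in place) and a learning-curve DataFrame with
    per-epoch mean training loss and accuracy.  ``lr=0`` leaves every
    parameter bit-identical.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    rng = np.random.default_rng(config.seed)
    params = net.param_arrays()
    velocity = {k: np.zeros_like(v) for k, v in params.items()}
    rows = []
    N = X.shape[0]
    for epoch in range(config.epochs):
        order = rng.permutation(N)
        losses = []
        for start in range(0, N, config.batch):
            idx = order[start : start + config.batch]
            record = rollout(net, X[idx], rng)
            loss = rollout_loss(net, record, y[idx], config.loss_mode).mean()
            if not np.isfinite(loss):
                raise RuntimeError(
                    f"non-finite loss at epoch {epoch}, batch starting {start}"
                )
            losses.append(loss)
            rep = ndl_backward(
                net, record, y[idx], loss_mode=config.loss_mode,
                surrogate=config.surrogate,
            )
            if config.lr > 0:
                for k, g in rep.grads.items():
                    velocity[k] = config.momentum * velocity[k] + g
                    params[k] -= config.lr * velocity[k]
        acc = evaluate_accuracy(net, X, y, seed=rng)
        rows.append({"epoch": epoch, "loss": float(np.mean(losses)), "accuracy": acc})
    return net, pd.DataFrame(rows)


def evaluate_accuracy(net, X, y, seed=0) -> float:
    """Accuracy of the time-averaged prediction over one rollout per sample."""
    record = rollout(net, np.asarray(X, dtype=float), seed)
    _, avg = predict(net, record)
    return float((avg.argmax(axis=1) == np.asarray(y, dtype=int)).mean())
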