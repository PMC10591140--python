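"""Brute-force ground truth for tiny noisy spiking networks.

Three routes to the gradient of the expected loss are provided, in
decreasing order of exactness:

* :func:`exact_gradient` — full enumeration of all 2^(N*T) spike
  configurations with analytic score-function gradients (cross-checked
  internally against finite differences of the enumerated expected loss);
* :func:`local_marginal_estimate` — the conditioning (local
  marginalisation) estimator: one sampled rollout, one exact summation per
  spike variable, with the loss difference of the flipped variable either
  evaluated exactly (re-simulating every downstream variable under common
  random numbers, which keeps the estimator unbiased for temporally coupled
  losses) or replaced by its first-order expansion;
* the first-order variant, which is algebraically identical to the NDL
  backward pass and is implemented here independently as a consistency
  check on that identity.

Everything in this module is deliberately restricted to networks with at
most ``ENUM_CAP`` binary spike variables.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .learning import GradientReport, _step_weights, ndl_backward, rollout_loss
from .network import NetworkSpec, RolloutRecord, SoftmaxHead, rollout
from .neuron import noise_cdf

ENUM_CAP = 16


def _labels(target, B):
    """Broadcast a scalar class label to a (B,) array; pass arrays through."""
    if target is None:
        return None
    t = np.asarray(target)
    return np.full(B, int(t)) if t.ndim == 0 else t


__all__ = [
    "ENUM_CAP",
    "Enumeration",
    "enumerate_expected_loss",
    "exact_gradient",
    "local_marginal_estimate",
    "mc_gradient_mean",
    "bias_variance_report",
]


@dataclass
class Enumeration:
    """All spike configurations of a tiny rollout with probability and loss."""

    o: list  # per layer: (C, T, n_l)
    prob: np.ndarray  # (C,)
    loss: np.ndarray  # (C,)

    @property
    def n_configs(self) -> int:
        return self.prob.shape[0]

    def marginals(self) -> list:
        """Exact marginal firing probability per layer/step/neuron."""
        return [np.einsum("c,ctn->tn", self.prob, ol) for ol in self.o]


def _count_vars(net: NetworkSpec, T: int) -> int:
    return T * sum(net.sizes)


def _all_configs(net: NetworkSpec, T: int) -> list:
    """Every spike configuration, as per-layer arrays of shape (C, T, n_l)."""
    K = _count_vars(net, T)
    C = 1 << K
    idx = np.arange(C, dtype=np.uint64)
    bits = ((idx[:, None] >> np.arange(K, dtype=np.uint64)[None, :]) & 1).astype(float)
    out, k = [], 0
    for n in net.sizes:
        layer_bits = np.empty((C, T, n))
        for t in range(T):
            layer_bits[:, t, :] = bits[:, k : k + n]
            k += n
        out.append(layer_bits)
    return out


def _config_loss(net, o_last, target, loss_mode):
    """Step-weighted loss for forced final-layer spikes of shape (C, T, n)."""
    T = o_last.shape[1]
    w = _step_weights(T, loss_mode)
    if isinstance(net.head, SoftmaxHead):
        C = o_last.shape[0]
        tt = np.broadcast_to(np.asarray(target, dtype=int).reshape(1, 1), (C, T))
        per_step = net.head.step_loss(o_last, tt)
    else:
        per_step = net.head.step_loss(o_last, target)
    return per_step @ w


def _forced_forward(net, x_seq, o_forced):
    """Membrane and firing-probability trajectories under forced spikes.

    Returns per-layer (C, T, n) arrays ``u`` (pre-reset) and ``p``.
    """
    x = np.asarray(x_seq, dtype=float)
    T = x.shape[0]
    C = o_forced[0].shape[0]
    u_out = [np.empty_like(ol) for ol in o_forced]
    p_out = [np.empty_like(ol) for ol in o_forced]
    u_prev = [np.full((C, n), l.params.u_reset) for n, l in zip(net.sizes, net.layers)]
    for t in range(T):
        inp = np.broadcast_to(x[t], (C, x.shape[1]))
        for li, layer in enumerate(net.layers):
            u = layer.params.tau * u_prev[li] + layer.transform(inp)
            p = noise_cdf(u - layer.params.v_th, layer.noise)
            u_out[li][:, t] = u
            p_out[li][:, t] = p
            o = o_forced[li][:, t]
            u_prev[li] = np.where(o == 1.0, layer.params.u_reset, u)
            inp = o
    return u_out, p_out


def enumerate_expected_loss(
    net: NetworkSpec,
    x_seq: np.ndarray,
    target=None,
    *,
    loss_mode: str = "mean",
    cap: int = ENUM_CAP,
):
    """Exact expected loss by summing over every spike configuration."""
    x = np.asarray(x_seq, dtype=float)
    T = x.shape[0]
    K = _count_vars(net, T)
    if K > cap:
        raise ValueError(f"enumeration needs {K} binary variables, cap is {cap}")
    o_all = _all_configs(net, T)
    _, p_all = _forced_forward(net, x, o_all)
    prob = np.ones(o_all[0].shape[0])
    for ol, pl in zip(o_all, p_all):
        prob *= np.prod(np.where(ol == 1.0, pl, 1.0 - pl), axis=(1, 2))
    loss = _config_loss(net, o_all[-1], target, loss_mode)
    enum = Enumeration(o=o_all, prob=prob, loss=loss)
    return float(prob @ loss), enum


def _score_accumulators(net, x_seq, o_all, u_all, p_all):
    """Per-config score-function sums S = sum_{m,t} dlog p(o_{l,m,t}) / dtheta_l."""
    x = np.asarray(x_seq, dtype=float)
    T = x.shape[0]
    C = o_all[0].shape[0]
    SW = [np.zeros((C,) + l.transform.W.shape) for l in net.layers]
    Sb = [np.zeros((C, n)) for n in net.sizes]
    DW = [np.zeros((C,) + l.transform.W.shape) for l in net.layers]
    Db = [np.zeros((C, n)) for n in net.sizes]
    for t in range(T):
        inp = np.broadcast_to(x[t], (C, x.shape[1]))
        for li, layer in enumerate(net.layers):
            o = o_all[li][:, t]
            u = u_all[li][:, t]
            p = np.clip(p_all[li][:, t], 1e-300, 1.0 - 1e-16)
            if t > 0:
                keep = layer.params.tau * (1.0 - o_all[li][:, t - 1])
                DW[li] = keep[:, :, None] * DW[li]
                Db[li] = keep * Db[li]
            DW[li] = DW[li] + inp[:, None, :] * np.ones((C, layer.size, 1))
            Db[li] = Db[li] + 1.0
            pdf = layer.noise.pdf(u - layer.params.v_th)
            coef = np.where(o == 1.0, pdf / p, -pdf / (1.0 - p))
            SW[li] += coef[:, :, None] * DW[li]
            Sb[li] += coef * Db[li]
            inp = o
    return SW, Sb


def exact_gradient(
    net: NetworkSpec,
    x_seq: np.ndarray,
    target=None,
    *,
    loss_mode: str = "mean",
    cap: int = ENUM_CAP,
) -> GradientReport:
    """Exact gradient of the expected loss via enumeration.

    Layer parameters use the analytic score-function form (the firing
    probabilities depend on them); head parameters use the probability-
    weighted direct loss gradient.
    """
    EL, enum = enumerate_expected_loss(net, x_seq, target, loss_mode=loss_mode, cap=cap)
    x = np.asarray(x_seq, dtype=float)
    u_all, p_all = _forced_forward(net, x, enum.o)
    SW, Sb = _score_accumulators(net, x, enum.o, u_all, p_all)
    w_loss = enum.prob * enum.loss
    grads = {}
    for li in range(net.n_layers):
        grads[f"layer{li}.W"] = np.einsum("c,c...->...", w_loss, SW[li])
        grads[f"layer{li}.b"] = np.einsum("c,c...->...", w_loss, Sb[li])
    if isinstance(net.head, SoftmaxHead):
        T = x.shape[0]
        wts = _step_weights(T, loss_mode)
        C = enum.n_configs
        tt = np.broadcast_to(np.asarray(target, dtype=int).reshape(1, 1), (C, T))
        hp = net.head.grad_params(enum.o[-1], tt)
        for k, v in hp.items():
            per_cfg = np.einsum("ct...,t->c...", v, wts)
            grads[k] = np.einsum("c,c...->...", enum.prob, per_cfg)
    rep = GradientReport(grads=grads, estimator="enumeration", n_samples=enum.n_configs)
    rep.extra["expected_loss"] = EL
    return rep


def finite_difference_gradient(net, x_seq, target=None, *, loss_mode="mean", h=1e-5):
    """Central finite differences of the enumerated expected loss."""
    grads = {}
    for name, arr in net.param_arrays().items():
        g = np.zeros_like(arr)
        it = np.nditer(arr, flags=["multi_index"])
        for _ in it:
            idx = it.multi_index
            orig = arr[idx]
            arr[idx] = orig + h
            ep, _ = enumerate_expected_loss(net, x_seq, target, loss_mode=loss_mode)
            arr[idx] = orig - h
            em, _ = enumerate_expected_loss(net, x_seq, target, loss_mode=loss_mode)
            arr[idx] = orig
            g[idx] = (ep - em) / (2.0 * h)
        grads[name] = g
    return GradientReport(grads=grads, estimator="finite_difference", n_samples=0)


def _carried(net, record, li, t):
    """Post-reset membrane of layer li after step t (t = -1 gives the rest state)."""
    if t < 0:
        return np.full((record.n_batch, net.sizes[li]), net.layers[li].params.u_reset)
    u = record.u[li][:, t]
    o = record.o[li][:, t]
    return np.where(o == 1.0, net.layers[li].params.u_reset, u)


def _flipped_loss(net, record, target, li_flip, t_flip, m_flip, *,
                  loss_mode, same_step_only):
    """Loss after flipping one spike and re-propagating downstream under CRN.

    The stored rollout uniforms are reused, so every variable that is not a
    descendant of the flipped one keeps its original value.
    """
    B, T = record.n_batch, record.n_steps
    target = _labels(target, B)
    L = net.n_layers
    o_new = [ol.copy() for ol in record.o]
    o_new[li_flip][:, t_flip, m_flip] = 1.0 - o_new[li_flip][:, t_flip, m_flip]

    last_step = t_flip if same_step_only else T - 1
    u_prev = [_carried(net, record, li, t_flip - 1) for li in range(L)]
    for t in range(t_flip, last_step + 1):
        inp = record.x[:, t]
        for li, layer in enumerate(net.layers):
            if t == t_flip and li < li_flip:
                # upstream of the flip: unchanged
                u = record.u[li][:, t]
                o = o_new[li][:, t]
            elif t == t_flip and li == li_flip:
                u = record.u[li][:, t]
                o = o_new[li][:, t]  # flip already applied
            else:
                u = layer.params.tau * u_prev[li] + layer.transform(inp)
                p = noise_cdf(u - layer.params.v_th, layer.noise)
                if layer.noise.is_deterministic:
                    o = p.copy()
                else:
                    o = (record.xi[li][:, t] < p).astype(float)
                o_new[li][:, t] = o
            u_prev[li] = np.where(o == 1.0, layer.params.u_reset, u)
            inp = o
    w = _step_weights(T, loss_mode)
    oL = o_new[-1]
    if isinstance(net.head, SoftmaxHead):
        tt = np.broadcast_to(np.asarray(target, dtype=int).reshape(B, 1), (B, T))
        per_step = net.head.step_loss(oL, tt)
    else:
        per_step = net.head.step_loss(oL, target)
    return per_step @ w


def _presynaptic_factors(net, record):
    """D_W, D_b: gradient of each membrane w.r.t. its own layer's parameters.

    Recursion along the realised trajectory with the reset factor
    tau * (1 - o_{t-1}); D_W[li] has shape (B, T, n_l, n_prev).
    """
    B, T = record.n_batch, record.n_steps
    DW = [np.zeros((B, T, l.size, l.transform.n_in)) for l in net.layers]
    Db = [np.zeros((B, T, l.size)) for l in net.layers]
    for li, layer in enumerate(net.layers):
        for t in range(T):
            inp = record.x[:, t] if li == 0 else record.o[li - 1][:, t]
            if t == 0:
                DW[li][:, t] = inp[:, None, :] * np.ones((B, layer.size, 1))
                Db[li][:, t] = 1.0
            else:
                keep = layer.params.tau * (1.0 - record.o[li][:, t - 1])
                DW[li][:, t] = keep[:, :, None] * DW[li][:, t - 1] + inp[:, None, :]
                Db[li][:, t] = keep * Db[li][:, t - 1] + 1.0
    return DW, Db


def _spike_adjoints(net, record, target, loss_mode):
    """Direct spike-gradient signal g_o per layer/step via the chain rule.

    Independent assembly of the global learning signal used by the
    first-order estimator (the own-layer temporal path lives in the
    pre-synaptic recursion, not here).
    """
    B, T = record.n_batch, record.n_steps
    L = net.n_layers
    target = _labels(target, B)
    w = _step_weights(T, loss_mode)
    oL = record.o[-1]
    if isinstance(net.head, SoftmaxHead):
        tt = np.broadcast_to(np.asarray(target, dtype=int).reshape(B, 1), (B, T))
        g_head = net.head.grad_o(oL, tt) * w[None, :, None]
    else:
        g_head = net.head.grad_o(oL, target) * w[None, :, None]

    g_o = [np.zeros((B, T, n)) for n in net.sizes]
    g_u = [np.zeros((B, T, n)) for n in net.sizes]
    for t in range(T - 1, -1, -1):
        for li in range(L - 1, -1, -1):
            layer = net.layers[li]
            g = g_head[:, t].copy() if li == L - 1 else np.zeros((B, layer.size))
            if li < L - 1:
                g += g_u[li + 1][:, t] @ net.layers[li + 1].transform.W
            g_o[li][:, t] = g
            pdf = layer.noise.pdf(record.u[li][:, t] - layer.params.v_th)
            gu = g * pdf
            if t < T - 1:
                gu += layer.params.tau * (1.0 - record.o[li][:, t]) * g_u[li][:, t + 1]
            g_u[li][:, t] = gu
    return g_o


def local_marginal_estimate(
    net: NetworkSpec,
    record: RolloutRecord,
    target=None,
    *,
    exact_delta: bool = True,
    same_step_only: bool = False,
    loss_mode: str = "mean",
    reduce: bool = True,
    cap: int = ENUM_CAP,
) -> GradientReport:
    """Conditioning estimator: one exact summation per spike variable.

    With ``exact_delta`` the loss difference of each flip is evaluated by
    re-propagating every downstream variable under the rollout's stored
    uniforms (unbiased); otherwise the first-order expansion
    (2o-1) * dL/do is used, which coincides with the NDL backward pass.
    """
    B, T = record.n_batch, record.n_steps
    target = _labels(target, B)
    K = _count_vars(net, T)
    if exact_delta and K > cap:
        raise ValueError(
            f"exact loss differences need {K} flip re-evaluations per sample; "
            f"cap is {cap} (tiny nets only)"
        )
    DW, Db = _presynaptic_factors(net, record)
    gW = [np.zeros((B,) + l.transform.W.shape) for l in net.layers]
    gb = [np.zeros((B, l.size)) for l in net.layers]
    degenerate = any(
        bool(np.any((pl == 0.0) | (pl == 1.0))) for pl in record.p
    )
    if exact_delta:
        loss_orig = rollout_loss(net, record, target, loss_mode)
        for li, layer in enumerate(net.layers):
            pdf = layer.noise.pdf(record.u[li] - layer.params.v_th)
            sign = 2.0 * record.o[li] - 1.0
            for t in range(T):
                for m in range(layer.size):
                    loss_flip = _flipped_loss(
                        net, record, target, li, t, m,
                        loss_mode=loss_mode, same_step_only=same_step_only,
                    )
                    s = sign[:, t, m] * pdf[:, t, m] * (loss_orig - loss_flip)
                    gW[li][:, m, :] += s[:, None] * DW[li][:, t, m, :]
                    gb[li][:, m] += s * Db[li][:, t, m]
        tag = "local_marginal_exact" + ("_same_step" if same_step_only else "")
    else:
        g_o = _spike_adjoints(net, record, target, loss_mode)
        for li, layer in enumerate(net.layers):
            pdf = layer.noise.pdf(record.u[li] - layer.params.v_th)
            s = pdf * g_o[li]  # (B, T, n); (2o-1)^2 = 1 cancels the sign
            gW[li] += np.einsum("btm,btmj->bmj", s, DW[li])
            gb[li] += np.einsum("btm,btm->bm", s, Db[li])
        tag = "local_marginal_first_order"

    grads = {}
    for li in range(net.n_layers):
        grads[f"layer{li}.W"] = gW[li].mean(axis=0) if reduce else gW[li]
        grads[f"layer{li}.b"] = gb[li].mean(axis=0) if reduce else gb[li]
    if isinstance(net.head, SoftmaxHead):
        w = _step_weights(T, loss_mode)
        tt = np.broadcast_to(np.asarray(target, dtype=int).reshape(B, 1), (B, T))
        hp = net.head.grad_params(record.o[-1], tt)
        for k, v in hp.items():
            per_sample = np.einsum("bt...,t->b...", v, w)
            grads[k] = per_sample.mean(axis=0) if reduce else per_sample
    rep = GradientReport(grads=grads, estimator=tag, n_samples=B)
    rep.extra["degenerate"] = degenerate
    return rep


def mc_gradient_mean(
    net: NetworkSpec,
    x_seq: np.ndarray,
    target=None,
    *,
    estimator: str = "ndl",
    n_samples: int = 200_000,
    seed: int = 0,
    batch: int = 4000,
    loss_mode: str = "mean",
) -> GradientReport:
    """Monte-Carlo mean (with standard errors) of a sampled estimator.

    Rollouts are batched and vectorised; the same x_seq is replicated across
    the batch.  ``estimator`` is ``ndl``, ``local_marginal_exact`` or
    ``local_marginal_first_order``.
    """
    x = np.asarray(x_seq, dtype=float)
    rng = np.random.default_rng(seed)
    sums, sqs = {}, {}
    done = 0
    while done < n_samples:
        b = min(batch, n_samples - done)
        X = np.broadcast_to(x, (b,) + x.shape)
        record = rollout(net, X, rng)
        tb = _labels(target, b)
        if estimator == "ndl":
            rep = ndl_backward(net, record, tb, loss_mode=loss_mode, reduce=False)
            per = rep.grads
        else:
            per = local_marginal_estimate(
                net, record, tb,
                exact_delta=(estimator == "local_marginal_exact"),
                loss_mode=loss_mode, reduce=False,
            ).grads
        for k, v in per.items():
            sums[k] = sums.get(k, 0.0) + v.sum(axis=0)
            sqs[k] = sqs.get(k, 0.0) + (v ** 2).sum(axis=0)
        done += b
    grads = {k: v / n_samples for k, v in sums.items()}
    se = {
        k: np.sqrt(np.maximum(sqs[k] / n_samples - grads[k] ** 2, 0.0) / n_samples)
        for k in sums
    }
    return GradientReport(grads=grads, estimator=estimator, n_samples=n_samples, se=se)


def bias_variance_report(
    net: NetworkSpec,
    x_seq: np.ndarray,
    target=None,
    *,
    estimators=("ndl", "local_marginal_exact"),
    n_samples: int = 20_000,
    seed: int = 0,
    loss_mode: str = "mean",
) -> pd.DataFrame:
    """Bias (vs enumeration), variance and SE per estimator and block."""
    ref = exact_gradient(net, x_seq, target, loss_mode=loss_mode)
    rows = []
    for i, name in enumerate(estimators):
        if name == "enumeration":
            for k, g in ref.grads.items():
                rows.append(
                    {"estimator": name, "block": k, "bias_rms": 0.0,
                     "variance": 0.0, "se_rms": 0.0, "n_samples": ref.n_samples}
                )
            continue
        rep = mc_gradient_mean(
            net, x_seq, target, estimator=name, n_samples=n_samples,
            seed=seed + i, loss_mode=loss_mode,
        )
        for k, g in rep.grads.items():
            bias = g - ref.grads.get(k, np.zeros_like(g))
            var = (rep.se[k] ** 2) * n_samples
            rows.append(
                {"estimator": name, "block": k,
                 "bias_rms": float(np.sqrt(np.mean(bias ** 2))),
                 "variance": float(np.mean(var)),
                 "se_rms": float(np.sqrt(np.mean(rep.se[k] ** 2))),
                 "n_samples": n_samples}
            )
    return pd.DataFrame(rows)
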