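"""Spike-train fitting: PSP filtering, the PSP-kernel MMD loss, and a
teacher-student neural-activity-fitting harness.

Spike trains are compared through their post-synaptic-potential (PSP)
traces, the first-order low-pass filter
``PSP_t = (1 - 1/tau_s) PSP_{t-1} + (1/tau_s) y_t`` (PSP_0 = 0).  The loss
averages, over every prefix length t, the accumulated squared distance
between the two filtered traces:

    L = (1/T) sum_{t=1..T} sum_{tau<=t} || PSP(y_hat, tau) - PSP(y, tau) ||^2,

a premetric on rasters: nonnegative, symmetric, and zero exactly when the
trains coincide (for tau_s > 1).  The double sum is evaluated in O(T) by
weighting prefix tau by (T - tau + 1)/T; agreement with the naive O(T^2)
sum is part of the test suite.

Rasters here carry neurons on axis -2 and time on axis -1; leading axes
(trials, stimuli) pass through elementwise.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.ndimage import uniform_filter1d

from .learning import backward_from_signal
from .network import NetworkSpec, rollout

__all__ = [
    "psp_transform",
    "mmd_psp_loss",
    "mmd_psp_loss_naive",
    "mmd_psp_grad",
    "FitConfig",
    "fit_activity",
    "smoothed_rates",
    "rate_correlation",
]


def _check_tau(tau_s: float) -> None:
    if not tau_s > 1.0:
        raise ValueError(f"tau_s must exceed 1, got {tau_s}")


def psp_transform(spikes: np.ndarray, tau_s: float = 2.0) -> np.ndarray:
    """First-order PSP filter along the last (time) axis, zero-initialised."""
    _check_tau(tau_s)
    y = np.asarray(spikes, dtype=float)
    a = 1.0 - 1.0 / tau_s
    out = np.empty_like(y)
    acc = np.zeros(y.shape[:-1])
    for t in range(y.shape[-1]):
        acc = a * acc + y[..., t] / tau_s
        out[..., t] = acc
    return out


def _prefix_weights(T: int) -> np.ndarray:
    # prefix tau (0-based) appears in every outer term t >= tau
    return (T - np.arange(T)) / T


def mmd_psp_loss(pred: np.ndarray, target: np.ndarray, tau_s: float = 2.0):
    """PSP-kernel MMD loss between two equal-shape rasters (O(T) form).

    Returns a scalar for (n, T) inputs; leading axes are preserved.
    """
    p = np.asarray(pred, dtype=float)
    q = np.asarray(target, dtype=float)
    if p.shape != q.shape:
        raise ValueError(f"shape mismatch: {p.shape} vs {q.shape}")
    diff = psp_transform(p, tau_s) - psp_transform(q, tau_s)
    w = _prefix_weights(p.shape[-1])
    per_prefix = (diff**2).sum(axis=-2)  # sum over neurons
    out = per_prefix @ w
    return float(out) if out.ndim == 0 else out


def mmd_psp_loss_naive(pred, target, tau_s: float = 2.0):
    """Literal O(T^2) double sum over prefixes (oracle for the O(T) form)."""
    p = np.asarray(pred, dtype=float)
    q = np.asarray(target, dtype=float)
    if p.shape != q.shape:
        raise ValueError(f"shape mismatch: {p.shape} vs {q.shape}")
    diff = psp_transform(p, tau_s) - psp_transform(q, tau_s)
    T = p.shape[-1]
    total = 0.0
    for t in range(T):
        for tau in range(t + 1):
            total += (diff[..., tau] ** 2).sum()
    return total / T


def mmd_psp_grad(pred, target, tau_s: float = 2.0) -> np.ndarray:
    """Gradient of the loss with respect to the predicted spike raster.

    The loss is linear-filter composed with a quadratic, so the gradient is
    the adjoint (time-reversed) PSP filter applied to the weighted trace
    difference.
    """
    p = np.asarray(pred, dtype=float)
    q = np.asarray(target, dtype=float)
    if p.shape != q.shape:
        raise ValueError(f"shape mismatch: {p.shape} vs {q.shape}")
    _check_tau(tau_s)
    diff = psp_transform(p, tau_s) - psp_transform(q, tau_s)
    T = p.shape[-1]
    w = _prefix_weights(T)
    g_trace = 2.0 * w * diff
    a = 1.0 - 1.0 / tau_s
    grad = np.empty_like(p)
    acc = np.zeros(p.shape[:-1])
    for t in range(T - 1, -1, -1):
        acc = a * acc + g_trace[..., t]
        grad[..., t] = acc / tau_s
    return grad


@dataclass
class FitConfig:
    epochs: int = 150
    lr: float = 0.5
    batch: int = 16
    seed: int = 0
    tau_s: float = 2.0
    bin_width: int = 5
    surrogate: object = None  # SurrogateSpec enables deterministic-mode fitting


def fit_activity(model: NetworkSpec, stimuli: np.ndarray, targets: np.ndarray,
                 config: FitConfig | None = None):
    """Fit a spiking model to target spike rasters by noise-driven descent
    on the PSP-MMD loss.

    ``stimuli`` has shape (S, T, d); ``targets`` either (S, n, T) or
    (S, trials, n, T) — with a trials axis one recorded trial is drawn at
    random per stimulus per epoch, so the student sees the trial-to-trial
    variability of the data.  Returns ``(model, curve)`` with a per-epoch
    mean-loss DataFrame.  Training aborts with the curve attached if the
    loss diverges.
    """
    config = config or FitConfig()
    stimuli = np.asarray(stimuli, dtype=float)
    targets = np.asarray(targets, dtype=float)
    S = stimuli.shape[0]
    n_out = model.sizes[-1]
    if targets.shape[-2] != n_out:
        raise ValueError(
            f"model output layer has {n_out} neurons but targets have "
            f"{targets.shape[-2]}"
        )
    rng = np.random.default_rng(config.seed)
    params = model.param_arrays()
    rows = []
    for epoch in range(config.epochs):
        order = rng.permutation(S)
        losses = []
        for start in range(0, S, config.batch):
            idx = order[start : start + config.batch]
            if targets.ndim == 4:
                trial = rng.integers(0, targets.shape[1], size=len(idx))
                tgt = targets[idx, trial]  # (B, n, T)
            else:
                tgt = targets[idx]
            record = rollout(model, stimuli[idx], rng)
            pred = np.swapaxes(record.o[-1], 1, 2)  # (B, n, T)
            loss = mmd_psp_loss(pred, tgt, config.tau_s)
            losses.append(float(np.mean(loss)))
            if not np.isfinite(losses[-1]):
                curve = pd.DataFrame(rows)
                raise RuntimeError(
                    f"MMD loss diverged at epoch {epoch}; curve:\n{curve}"
                )
            g_pred = mmd_psp_grad(pred, tgt, config.tau_s)  # (B, n, T)
            g_oL = np.swapaxes(g_pred, 1, 2)  # (B, T, n)
            grads, _ = backward_from_signal(
                model, record, g_oL, surrogate=config.surrogate
            )
            if config.lr > 0:
                for k, g in grads.items():
                    params[k] -= config.lr * g
        rows.append({"epoch": epoch, "loss": float(np.mean(losses))})
    return model, pd.DataFrame(rows)


def smoothed_rates(raster: np.ndarray, bin_width: int = 5) -> np.ndarray:
    """Trial-averaged firing rate, smoothed with a sliding boxcar in time.

    ``raster`` is (trials, n, T) or (n, T); returns (n, T).
    """
    r = np.asarray(raster, dtype=float)
    if r.ndim == 3:
        r = r.mean(axis=0)
    return uniform_filter1d(r, size=bin_width, axis=-1, mode="nearest")


def simulate_rasters(model: NetworkSpec, stimuli, trials: int, seed: int = 0):
    """Per-stimulus ensembles of model rasters, shape (S, trials, n, T)."""
    stimuli = np.asarray(stimuli, dtype=float)
    S, T, _ = stimuli.shape
    X = np.repeat(stimuli, trials, axis=0)
    record = rollout(model, X, seed)
    o = record.o[-1]  # (S*trials, T, n)
    return np.swapaxes(o, 1, 2).reshape(S, trials, model.sizes[-1], T)


def rate_correlation(model: NetworkSpec, stimuli, target_rasters, *,
                     trials: int = 20, seed: int = 0, bin_width: int = 5):
    """Per-neuron Pearson r between model and target smoothed rate curves.

    Rate curves are concatenated across stimuli before correlating.
    Neurons whose model or target curve has zero variance are skipped
    (returned as NaN).  Returns ``(per_neuron_r, mean_r)``.
    """
    pred = simulate_rasters(model, stimuli, trials, seed)
    n = pred.shape[2]
    pr = np.concatenate([smoothed_rates(pred[s], bin_width) for s in range(pred.shape[0])], axis=-1)
    tg = np.concatenate(
        [smoothed_rates(np.asarray(target_rasters, dtype=float)[s], bin_width)
         for s in range(np.shape(target_rasters)[0])], axis=-1)
    rs = np.full(n, np.nan)
    for m in range(n):
        if np.ptp(pr[m]) > 0 and np.ptp(tg[m]) > 0:
            rs[m] = stats.pearsonr(pr[m], tg[m])[0]
    ok = np.isfinite(rs)
    return rs, float(rs[ok].mean()) if ok.any() else float("nan")
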