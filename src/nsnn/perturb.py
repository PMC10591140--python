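"""Perturbation operators for robustness evaluation.

Four operators: the fast gradient sign method (FGSM, an L-inf one-step
attack), a direct-optimisation L2 attack (iterative ascent constrained to a
sphere), random event dropping for event-stream inputs, and random
spike-state flips inside the network.  Gradients with respect to the input
come from the same noise-driven backward pass used for learning.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .learning import ndl_backward, rollout_loss
from .network import NetworkSpec, rollout

__all__ = [
    "PerturbConfig",
    "fgsm",
    "direct_opt_attack",
    "event_drop",
    "spike_flip_raster",
    "rollout_with_spike_flips",
]


@dataclass
class PerturbConfig:
    """Attack settings; ``strength`` is gamma / rho / beta depending on kind."""

    kind: str = "fgsm"
    strength: float = 0.0
    iters: int = 30
    step_size: float = 0.002
    adam: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind in ("event_drop", "spike_flip") and not 0.0 <= self.strength <= 1.0:
            raise ValueError("drop/flip probability must lie in [0, 1]")
        if self.strength < 0:
            raise ValueError("perturbation strength must be nonnegative")


def _input_grad(net, x, y, seed, surrogate, loss_mode):
    record = rollout(net, x, seed)
    rep = ndl_backward(
        net, record, y, loss_mode=loss_mode, surrogate=surrogate,
        compute_input_grad=True,
    )
    g = rep.extra["input_grad"]
    loss = rollout_loss(net, record, np.asarray(y).reshape(-1), loss_mode)
    return g, loss


def fgsm(net: NetworkSpec, x_seq, y, gamma: float, *, seed: int = 0,
         surrogate=None, loss_mode: str = "mean") -> np.ndarray:
    """One-step sign attack: x + gamma * sign(grad_x loss).

    The L-inf distortion is exactly gamma wherever the gradient is nonzero
    and zero elsewhere.
    """
    x = np.asarray(x_seq, dtype=float)
    single = x.ndim == 2
    X = x[None] if single else x
    yy = np.atleast_1d(np.asarray(y))
    g, _ = _input_grad(net, X, yy, seed, surrogate, loss_mode)
    adv = X + gamma * np.sign(g)
    return adv[0] if single else adv


def direct_opt_attack(net: NetworkSpec, x_seq, y, gamma: float,
                      cfg: PerturbConfig | None = None, *,
                      surrogate=None, loss_mode: str = "mean"):
    """L2-sphere attack: maximise the loss over ||dx||_2 = gamma.

    The perturbation starts at zero, ascends the loss gradient (plain steps
    or Adam moments) and is renormalised onto the sphere of radius gamma
    after every iteration.  If the gradient vanishes throughout, a random
    point on the sphere is returned and flagged.
    """
    cfg = cfg or PerturbConfig(kind="do")
    x = np.asarray(x_seq, dtype=float)
    single = x.ndim == 2
    X = x[None] if single else x
    yy = np.atleast_1d(np.asarray(y))
    B = X.shape[0]
    if gamma == 0.0:
        return x.copy(), {"flagged_random": False}
    rng = np.random.default_rng(cfg.seed)
    dx = np.zeros_like(X)
    m = np.zeros_like(X)
    v = np.zeros_like(X)
    saw_gradient = np.zeros(B, dtype=bool)
    flat = lambda a: a.reshape(B, -1)
    for it in range(cfg.iters):
        g, _ = _input_grad(net, X + dx, yy, cfg.seed + 1 + it, surrogate, loss_mode)
        gn = np.linalg.norm(flat(g), axis=1)
        saw_gradient |= gn > 0
        if cfg.adam:
            m = 0.9 * m + 0.1 * g
            v = 0.999 * v + 0.001 * g**2
            mh = m / (1 - 0.9 ** (it + 1))
            vh = v / (1 - 0.999 ** (it + 1))
            dx = dx + cfg.step_size * mh / (np.sqrt(vh) + 1e-8)
        else:
            dx = dx + cfg.step_size * g
        norms = np.linalg.norm(flat(dx), axis=1)
        norms = np.where(norms == 0.0, 1.0, norms)
        dx = dx * (gamma / norms)[:, None, None]
    flagged = False
    if not saw_gradient.all():
        flagged = True
        rnd = rng.normal(size=X.shape)
        rnd *= (gamma / np.linalg.norm(flat(rnd), axis=1))[:, None, None]
        dead = ~saw_gradient
        dx[dead] = rnd[dead]
    adv = X + dx
    info = {"flagged_random": flagged}
    return (adv[0], info) if single else (adv, info)


def event_drop(events: pd.DataFrame, rho: float, seed: int = 0) -> pd.DataFrame:
    """Random Drop: delete each event independently with probability rho.

    Uniform per-event deletion realises the combined spatial+temporal
    random-drop marginal; ordering of the surviving rows is preserved.
    """
    if not 0.0 <= rho <= 1.0:
        raise ValueError("rho must lie in [0, 1]")
    if rho == 0.0:
        return events.copy()
    rng = np.random.default_rng(seed)
    keep = rng.random(len(events)) >= rho
    return events.loc[keep].reset_index(drop=True)


def event_drop_window(events: pd.DataFrame, rho: float, seed: int = 0, *,
                      by: str = "time", n_bins: int = 8) -> pd.DataFrame:
    """Dimension-targeted variant: drop whole time windows or spatial bins."""
    if by not in ("time", "space"):
        raise ValueError("by must be 'time' or 'space'")
    rng = np.random.default_rng(seed)
    col = events["t"] if by == "time" else events["x"]
    lo, hi = col.min(), col.max() + 1
    edges = np.linspace(lo, hi, n_bins + 1)
    bin_idx = np.clip(np.searchsorted(edges, col, side="right") - 1, 0, n_bins - 1)
    dropped_bins = rng.random(n_bins) < rho
    keep = ~dropped_bins[bin_idx]
    return events.loc[keep].reset_index(drop=True)


def spike_flip_raster(raster: np.ndarray, beta: float, seed: int = 0) -> np.ndarray:
    """Flip each binary state independently with probability beta."""
    if not 0.0 <= beta <= 1.0:
        raise ValueError("beta must lie in [0, 1]")
    r = np.asarray(raster)
    if not np.isin(r, (0, 1)).all():
        raise ValueError("raster must be binary")
    rng = np.random.default_rng(seed)
    flips = rng.random(r.shape) < beta
    return np.abs(r - flips.astype(r.dtype))


def rollout_with_spike_flips(net, x_seq, beta: float, seed=0, *,
                             flip_last_layer: bool = True):
    """Rollout in which every hidden spike state is flipped with prob beta.

    The flipped spikes enter the dynamics (reset, membrane recurrence and
    downstream drive), not just the readout.
    """
    return rollout(net, x_seq, seed, flip_prob=beta, flip_last_layer=flip_last_layer)
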