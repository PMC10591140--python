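"""Seeded synthetic-data generators.

Every generator is a pure function of its parameters and seed.  Rates are
per-step firing probabilities rather than Hz (the discrete simulation fixes
no physical step duration).  Default toy sizes (20 inputs, 10 steps, 400
samples) keep end-to-end training experiments well under a minute.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .network import NetworkSpec, rollout

__all__ = [
    "gen_poisson_raster",
    "gen_rate_task",
    "gen_teacher_responses",
    "gen_event_stream",
]


def gen_poisson_raster(rates, trials: int = 1, seed: int = 0, T: int | None = None):
    """Bernoulli ("Poisson" at per-step resolution) raster.

    ``rates`` is per-neuron (n,) with ``T`` given, or per-neuron-per-step
    (n, T).  Returns a binary array of shape (trials, n, T).
    """
    rates = np.asarray(rates, dtype=float)
    if rates.ndim == 1:
        if T is None:
            raise ValueError("T is required with per-neuron rates")
        rates = np.broadcast_to(rates[:, None], (rates.shape[0], T))
    if np.any(rates < 0) or np.any(rates > 1):
        raise ValueError("rates are per-step probabilities and must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    return (rng.random((trials,) + rates.shape) < rates).astype(float)


def gen_rate_task(
    n_classes: int = 2,
    n_inputs: int = 20,
    T: int = 10,
    n_samples: int = 400,
    contrast: float = 0.3,
    base: float = 0.2,
    noise_sd: float = 0.3,
    seed: int = 0,
):
    """Two-class (or k-class) firing-rate-pattern classification task.

    Each class elevates the drive of its own contiguous block of inputs by
    ``contrast`` above the shared baseline; i.i.d. Gaussian noise is added
    everywhere.  With contrast 0 the classes are indistinguishable; as the
    contrast grows a linear readout of the time-averaged input separates
    the classes perfectly.  Returns ``(X, y)`` with X of shape
    (n_samples, T, n_inputs) and integer labels y.
    """
    if contrast < 0:
        raise ValueError("contrast must be nonnegative")
    rng = np.random.default_rng(seed)
    y = rng.integers(0, n_classes, size=n_samples)
    block = n_inputs // n_classes
    X = np.full((n_samples, T, n_inputs), base)
    for k in range(n_classes):
        rows = y == k
        lo = k * block
        hi = n_inputs if k == n_classes - 1 else lo + block
        X[rows, :, lo:hi] += contrast
    X += rng.normal(0.0, noise_sd, X.shape)
    return X, y


def gen_teacher_responses(teacher: NetworkSpec, stimuli, trials: int, seed: int = 0):
    """Per-trial rollouts of a (noisy) teacher network.

    Returns rasters of shape (S, trials, n_out, T); with a noisy teacher
    the trials differ and the ensemble Fano factor is positive, emulating
    recorded sensory responses with trial-to-trial variability.
    """
    stimuli = np.asarray(stimuli, dtype=float)
    S, T, _ = stimuli.shape
    X = np.repeat(stimuli, trials, axis=0)
    record = rollout(teacher, X, seed)
    o = record.o[-1]  # (S*trials, T, n)
    return np.swapaxes(o, 1, 2).reshape(S, trials, teacher.sizes[-1], T)


def gen_event_stream(
    pattern: str = "moving_bar",
    density: float = 0.05,
    sensor_size: tuple = (16, 16),
    T: int = 100,
    seed: int = 0,
) -> pd.DataFrame:
    """Toy event-camera stream: a moving pattern plus uniform background.

    Returns a DataFrame with columns (t, x, y, polarity), sorted by t, all
    coordinates within sensor bounds.  Expected event count is about
    density * T * area (half from the pattern, half background).
    """
    if not 0.0 < density <= 1.0:
        raise ValueError("density must lie in (0, 1]")
    W, H = sensor_size
    rng = np.random.default_rng(seed)
    rows = []
    for t in range(T):
        # uniform background events
        n_bg = rng.binomial(W * H, density / 2.0)
        xs = rng.integers(0, W, n_bg)
        ys = rng.integers(0, H, n_bg)
        pol = rng.integers(0, 2, n_bg)
        rows.append(np.column_stack([np.full(n_bg, t), xs, ys, pol]))
        if pattern == "moving_bar":
            col = t % W
            mask = rng.random(H) < min(1.0, density * W / 2.0)
            ys_b = np.nonzero(mask)[0]
            rows.append(
                np.column_stack(
                    [np.full(len(ys_b), t), np.full(len(ys_b), col), ys_b,
                     np.ones(len(ys_b))]
                )
            )
        elif pattern != "background":
            raise ValueError(f"unknown pattern {pattern!r}")
    ev = np.concatenate(rows, axis=0).astype(int)
    df = pd.DataFrame(ev, columns=["t", "x", "y", "polarity"])
    return df.sort_values("t", kind="stable").reset_index(drop=True)
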