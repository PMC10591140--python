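"""Trial-to-trial variability and reliability analytics.

Repeated stochastic rollouts of one input give an ensemble of final-layer
spike counts (the neural code) and prediction vectors.  Spike-count
variability is summarised by the Fano factor (variance over mean, unbiased
sample variance with n-1 denominator); prediction reliability by the mean
pairwise cosine similarity of the prediction vectors.  Correlating mean
Fano factor against prediction similarity across inputs probes whether a
trained network uses a rate-based code: under rate coding, inputs whose
codes vary more between trials yield less stable predictions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .network import NetworkSpec, predict, rollout

__all__ = [
    "TrialEnsemble",
    "trial_ensemble",
    "fano_factor",
    "prediction_similarity",
    "ff_similarity_correlation",
    "coding_summary",
]


@dataclass
class TrialEnsemble:
    """Spike counts (trials x neurons) and predictions (trials x classes)."""

    counts: np.ndarray
    predictions: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        self.predictions = np.asarray(self.predictions, dtype=float)
        if self.counts.ndim != 2 or self.counts.shape[0] < 2:
            raise ValueError("ensemble needs >= 2 trials of (trials, neurons) counts")
        if np.any(self.counts < 0) or np.any(self.counts != np.round(self.counts)):
            raise ValueError("spike counts must be nonnegative integers")

    @property
    def n_trials(self) -> int:
        return self.counts.shape[0]


def trial_ensemble(net: NetworkSpec, x_seq, trials: int, seed: int = 0) -> TrialEnsemble:
    """Repeated rollouts of one input: final-layer counts + averaged predictions."""
    X = np.broadcast_to(np.asarray(x_seq, dtype=float), (trials,) + np.shape(x_seq))
    record = rollout(net, X, seed)
    counts = record.o[-1].sum(axis=1)  # (trials, n_L)
    _, preds = predict(net, record)
    return TrialEnsemble(counts=counts, predictions=preds)


def fano_factor(ensemble: TrialEnsemble):
    """Per-neuron Fano factor and its mean over non-silent neurons.

    Neurons with zero mean count are excluded (their FF is undefined) and
    reported.  Returns ``(ff_per_neuron, mean_ff, included_mask)`` where
    excluded entries are NaN.
    """
    counts = ensemble.counts
    if counts.shape[0] < 2:
        raise ValueError("Fano factor needs at least 2 trials")
    mean = counts.mean(axis=0)
    var = counts.var(axis=0, ddof=1)
    included = mean > 0
    ff = np.full(counts.shape[1], np.nan)
    ff[included] = var[included] / mean[included]
    mean_ff = float(ff[included].mean()) if included.any() else float("nan")
    return ff, mean_ff, included


def prediction_similarity(ensemble: TrialEnsemble) -> float:
    """Mean cosine similarity over unordered trial pairs of predictions.

    Zero-norm prediction vectors are excluded pairwise (flagged by raising
    only if fewer than two nonzero vectors remain).
    """
    P = ensemble.predictions
    norms = np.linalg.norm(P, axis=1)
    ok = norms > 0
    if ok.sum() < 2:
        raise ValueError("fewer than two nonzero prediction vectors")
    U = P[ok] / norms[ok][:, None]
    G = U @ U.T
    n = U.shape[0]
    iu = np.triu_indices(n, k=1)
    return float(G[iu].mean())


def ff_similarity_correlation(mean_ffs, similarities):
    """Pearson correlation between per-input mean FF and prediction similarity.

    Returns ``(r, p)``; the p-value comes from the usual t transform and is
    reported for context, not used for gating.
    """
    x = np.asarray(mean_ffs, dtype=float)
    y = np.asarray(similarities, dtype=float)
    if x.size < 3:
        raise ValueError("need at least 3 inputs")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero variance in FF or similarity; correlation undefined")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)


def coding_summary(net: NetworkSpec, X, trials: int = 20, seed: int = 0):
    """Per-input (mean FF, prediction similarity) table plus their correlation.

    ``X`` has shape (n_inputs, T, d).  Returns ``(ffs, sims, r, p)``.
    """
    ffs, sims = [], []
    for i, x in enumerate(np.asarray(X, dtype=float)):
        ens = trial_ensemble(net, x, trials, seed=seed + i)
        _, mean_ff, _ = fano_factor(ens)
        ffs.append(mean_ff)
        sims.append(prediction_similarity(ens))
    ffs = np.asarray(ffs)
    sims = np.asarray(sims)
    keep = np.isfinite(ffs)
    r, p = ff_similarity_correlation(ffs[keep], sims[keep])
    return ffs, sims, r, p
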