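"""Canned desk-scale experiments shared by the CLI, tests and scripts.

Each function fixes one study design (network shape, task sizes, training
budget) so that results quoted anywhere in the project come from a single
definition.  All randomness flows from the seed argument.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .coding import coding_summary
from .learning import TrainConfig, erf_surrogate, evaluate_accuracy, train
from .network import Affine, LayerSpec, NetworkSpec, SoftmaxHead, make_mlp
from .neuron import NeuronParams, NoiseModel
from .spikefit import FitConfig, fit_activity, rate_correlation, simulate_rasters
from .synth import gen_rate_task, gen_teacher_responses

__all__ = [
    "rate_task_experiment",
    "sigma_sweep",
    "single_layer_population",
    "teacher_student_experiment",
    "coding_experiment",
]


def rate_task_experiment(
    sigma: float = 0.3,
    seed: int = 0,
    *,
    epochs: int = 50,
    hidden=(30, 20),
    lr: float = 0.5,
    n_test: int = 200,
    deterministic: bool = False,
) -> dict:
    """Train a two-spiking-layer classifier on the synthetic rate task.

    With ``deterministic`` the network has Heaviside neurons and trains by
    surrogate gradients (matched ERF bump) instead of noise densities.
    Returns final train/test accuracy and the learning curve.
    """
    X, y = gen_rate_task(seed=seed)
    Xte, yte = gen_rate_task(n_samples=n_test, seed=10_000 + seed)
    noise = NoiseModel("none", 1.0) if deterministic else NoiseModel("gaussian", sigma)
    net = make_mlp(X.shape[2], list(hidden), 2, noise=noise, seed=seed)
    cfg = TrainConfig(epochs=epochs, lr=lr, seed=seed,
                      surrogate=erf_surrogate() if deterministic else None)
    net, curve = train(net, X, y, cfg)
    return {
        "net": net,
        "curve": curve,
        "train_accuracy": float(curve["accuracy"].iloc[-1]),
        "test_accuracy": evaluate_accuracy(net, Xte, yte, seed=99),
        "task": (X, y),
    }


def sigma_sweep(sigmas=(0.3, 3.0), seeds=range(5), *, epochs: int = 50) -> pd.DataFrame:
    """Accuracy of identically built/trained networks across noise scales."""
    rows = []
    for sigma in sigmas:
        for seed in seeds:
            res = rate_task_experiment(sigma, seed, epochs=epochs)
            rows.append({"sigma": sigma, "seed": seed,
                         "train_accuracy": res["train_accuracy"],
                         "test_accuracy": res["test_accuracy"]})
    return pd.DataFrame(rows)


def single_layer_population(
    n_in: int = 5,
    n_out: int = 8,
    *,
    sigma: float = 0.2,
    seed: int = 0,
    weight_scale: float = 1.2,
    bias: float = 0.5,
    family: str = "gaussian",
) -> NetworkSpec:
    """One spiking layer biased near threshold (a small sensory population).

    The positive bias keeps baseline membranes near v_th so most neurons
    have moderate, stimulus-modulated firing rates.
    """
    rng = np.random.default_rng(seed)
    W = rng.normal(0.0, weight_scale / np.sqrt(n_in), (n_out, n_in))
    noise = NoiseModel(family, sigma) if family != "none" else NoiseModel("none", 1.0)
    layer = LayerSpec(Affine(W, np.full(n_out, bias)), NeuronParams(), noise)
    head = SoftmaxHead(np.zeros((2, n_out)), np.zeros(2))
    return NetworkSpec([layer], head)


def teacher_student_experiment(
    seed: int = 0,
    *,
    student_noise: str = "gaussian",  # "none" => deterministic student
    n_stimuli: int = 60,
    n_heldout: int = 15,
    T: int = 30,
    epochs: int = 200,
    lr: float = 0.1,
    eval_trials: int = 20,
) -> dict:
    """Teacher-student spike-train fitting with the PSP-MMD loss.

    A noisy single-layer teacher generates trial-varying "recorded"
    rasters; a student of the same shape is fitted to them and evaluated on
    held-out stimuli by the Pearson correlation of smoothed rate curves and
    by trial-to-trial Fano factors.  A deterministic student
    (``student_noise='none'``) trains through the matched ERF surrogate and
    produces identical repeats (between-trial FF exactly 0).
    """
    rng = np.random.default_rng(seed)
    d, n_out = 5, 8
    teacher = single_layer_population(d, n_out, sigma=0.2, seed=seed)
    stim_tr = rng.normal(0.5, 0.5, (n_stimuli, T, d))
    stim_te = rng.normal(0.5, 0.5, (n_heldout, T, d))
    tgt_tr = gen_teacher_responses(teacher, stim_tr, trials=5, seed=seed + 10)
    tgt_te = gen_teacher_responses(teacher, stim_te, trials=eval_trials, seed=seed + 20)

    deterministic = student_noise == "none"
    student = single_layer_population(
        d, n_out, sigma=0.2, seed=seed + 100, weight_scale=0.8,
        family=student_noise,
    )
    cfg = FitConfig(epochs=epochs, lr=lr, seed=seed,
                    surrogate=erf_surrogate() if deterministic else None)
    student, curve = fit_activity(student, stim_tr, tgt_tr, cfg)
    rs, mean_r = rate_correlation(student, stim_te, tgt_te,
                                  trials=eval_trials, seed=seed + 30)
    pred = simulate_rasters(student, stim_te, eval_trials, seed + 40)

    def mean_ff(rasters):  # rasters (S, trials, n, T)
        counts = rasters.sum(axis=3)  # (S, trials, n)
        m = counts.mean(axis=1)
        v = counts.var(axis=1, ddof=1)
        ok = m > 0
        return float((v[ok] / m[ok]).mean()) if ok.any() else 0.0

    return {
        "student": student,
        "teacher": teacher,
        "curve": curve,
        "per_neuron_r": rs,
        "mean_r": mean_r,
        "student_ff": mean_ff(pred),
        "teacher_ff": mean_ff(tgt_te),
    }


def coding_experiment(
    seed: int = 0,
    *,
    sigma: float = 0.3,
    n_inputs: int = 100,
    trials: int = 20,
    epochs: int = 20,
) -> dict:
    """Fano factor vs prediction-similarity correlation on a trained network."""
    res = rate_task_experiment(sigma, seed, epochs=epochs)
    X, _ = gen_rate_task(n_samples=n_inputs, seed=20_000 + seed)
    ffs, sims, r, p = coding_summary(res["net"], X, trials=trials, seed=seed)
    return {"mean_ff": ffs, "similarity": sims, "pearson_r": r, "p_value": p}
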