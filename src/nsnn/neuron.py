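"""Noisy and deterministic leaky integrate-and-fire (LIF) neuron dynamics.

The membrane potential follows the discrete leaky integrator
``u_t = tau * u_{t-1} + drive_t`` and firing is a Bernoulli event whose
probability is the membrane-noise cumulative distribution function evaluated
at ``u_t - v_th`` (escape-noise convention).  The carried state is the
noise-free accumulation; membrane noise is marginalised analytically into
the firing probability.  After a spike the membrane is hard-reset to
``u_reset`` within the same step.

The deterministic LIF neuron is the zero-noise special case: the firing
probability collapses to a (strict) Heaviside step at the threshold.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

import numpy as np
from scipy.special import expit, ndtr


class NoiseFamily(str, Enum):
    GAUSSIAN = "gaussian"
    LOGISTIC = "logistic"
    UNIFORM = "uniform"
    NONE = "none"


@dataclass(frozen=True)
class NoiseModel:
    """Zero-mean symmetric membrane-noise distribution.

    ``scale`` is the standard deviation for the Gaussian family, the scale
    parameter for the logistic family and the half-width for the uniform
    family; it is ignored for ``none`` (the deterministic neuron).
    """

    family: NoiseFamily = NoiseFamily.GAUSSIAN
    scale: float = 0.3

    def __post_init__(self) -> None:
        object.__setattr__(self, "family", NoiseFamily(self.family))
        if self.family is not NoiseFamily.NONE and not self.scale > 0:
            raise ValueError(f"noise scale must be positive, got {self.scale}")

    @property
    def is_deterministic(self) -> bool:
        return self.family is NoiseFamily.NONE

    def cdf(self, x):
        return noise_cdf(x, self)

    def pdf(self, x):
        return noise_pdf(x, self)

    def pdf_peak(self) -> float:
        """Density at the mode (x = 0)."""
        return float(noise_pdf(0.0, self))

    def sample(self, rng: np.random.Generator, size):
        """Draw membrane-noise realisations (explicit-noise mode)."""
        if self.family is NoiseFamily.GAUSSIAN:
            return rng.normal(0.0, self.scale, size)
        if self.family is NoiseFamily.LOGISTIC:
            return rng.logistic(0.0, self.scale, size)
        if self.family is NoiseFamily.UNIFORM:
            return rng.uniform(-self.scale, self.scale, size)
        return np.zeros(size)


def _check_finite(x: np.ndarray, what: str) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    if not np.all(np.isfinite(x)):
        raise ValueError(f"non-finite value in {what}")
    return x


def noise_cdf(x, nm: NoiseModel):
    """Firing probability F_eps(x) at membrane-threshold gap ``x``.

    For the deterministic family this is the strict Heaviside step: the
    neuron fires only for x > 0 (F(0) = 0, fixed for reproducibility).
    """
    x = _check_finite(x, "noise_cdf input")
    if nm.family is NoiseFamily.GAUSSIAN:
        return ndtr(x / nm.scale)
    if nm.family is NoiseFamily.LOGISTIC:
        return expit(x / nm.scale)
    if nm.family is NoiseFamily.UNIFORM:
        return np.clip((x + nm.scale) / (2.0 * nm.scale), 0.0, 1.0)
    return (x > 0).astype(float)


def noise_pdf(x, nm: NoiseModel):
    """Membrane-noise density F_eps'(x) — the post-synaptic learning factor."""
    x = _check_finite(x, "noise_pdf input")
    if nm.family is NoiseFamily.GAUSSIAN:
        s = nm.scale
        return np.exp(-0.5 * (x / s) ** 2) / (s * np.sqrt(2.0 * np.pi))
    if nm.family is NoiseFamily.LOGISTIC:
        p = expit(x / nm.scale)
        return p * (1.0 - p) / nm.scale
    if nm.family is NoiseFamily.UNIFORM:
        return np.where(np.abs(x) <= nm.scale, 1.0 / (2.0 * nm.scale), 0.0)
    raise ValueError(
        "deterministic neuron (family='none') has no density and hence no "
        "learning factor; use a SurrogateSpec instead"
    )


@dataclass(frozen=True)
class NeuronParams:
    """LIF constants: leak tau in [0, 1), threshold v_th, reset potential."""

    tau: float = 0.5
    v_th: float = 1.0
    u_reset: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.tau < 1.0:
            raise ValueError(f"tau must lie in [0, 1), got {self.tau}")


@dataclass
class NeuronState:
    """Membrane potential and last spike vector of a neuron population."""

    u: np.ndarray
    o: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.u = np.asarray(self.u, dtype=float)
        if self.o is None:
            self.o = np.zeros_like(self.u)
        self.o = np.asarray(self.o, dtype=float)

    @classmethod
    def zeros(cls, n: int, params: NeuronParams | None = None) -> "NeuronState":
        u0 = (params.u_reset if params is not None else 0.0) * np.ones(n)
        return cls(u=u0, o=np.zeros(n))


def step(
    state: NeuronState,
    drive: np.ndarray,
    nm: NoiseModel,
    params: NeuronParams,
    rng: np.random.Generator,
    *,
    explicit_noise: bool = False,
):
    """One discrete update of a noisy LIF population.

    Returns ``(new_state, p_fire, o)``.  The default mode marginalises the
    membrane noise: the carried potential is the deterministic accumulation
    and the spike is Bernoulli(F_eps(u - v_th)).  With ``explicit_noise`` a
    noise realisation is drawn, added to the membrane and carried forward
    (used by the stability demonstrations); firing then thresholds the noisy
    potential directly.
    """
    drive = _check_finite(drive, "drive")
    if drive.shape != state.u.shape:
        raise ValueError(f"drive shape {drive.shape} != state shape {state.u.shape}")
    u_new = params.tau * state.u + drive
    if explicit_noise and not nm.is_deterministic:
        u_new = u_new + nm.sample(rng, u_new.shape)
        p_fire = (u_new > params.v_th).astype(float)
        o = p_fire.copy()
    else:
        p_fire = noise_cdf(u_new - params.v_th, nm)
        if nm.is_deterministic:
            o = p_fire.copy()
        else:
            o = (rng.random(u_new.shape) < p_fire).astype(float)
    u_stored = np.where(o == 1.0, params.u_reset, u_new)
    return NeuronState(u=u_stored, o=o), p_fire, o
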