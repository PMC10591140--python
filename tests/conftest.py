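import numpy as np
import pytest

from nsnn.network import Affine, LayerSpec, NetworkSpec, SoftmaxHead
from nsnn.neuron import NeuronParams, NoiseModel


def make_tiny_net(seed: int = 0, sigma: float = 0.3) -> NetworkSpec:
    """2-3-2 classifier with all marginal firing probabilities moderate.

    Weights/biases are drawn around 0.5/0.4 so that no spike variable is a
    near-certain event — Monte-Carlo estimator comparisons then have finite
    relative standard errors for every parameter.
    """
    rng = np.random.default_rng(seed)
    nm = NoiseModel("gaussian", sigma)
    layers, fan = [], 2
    for n in (2, 3, 2):
        W = rng.normal(0.5, 0.4, (n, fan))
        b = rng.normal(0.4, 0.1, n)
        layers.append(LayerSpec(Affine(W, b), NeuronParams(), nm))
        fan = n
    head = SoftmaxHead(rng.normal(0.0, 0.8, (2, 2)), np.zeros(2))
    return NetworkSpec(layers, head)


@pytest.fixture
def tiny_net() -> NetworkSpec:
    return make_tiny_net(0)


@pytest.fixture
def tiny_x() -> np.ndarray:
    return np.random.default_rng(100).normal(0.4, 0.3, (2, 2))
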