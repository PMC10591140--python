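"""Enumeration oracle and local-marginalisation estimators."""

import numpy as np
import pytest

from nsnn.learning import ndl_backward, rollout_loss
from nsnn.network import (
    Affine,
    LayerSpec,
    LinearSpikeLoss,
    MultilinearSpikeLoss,
    NetworkSpec,
    SoftmaxHead,
    SpikeFunctionHead,
    make_mlp,
    rollout,
)
from nsnn.neuron import NeuronParams, NoiseModel
from nsnn.oracle import (
    bias_variance_report,
    enumerate_expected_loss,
    exact_gradient,
    finite_difference_gradient,
    local_marginal_estimate,
    mc_gradient_mean,
)

from conftest import make_tiny_net


def single_neuron_net(w=0.8, b=0.3, sigma=0.3, loss=None):
    return NetworkSpec(
        [LayerSpec(Affine(np.array([[w]]), np.array([b])), NeuronParams(),
                   NoiseModel("gaussian", sigma))],
        SpikeFunctionHead(loss or LinearSpikeLoss(np.array([1.0]))),
    )


class TestEnumeration:
    def test_single_bernoulli_mean(self):
        # p = 0.5 at threshold; E[o] = 0.5
        net = single_neuron_net(w=0.0, b=1.0)
        EL, enum = enumerate_expected_loss(net, np.zeros((1, 1)))
        assert EL == pytest.approx(0.5)
        assert enum.prob.sum() == pytest.approx(1.0, abs=1e-12)

    def test_two_independent_neurons_product_loss(self):
        # two neurons at p = 0.5, f = o1 * o2 => E = 0.25
        A = np.zeros((2, 2))
        A[0, 1] = 1.0
        net = NetworkSpec(
            [LayerSpec(Affine(np.zeros((2, 1)), np.array([1.0, 1.0])),
                       NeuronParams(), NoiseModel("gaussian", 0.3))],
            SpikeFunctionHead(MultilinearSpikeLoss(np.zeros(2), A)),
        )
        EL, _ = enumerate_expected_loss(net, np.zeros((1, 1)))
        assert EL == pytest.approx(0.25)

    def test_probability_sums_to_one(self, tiny_net, tiny_x):
        _, enum = enumerate_expected_loss(tiny_net, tiny_x, 0)
        assert enum.prob.sum() == pytest.approx(1.0, abs=1e-9)
        assert enum.n_configs == 2 ** 14

    def test_monte_carlo_loss_matches_enumeration(self):
        net = make_tiny_net(4)
        x = np.random.default_rng(5).normal(0.4, 0.3, (2, 2))
        EL, enum = enumerate_expected_loss(net, x, 1)
        n = 100_000
        rec = rollout(net, np.broadcast_to(x, (n, 2, 2)), 6)
        losses = rollout_loss(net, rec, np.ones(n, dtype=int))
        se = losses.std(ddof=1) / np.sqrt(n)
        assert abs(losses.mean() - EL) < 3 * se

    def test_cap_exceeded(self):
        net = make_mlp(2, [5, 5], 2, seed=0)
        with pytest.raises(ValueError, match="binary variables"):
            enumerate_expected_loss(net, np.zeros((2, 2)), 0)


class TestExactGradient:
    def test_constant_loss_zero_gradient(self):
        net = single_neuron_net(loss=LinearSpikeLoss(np.array([0.0])))
        rep = exact_gradient(net, np.array([[0.9]]))
        assert all(np.all(g == 0.0) for g in rep.grads.values())

    def test_single_neuron_closed_form(self):
        # T=1, f(o)=o: dE/db = F'(u - v_th), u = w*x + b
        net = single_neuron_net(w=0.8, b=0.3, sigma=0.3)
        x = np.array([[0.9]])
        u = 0.8 * 0.9 + 0.3
        expected = NoiseModel("gaussian", 0.3).pdf(u - 1.0)
        rep = exact_gradient(net, x)
        assert rep.grads["layer0.b"][0] == pytest.approx(float(expected), rel=1e-10)
        assert rep.grads["layer0.W"][0, 0] == pytest.approx(float(expected) * 0.9, rel=1e-10)

    def test_matches_finite_differences(self, tiny_net, tiny_x):
        ex = exact_gradient(tiny_net, tiny_x, 0)
        fd = finite_difference_gradient(tiny_net, tiny_x, 0)
        for k in ex.grads:
            scale = np.abs(fd.grads[k]).max() + 1e-12
            assert np.abs(ex.grads[k] - fd.grads[k]).max() / scale < 1e-4


class TestLocalMarginal:
    def test_first_order_equals_ndl_backward(self, tiny_net, tiny_x):
        """The first-order conditioning estimator, assembled from explicit
        pre-synaptic factors and spike adjoints, reproduces the BPTT result."""
        X = np.broadcast_to(tiny_x, (13, 2, 2))
        rec = rollout(tiny_net, X, 21)
        y = np.ones(13, dtype=int)
        lm = local_marginal_estimate(tiny_net, rec, y, exact_delta=False).grads
        nd = ndl_backward(tiny_net, rec, y).grads
        for k in nd:
            assert np.abs(lm[k] - nd[k]).max() < 1e-12

    def test_exact_and_first_order_identical_for_multilinear_single_layer(self):
        """First-order loss differences are exact for a multilinear map."""
        rng = np.random.default_rng(0)
        net = NetworkSpec(
            [LayerSpec(Affine(rng.normal(0.5, 0.4, (3, 2)), rng.normal(0.4, 0.1, 3)),
                       NeuronParams(), NoiseModel("gaussian", 0.3))],
            SpikeFunctionHead(MultilinearSpikeLoss(rng.normal(0, 1, 3),
                                                   rng.normal(0, 1, (3, 3)))),
        )
        x = rng.normal(0.4, 0.3, (1, 2))
        rec = rollout(net, np.broadcast_to(x, (50, 1, 2)), 3)
        g_ex = local_marginal_estimate(net, rec, exact_delta=True, reduce=False).grads
        g_fo = local_marginal_estimate(net, rec, exact_delta=False, reduce=False).grads
        for k in g_ex:
            assert np.allclose(g_ex[k], g_fo[k], atol=1e-10)

    def test_exact_delta_unbiased_small(self):
        """Monte-Carlo mean of the exact-flip estimator hits the enumeration
        gradient (moderate sample version of the headline property)."""
        net = make_tiny_net(0)
        x = np.random.default_rng(100).normal(0.4, 0.3, (2, 2))
        ex = exact_gradient(net, x, 0)
        mc = mc_gradient_mean(net, x, 0, estimator="local_marginal_exact",
                              n_samples=40_000, seed=17, batch=5000)
        for k in ex.grads:
            z = np.abs(mc.grads[k] - ex.grads[k]) / np.maximum(mc.se[k], 1e-15)
            assert z.max() < 4.0

    def test_exact_delta_cap(self):
        net = make_mlp(2, [5, 5], 2, seed=0)
        rec = rollout(net, np.zeros((2, 2)), 0)
        with pytest.raises(ValueError, match="cap"):
            local_marginal_estimate(net, rec, np.array([0]), exact_delta=True)

    def test_degenerate_probabilities_flagged(self):
        net = single_neuron_net(w=0.0, b=5.0, sigma=0.05)  # p == 1 numerically
        rec = rollout(net, np.array([[0.0]]), 0)
        rep = local_marginal_estimate(net, rec, exact_delta=True)
        assert rep.extra["degenerate"]


class TestBiasVarianceReport:
    def test_report_structure_and_enumeration_row(self):
        net = make_tiny_net(3)
        x = np.random.default_rng(9).normal(0.4, 0.3, (1, 2))
        df = bias_variance_report(net, x, 0,
                                  estimators=("enumeration", "ndl"),
                                  n_samples=4000, seed=1)
        enum_rows = df[df["estimator"] == "enumeration"]
        assert (enum_rows["bias_rms"] == 0).all()
        assert np.isfinite(df[df["estimator"] == "ndl"]["bias_rms"]).all()

    def test_variance_scales_inversely_with_samples(self):
        net = make_tiny_net(3)
        x = np.random.default_rng(9).normal(0.4, 0.3, (1, 2))
        se_n = mc_gradient_mean(net, x, 0, estimator="ndl", n_samples=8000,
                                seed=2).se["layer0.W"]
        se_4n = mc_gradient_mean(net, x, 0, estimator="ndl", n_samples=32000,
                                 seed=3).se["layer0.W"]
        ratio = (se_n / se_4n) ** 2
        assert np.all((ratio > 4 * 0.7) & (ratio < 4 * 1.3))
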