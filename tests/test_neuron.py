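"""Single-neuron dynamics: firing law, noise densities, reset behaviour."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st_

from nsnn.neuron import (
    NeuronParams,
    NeuronState,
    NoiseModel,
    noise_cdf,
    noise_pdf,
    step,
)

FAMILIES = ["gaussian", "logistic", "uniform"]


class TestFiringLaw:
    @pytest.mark.parametrize(
        "x,nm,expected",
        [
            (0.0, NoiseModel("gaussian", 0.3), 0.5),
            (0.3, NoiseModel("gaussian", 0.3), 0.8413447460685429),
            (0.5 * np.log(3), NoiseModel("logistic", 0.5), 0.75),
            (0.0, NoiseModel("logistic", 0.2), 0.5),
            (0.0, NoiseModel("uniform", 0.4), 0.5),
            (0.4, NoiseModel("uniform", 0.4), 1.0),
            (1.0, NoiseModel("none", 1.0), 1.0),
            (0.0, NoiseModel("none", 1.0), 0.0),  # strict threshold
            (-0.1, NoiseModel("none", 1.0), 0.0),
        ],
    )
    def test_cdf_closed_forms(self, x, nm, expected):
        assert noise_cdf(x, nm) == pytest.approx(expected, abs=1e-12)

    @pytest.mark.parametrize(
        "nm,expected",
        [
            (NoiseModel("gaussian", 0.3), 1.0 / (0.3 * np.sqrt(2 * np.pi))),
            (NoiseModel("logistic", 0.5), 1.0 / (4 * 0.5)),
            (NoiseModel("uniform", 0.4), 1.0 / 0.8),
        ],
    )
    def test_pdf_peak_at_zero(self, nm, expected):
        assert noise_pdf(0.0, nm) == pytest.approx(expected, rel=1e-12)

    @pytest.mark.parametrize("family", FAMILIES)
    def test_pdf_integrates_to_one(self, family):
        nm = NoiseModel(family, 0.37)
        x = np.linspace(-8, 8, 200_001)
        integral = np.trapezoid(noise_pdf(x, nm), x)
        assert integral == pytest.approx(1.0, abs=1e-3)

    @pytest.mark.parametrize("family", FAMILIES)
    def test_pdf_is_cdf_derivative(self, family):
        nm = NoiseModel(family, 0.5)
        x = np.linspace(-2, 2, 401)
        h = 1e-6
        fd = (noise_cdf(x + h, nm) - noise_cdf(x - h, nm)) / (2 * h)
        # skip the uniform kink points
        keep = np.abs(np.abs(x) - nm.scale) > 1e-3
        assert np.allclose(noise_pdf(x, nm)[keep], fd[keep], atol=1e-6)

    @settings(derandomize=True, max_examples=60)
    @given(
        x1=st_.floats(-5, 5),
        x2=st_.floats(-5, 5),
        scale=st_.floats(0.05, 3.0),
        family=st_.sampled_from(FAMILIES),
    )
    def test_cdf_monotone_and_symmetric(self, x1, x2, scale, family):
        nm = NoiseModel(family, scale)
        lo, hi = min(x1, x2), max(x1, x2)
        assert noise_cdf(lo, nm) <= noise_cdf(hi, nm) + 1e-15
        assert noise_cdf(x1, nm) + noise_cdf(-x1, nm) == pytest.approx(1.0, abs=1e-12)

    def test_errors(self):
        with pytest.raises(ValueError):
            noise_cdf(np.nan, NoiseModel("gaussian", 0.3))
        with pytest.raises(ValueError):
            NoiseModel("gaussian", -1.0)
        with pytest.raises(ValueError, match="no density"):
            noise_pdf(0.0, NoiseModel("none", 1.0))


class TestStep:
    def test_strong_drive_fires_and_resets(self):
        nm = NoiseModel("gaussian", 1e-12)
        st = NeuronState.zeros(1)
        st2, p, o = step(st, np.array([2.0]), nm, NeuronParams(), np.random.default_rng(0))
        assert p[0] == 1.0 and o[0] == 1.0 and st2.u[0] == 0.0

    def test_half_probability_at_threshold(self):
        nm = NoiseModel("gaussian", 0.3)
        st = NeuronState.zeros(1)
        _, p, _ = step(st, np.array([1.0]), nm, NeuronParams(), np.random.default_rng(0))
        assert p[0] == pytest.approx(0.5)

    def test_deterministic_hand_recursion(self):
        # drive 0.6 then 0.8 from rest: u=0.6 (no spike), then 0.5*0.6+0.8=1.1>1
        nm = NoiseModel("none", 1.0)
        params = NeuronParams(tau=0.5, v_th=1.0, u_reset=0.0)
        st = NeuronState.zeros(1)
        rng = np.random.default_rng(0)
        st, _, o1 = step(st, np.array([0.6]), nm, params, rng)
        assert o1[0] == 0.0 and st.u[0] == pytest.approx(0.6)
        st, _, o2 = step(st, np.array([0.8]), nm, params, rng)
        assert o2[0] == 1.0 and st.u[0] == 0.0

    @pytest.mark.parametrize("family", FAMILIES)
    def test_empirical_firing_frequency_matches_cdf(self, family):
        nm = NoiseModel(family, 0.3)
        params = NeuronParams()
        n = 100_000
        st = NeuronState(u=np.zeros(n))
        drive = np.full(n, 1.2)  # u - v_th = 0.2
        _, p, o = step(st, drive, nm, params, np.random.default_rng(42))
        expect = noise_cdf(0.2, nm)
        se = np.sqrt(expect * (1 - expect) / n)
        assert abs(o.mean() - expect) < 3 * se

    def test_reset_idempotence(self):
        params = NeuronParams(tau=0.5, v_th=1.0, u_reset=0.2)
        nm = NoiseModel("gaussian", 1e-12)
        st = NeuronState.zeros(1, params)
        st, _, o = step(st, np.array([2.0]), nm, params, np.random.default_rng(0))
        assert o[0] == 1.0 and st.u[0] == params.u_reset
        st, _, _ = step(st, np.array([0.0]), nm, params, np.random.default_rng(1))
        assert st.u[0] == pytest.approx(params.tau * params.u_reset)

    def test_shape_and_finiteness_errors(self):
        nm = NoiseModel("gaussian", 0.3)
        st = NeuronState.zeros(2)
        with pytest.raises(ValueError):
            step(st, np.array([1.0]), nm, NeuronParams(), np.random.default_rng(0))
        with pytest.raises(ValueError):
            step(st, np.array([np.inf, 0.0]), nm, NeuronParams(), np.random.default_rng(0))

    def test_explicit_noise_mode_carries_noisy_state(self):
        nm = NoiseModel("gaussian", 0.3)
        st = NeuronState.zeros(1)
        st2, _, o = step(st, np.array([0.5]), nm, NeuronParams(),
                         np.random.default_rng(5), explicit_noise=True)
        if o[0] == 0.0:
            assert st2.u[0] != pytest.approx(0.5)  # noise realisation carried
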