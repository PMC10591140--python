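# Methods

## The neuron model

The package simulates discrete-time leaky integrate-and-fire (LIF) neurons
with membrane noise.  The sub-threshold recursion is

    u_t = tau * u_{t-1} + phi_theta(x_t) + eps,

with leak `tau = 0.5`, threshold `v_th = 1`, hard reset to `u_reset = 0`
after a spike, and `eps` drawn i.i.d. from a zero-mean symmetric
distribution.  Because the noise enters additively, it can be marginalised
analytically at the threshold test: the spike is a Bernoulli variable with

    P[o_t = 1] = F_eps(u_t - v_th),

where `F_eps` is the noise cumulative distribution function (the
escape-noise convention).  The implementation therefore carries the
*noise-free* membrane state forward and samples the spike from the
analytic probability.  The alternative — sampling `eps` explicitly and
carrying the noisy state — changes what the recurrence accumulates; it is
available as `step(..., explicit_noise=True)` for the stability
demonstrations, but the marginalised form is the default because it is the
form under which the firing law, the learning rule, and the deterministic
limit are exact statements.

Three noise families are supported (Gaussian, logistic, uniform), each
parameterised by a single scale (standard deviation, logistic scale, and
half-width respectively).  The default is Gaussian with scale 0.3 — large
enough that the learning factor below carries information, small enough
that the membrane dynamics are not swamped.  The deterministic neuron is
the `none` family: its "cdf" is the strict Heaviside step.  At exactly
`u = v_th` the deterministic neuron does *not* fire; the tie is a
measure-zero event and fixing it one way keeps every rollout reproducible.

## Networks and the joint spike distribution

A network is a stack of affine-drive spiking layers plus a softmax
predictive head (or an arbitrary differentiable loss on the final spike
vector).  Within a time step, layers are evaluated bottom-up on the
same-step spikes of the layer below; the only unit delay is the membrane
recurrence itself.  Conditioned on its parents (previous-layer same-step
spikes and its own history through leak and reset), every spike is an
independent Bernoulli variable, so a full rollout factorises as a directed
graphical model; `joint_log_prob` evaluates that factorisation and the
test suite checks it sums to one over exhaustive enumeration of tiny
networks.  The instantaneous loss is computed every step; the trainer
averages losses over the `T` steps by default, with `loss_mode` switching
to sum or last-step-only.

Time is 1..T in prose and 0-based in storage — stated here once and
checked in the tests.

## Noise-driven learning

The gradient of the expected loss with respect to a layer's parameters is
estimated by a backward pass in which the non-existent spike derivative
do/du is replaced by the noise density `F_eps'(u - v_th)`.  The rule is
three-factor: pre-synaptic factor (the parameter gradient of the
membrane), post-synaptic factor (the noise density), and a global learning
signal (the loss gradient with respect to the spike, chained through
layers and time).  Two deliberate conventions:

* **Reset path blocked.**  A spike's effect on *later* membranes through
  the hard reset is not differentiated; temporal credit flows only through
  `tau * (1 - o_t)`.  This keeps the estimator assembly local and matches
  common practice for backpropagation-through-time in spiking networks.
* **Surrogate equivalence.**  Replacing the density by any symmetric bump
  recovers surrogate-gradient learning.  `surrogate_from_noise` and
  `noise_from_surrogate` convert in both directions; the widely used ERF
  surrogate `(1/pi) exp(-x^2)` corresponds to Gaussian membrane noise with
  sigma = 1/sqrt(2) and a learning-rate multiplier 1/sqrt(pi).  On a fixed
  rollout, NDL with Gaussian noise and the matched erf-like surrogate
  produce bit-identical backward passes (asserted to 1e-10 relative).

## Validation oracles

For networks with at most 16 spike variables (`N * T <= 16`) the package
computes ground truth by brute force:

* `enumerate_expected_loss` sums the loss over all `2^(N*T)`
  configurations, respecting the temporal structure (membranes are
  propagated per forced history, resets applied).
* `exact_gradient` differentiates that sum analytically: layer parameters
  through the score function of each Bernoulli factor, head parameters
  through the probability-weighted direct loss gradient.  It is
  cross-checked against central finite differences (h = 1e-5, 1e-4
  relative agreement) in the tests.
* `local_marginal_estimate` is the conditioning estimator: one sampled
  rollout, one exact two-point summation per spike variable.  With
  `exact_delta=True` the loss difference of each flip is evaluated by
  **re-propagating every downstream variable under the rollout's stored
  uniform draws** (common random numbers).  This coupling is what makes
  the flip estimator unbiased when the loss is temporally coupled: holding
  the uniforms fixed, the re-simulation is a proper conditional sample of
  the descendants given the flipped value, and non-descendants reproduce
  themselves exactly.  A cheaper same-step-only flip mode is provided for
  comparison.  With `exact_delta=False` the loss difference is replaced by
  its first-order expansion, and the result coincides with the NDL
  backward pass — the identity is implemented twice (local-marginal
  assembly with explicit pre-synaptic factors vs. BPTT accumulation) and
  asserted to 1e-12.

The first-order expansion is exact when the loss is multilinear in each
spike variable *with everything else held fixed*.  With temporal coupling
(leak/reset) or stochastic downstream layers, flipping a spike also moves
the conditional distribution of later variables, so the bias-vanishing
statement is exercised where it holds literally: a single spiking layer at
`T = 1` with a multilinear readout.  For the default cross-entropy head the
NDL bias is *reported* by `bias_variance_report`, never asserted small.

## Stochastic stability

The continuous-time membrane of a noisy LIF layer is the linear SDE
`du = (a1 u + B1 I) dt + (a2 + b2 (a1 u + B1 I)) dW` with `a1 = -1/tau_m`,
additive amplitude `a2 = sigma`, multiplicative amplitude `b2`.  Stability
of the error `eps_t` between two perturbed copies is measured by the
sample Lyapunov exponent (the asymptotic slope of `log ||eps_t||`), which
is bounded almost surely by

    LB = a1 - a2^2/2 - b2^2 - 2 a2 b2,
    UB = a1 - a2^2/2 + b2^2/2 + a2 b2,

*provided* the error diffusion satisfies
`a2 ||eps|| <= ||dg(eps)|| <= (a2 + b2) ||eps||`.

A subtlety the package surfaces explicitly: if the two copies are driven
by the *same* Wiener path and the diffusion is purely additive, the noise
cancels in the subtraction, the error dynamics are deterministic
(`LE = a1`), and the hypothesis above cannot hold.  `simulate_pair`
implements this literal paired Euler–Maruyama integration, checks the
hypothesis along the run, and flags the violation.  The bound
*verification* therefore integrates the error equation under the
hypothesis' own instantiation, `dg(eps) = (a2 + kappa b2) eps` with mixing
`kappa` in [0, 1] (default 0.5) — precisely the diffusion magnitudes the
theorem admits.  For that family the exponent is `a1 - (a2 + kappa b2)^2/2`,
which collapses to `a1 - a2^2/2` in the additive case (noise makes the
exponent *more* negative than the noise-free `a1`, i.e. faster
self-correction) and lies inside [LB, UB] for every `kappa`.

Numerics: integration of the log-norm (under/overflow-proof over long
horizons); slope by ordinary least squares after discarding a 20% burn-in
(lower variance than endpoint ratios); the finite horizon and tolerance
are always reported with the estimate.  Default verification sizes:
dt = 1e-3, horizon 50, 50 paths for the additive case; horizon 20 and 8
paths per system for bound-coverage scans.

## Perturbation operators

* **FGSM**: `x + gamma * sign(grad_x loss)`; the input gradient comes from
  the same noise-driven backward pass.  L-inf distortion is exactly gamma
  wherever the gradient is nonzero.
* **Direct optimisation (DO)**: ascend the loss over the L2 sphere
  `||dx||_2 = gamma`, zero-initialised, 30 iterations at step 0.002
  (adaptive moments by default, plain ascent optionally), renormalising
  onto the sphere each iteration.  A gradient that vanishes throughout
  yields a random point on the sphere, flagged.
* **EventDrop (Random Drop)**: each event of an event table is deleted
  independently with probability rho; uniform per-event deletion realises
  the combined spatial+temporal random-drop marginal, and dimension-
  targeted variants (whole time windows / spatial bins) are optional
  modes since the mixing proportions of the combination are free.
* **Spike-state flips**: during a rollout every hidden spike flips with
  probability beta and the flipped value enters the dynamics (reset,
  membrane recurrence, downstream drive), not just the readout.  Whether
  the final spiking layer is flipped is switchable (default: yes).

## Coding analytics

Repeated stochastic rollouts of one input give spike counts of the final
spiking layer (the neural code) and per-trial prediction vectors.
Variability is the Fano factor per neuron — **unbiased sample variance
(n-1 denominator)** over mean count; neurons with zero mean are excluded
and reported, and exclusion happens *before* averaging into the mean FF.
Reliability is the mean pairwise cosine similarity of prediction vectors.
Correlating mean FF against similarity across inputs (20 trials per input
by default, each input one point) probes rate coding: in trained noisy
networks the correlation is negative — inputs whose codes fluctuate more
across trials receive less stable predictions.  The zero-noise network is
the degenerate control: identical trials, FF exactly 0, similarity
exactly 1.

## Spike-train fitting

Spike trains are compared through first-order post-synaptic-potential
(PSP) traces, `PSP_t = (1 - 1/tau_s) PSP_{t-1} + y_t / tau_s` with
`tau_s = 2`.  The loss averages the accumulated squared trace distance
over all prefixes; as written it is an O(T^2) double sum, evaluated here
in O(T) by weighting prefix `t` (1-based) with `(T - t + 1)/T` — equality
with the naive double loop is asserted to 1e-12.  The loss is a premetric
on rasters (nonnegative, symmetric, zero exactly on equality for
tau_s > 1; the triangle inequality is not claimed).  Its gradient with
respect to the predicted spikes is the time-reversed (adjoint) PSP filter
applied to the weighted trace differences; from there the NDL backward
pass assigns credit to the parameters.  No per-neuron normalisation is
applied inside the norm.

The teacher-student harness emulates sensory-response fitting: a noisy
single-layer teacher (8 neurons, 5 stimulus channels, sigma = 0.2, biased
near threshold so rates are moderate and stimulus-modulated) generates
trial-varying rasters for 60 training and 15 held-out stimuli of 30 steps;
a student of the same shape, independently initialised, is fitted with
plain SGD (lr 0.1, 200 epochs, one randomly drawn recorded trial per
stimulus per epoch so the student sees the data's variability).
Evaluation: Pearson correlation between smoothed (5-step boxcar,
trial-averaged) rate curves of student and teacher on held-out stimuli,
concatenated across stimuli, per neuron.  Neurons whose curves are
constant (silent or saturated) are reported as NaN and excluded from the
mean — with this teacher the very-low-rate neurons are the hard cases and
occasionally die in the student; the mean correlation over active neurons
is the headline metric (≈ 0.9 in the shipped configuration).  A
deterministic student trained through the matched ERF surrogate fits rates
but produces identical repeats: its between-trial Fano factor is exactly
zero, while the noisy student's is positive and closer to the teacher's.

## Synthetic data

Generators are pure functions of (parameters, seed).  Rates are per-step
firing probabilities, not Hz — the discrete simulation fixes no physical
step duration, and a probability avoids smuggling in a dt convention.

The two-class rate task (20 inputs, 10 steps, 400 samples) elevates a
class-specific block of inputs by `contrast = 0.3` over a baseline of 0.2
with i.i.d. Gaussian input noise of SD 0.3.  The contrast is deliberately
on the order of the input noise: with a large margin the task is linearly
separable regardless of internal noise and says nothing about noise-level
effects; at margin ≈ noise the task is still reliably learnable at
moderate internal noise (train accuracy 1.0 within 50 epochs) but
degrades when the membrane noise dwarfs the threshold (sigma = 3), giving
the sweep its rise-plateau-decline shape.  What passing these tests shows
is that the learning rule extracts a rate code under realistic
signal-to-noise conditions; it does not show anything about image-scale
benchmarks, convolutional architectures, or data augmentation, which are
outside this package's scope.

Event streams are a moving-bar pattern plus uniform background on a
16x16 sensor — enough structure for the drop operators to act on, with no
pretence of emulating a real event camera.

## Trainer

Plain SGD (optional momentum) for auditability; batch gradients are
averaged; `lr = 0` is bit-exact identity, same seed gives identical
curves.  Accuracy is evaluated from the time-averaged softmax over one
stochastic rollout per sample.  Adaptive optimisers and schedulers are
deliberately out of the core loop.

## Numerical choices and degenerate inputs

* Gaussian cdf via `scipy.special.ndtr`; logistic via `expit`; uniform by
  clipped linear form.
* Firing probabilities exactly 0/1 (saturation) make the conditioning
  estimator degenerate; the report flags it (`extra["degenerate"]`)
  rather than silently dividing.
* Enumeration is capped at 16 binary variables (65,536 configurations)
  to keep the oracle in seconds.
* All randomness flows through explicitly seeded `numpy` generators; no
  global RNG state anywhere.
* Problem sizes used by the shipped verification runs (2-3-2 network with
  T=2 for estimator checks at 2e5 samples; 5-seed, 50-epoch toy-task
  training; 3-seed activity fitting) were chosen so the full suite runs
  in a couple of minutes on one CPU while leaving Monte-Carlo standard
  errors small enough for 3-SE comparisons to be meaningful.

## Known limitations

* Affine (fully connected) drives only; convolutional transforms are an
  extension point.
* No recurrent synaptic connectivity beyond the membrane self-recurrence;
  no refractoriness beyond the hard reset; no temporally correlated
  noise.
* The NDL estimator is biased for non-multilinear losses (including the
  cross-entropy head); the bias is measurable with the shipped oracles
  and is reported, not hidden.
* The stability analysis verifies the scalar/diagonal instantiation of
  the bound hypothesis; general matrix couplings in the diffusion are not
  covered.
* The Lyapunov bound verification simulates the error equation under the
  bound's own diffusion hypothesis; the literal paired simulation with
  shared noise is provided and flags, rather than hides, the additive
  cancellation.
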