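# Methods

This note documents the models implemented in `emghybrid`, the
assumptions behind them, the defaults and why they were chosen, what the
synthetic generators do and do not emulate, and the numerical choices
that matter when reproducing results.

## Signal chain

EMG preprocessing follows the standard amplitude-envelope route for
myoelectric control. All filtering is **causal** (single-pass IIR), since
the system being modelled is an online controller; zero-phase filtering
would use future samples. "Second-order Butterworth bandpass" is
implemented as `scipy.signal.butter(2, [fc_low, fc_high], "bandpass")`,
i.e. second order per band edge, the conventional reading in the EMG
literature. The smoothing low-pass at `fc_smooth` = 1 Hz has a group
delay of roughly 1/(2π·1 Hz) ≈ 0.16 s near DC; envelope statistics are
therefore unreliable while the filter settles, and calibration excludes
the first three time constants (≈ 0.48 s) of each recording.

Calibration constants are per-channel scalars: the rest level
E<sup>st</sup> is the **mean** envelope of the rest recording (mean
rather than max, for noise robustness), and E<sup>max</sup> is the maximum envelope while the user
performs the desired motions voluntarily; when several movements are
calibrated, the per-channel maximum is taken across all of them
(`concat_envelopes`). Normalized envelopes below rest are clipped to 0
because the downstream ratio and mean assume non-negativity. The
coordination-vector division is guarded at ε = 10⁻⁶: below that summed
envelope the ratio is meaningless, a uniform vector is substituted and
the sample flagged; the activation gate excludes such samples anyway.
The gate itself (threshold 0.2 on F(t), 50 ms debounce) is a design
choice exposed in `SignalConfig` — only "a predefined threshold" is
prescribed by the method.

## Recurrent probabilistic classifier

The classifier embeds, per class, a K-state hidden Markov model with
M-component Gaussian-mixture emissions, log-linearized so that every
unit (c, k′, k, m) computes exp(wᵀX) on the quadratic expansion
X = [1, x, {x<sub>i</sub>x<sub>j</sub>}]. Any product of transition
probability, mixture weight and Gaussian density is exactly
representable, which is what the oracle-equivalence test exploits: a
known GMM-HMM is log-linearized and the network's posterior is compared
with a direct forward-algorithm computation (and with `hmmlearn`
per-class likelihoods) to 10⁻⁶.

Numerics: the recursion is computed with a per-time-step subtraction of
the maximum pre-activation before exponentiation. Because the
normalization makes the posterior invariant to a common positive scaling
of all unit activations within a time step, this changes nothing
mathematically while keeping every exponential ≤ 1 (exp of quadratics at
H = 15 overflows quickly otherwise); the same invariance makes the
max-subtraction transparent to the analytic gradient. The state prior at
t = 0 is uniform (any positive constant is equivalent after
normalization). One reference unit's weights are pinned at zero for
identifiability. Argmax ties break toward the lowest class index.

Training is full-batch steepest descent with Armijo backtracking
(initial step doubled after each accepted step, halved on rejection),
stopping on relative loss change < 10⁻⁸ or at `max_iter` (default 2000).
A trial step that collapses a training posterior to zero counts as a
rejected step. Weights initialize from N(0, 0.01²) under the given seed;
identical data and seed reproduce identical weights bit for bit. The
optimizer is deliberately simple and pluggable — nothing in the
architecture requires this particular schedule. Training windows are
sliding `seq_len = 50` sub-sequences of the 500 recorded samples per
movement; the stride is configurable (default 1). The decision rule in
`estimate_motion` classifies the **trailing** 50 samples at gate onset —
an online-causal choice — and emits one decision per activation episode.

## Minimum-jerk instruction and FES model

Instruction mode moves the wrist along
P(τ) = P₀ + (P_T − P₀)(6τ⁵ − 15τ⁴ + 10τ³) over T_instruct = 2 s. The
simulated "realized" motion during instruction equals the commanded
trajectory: the robot dominates the FES torque, so robot–FES conflict
dynamics are not modelled. Targets beyond the ±45-degree servo range
raise validation errors rather than being clipped silently. Sign
conventions (not prescribed anywhere): flexion = +X, radial
deviation = +Y.

The FES model is the steady-state sigmoid θ(I) = d/(1 + e^{b(c−I)})
with its algebraic inverse for open-loop current commands; the dynamic
muscle response to stimulation is out of scope. Commanded angles are
clipped into [εd, (1−ε)d] with ε = 10⁻³ (logged) to keep the logarithm
finite. Calibration fits (b, c, d) by `scipy.optimize.curve_fit` with
d₀ = 1.05·max angle, c₀ at half-maximum, b₀ from the local slope
(logistic slope at c is bd/4), bounds b, d > 0. One parameter set per
muscle; the direction→muscle map is configuration data, since electrode
placement cannot be computed. The active muscle per sample follows the
dominant axis of the displacement from the movement start. Currents are
assumed in mA and θ is the magnitude along the commanded axis.

## Pointing indices

Trajectories are decomposed onto the unit start→target vector
(parallel) and its +90° rotation (perpendicular, right-hand sign). The
endpoint deviation *s* is implemented exactly as defined — the **mean
distance** of trial endpoints from their mean endpoint, not a
conventional standard deviation. The orbit correlation averages Pearson
r over unordered trial pairs (equal to the ordered-pair mean by
symmetry); trials of unequal length are linearly resampled onto the
longest trial's grid first, and zero-variance series exclude a pair with
a warning. The correlated quantity is the parallel displacement
component.

The jerk cost uses a 7-point central third-derivative stencil with
**odd** (antisymmetric) reflection padding and trapezoidal quadrature.
Odd reflection preserves odd derivatives at the boundary; plain (even)
reflection would force the edge jerk estimate to zero, where a
minimum-jerk profile's jerk is in fact maximal, biasing the integral by
≈ 1.5%. With odd reflection the discretization reproduces the closed
form 360 A²/T⁵ to < 10⁻⁵ relative at 1 kHz, and the convergence test
verifies at least first-order behaviour in the step size. An optional
pre-smoothing low-pass (`presmooth_hz`) exists for noisy measured data
and is off for analytic tests.

Reaching time is operationalized (no definition is prescribed): onset
when the parallel speed first exceeds 5% of its peak; arrival at the
final entry into a 2-degree ball around the movement endpoint, provided
the position stays inside through the end of the recording and for at
least 100 ms. The smoothness integrals in `evaluate_trial` run over this
onset→arrival window when it is detectable, since the indices are
defined over the movement, not the recording. All thresholds are
keyword-configurable.

## Synthetic generators

`generate_emg` emulates a four-channel wrist montage (FCU, FCR, ECU,
ECR). Each channel is Gaussian noise bandpassed to 20–450 Hz — the
standard interference-pattern surrogate — scaled so its mean rectified
value is 1, then amplitude-modulated by
rest + peak·pattern<sub>l</sub>·shape(t), where shape(t) is a
raised-cosine ramp/plateau/ramp profile and the per-class coordination
patterns sum to one (flexion excites both flexors, radial deviation FCR
+ ECR, and so on). Envelope variability is slow multiplicative Gaussian
noise (low-passed at 5 Hz, default s.d. 0.1 of the local envelope);
per-subject pattern jitter (s.d. 0.08, renormalized) models individual
montage differences. What this does **not** emulate: motor-unit
dynamics, signal nonstationarity within a contraction, electrode lift or
crosstalk, or mains hum. Consequently, a passing classification
benchmark shows the pipeline and network are correct and well
conditioned — not that real paralytic EMG would be classified at the
same rate.

`generate_trial` composes a minimum-jerk backbone toward
target + bias + isotropic Gaussian endpoint noise, a half-sine lateral
bow (random sign), and sinusoidal tremor faded in and out so endpoints
stay exact. Motor learning is multiplicative per-session decay of each
error parameter toward a floor (p_s = floor + (p₀ − floor)·decay^s) —
a phenomenological curve that yields monotone error decay, not a
cognitive model. The two experiment arms differ only in this profile:
the hybrid arm decays at 0.85/session toward an 8% floor with movement
duration converging to T_instruct (so post-training reaching times match
the instructed tempo); the visual-feedback arm decays faster (0.75) but
plateaus at a 30% floor and keeps its own tempo. These numbers were
chosen once to reproduce the qualitative phenomenology (early fast
improvement then stagnation for visual feedback; steady convergence to
the instructed movement for hybrid) and are overridable per run.

Improvement ratios are normalized to pre-training and sign-aware:
100·(pre − post)/pre for indices where lower is better and
100·(post − pre)/pre for r_orbit and v̄_norm, so positive always means
improvement. Intra-group stage comparisons use Wilcoxon signed-rank
with Bonferroni adjustment over the three stage pairs (the underlying
paired test is not prescribed; a nonparametric choice matches the
Mann–Whitney U used for the inter-group improvement comparison, which
follows scipy's default exact-when-small-and-untied policy).

## Problem sizes and determinism

The classifier benchmark trains five subjects on stride-5 windows of
the 500 recorded samples per movement (91 windows per class, 364
sequences of length 50) with `max_iter` = 300, and evaluates 100 gated
held-out windows per subject; one subject takes ~20 s on one CPU. The
experiment simulations in the tests use 2–3 subjects per group and 2–20
sessions. Every stochastic component takes an explicit seed or
`numpy.random.Generator`; subject seeds derive from the root seed via
`SeedSequence`, and repeated runs are bytewise identical, which the
test suite asserts on the rendered CSV output.

## Known limitations

- Open-loop FES with a steady-state muscle model; no antagonist
  co-stimulation, no musculoskeletal dynamics.
- The classifier is trained per subject on a single recording per
  movement, as in the emulated protocol; no cross-session adaptation.
- The learning model is a parametric decay; retention is simulated as
  the final skill (no forgetting model), so retention-stage contrasts
  exercise the statistics plumbing rather than a memory hypothesis.
- Human-subject outcome values are not reproduction targets; the
  simulator's claims are about the computational pipeline.
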