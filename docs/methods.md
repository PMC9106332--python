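# Methods

## Task model

The dynamic blind source separation task generates stimuli
x⃗(t) = A(t) s⃗(t) + σ_n ξ⃗(t) with n_s = 2 sources. Defaults: chord
sources (two unit sines per source at 100/125 Hz and 150/210 Hz,
f_s = 8 kHz, no rescaling, so each source has variance ≈ 1 and range
[−2, 2]); context duration n_t = 1000 samples; noise amplitude
σ_n = 0.001 with ξ i.i.d. standard Gaussian per sample and channel
("white noise" is read as Gaussian); mixing entries uniform on [0, 1]
with rows normalised to sum one and rejection sampling until
|det A| ≥ 0.2 (absolute value, since only invertibility matters; the
rejection cap is 10⁴ attempts). For n_s = 2 the accepted contexts live on
the two-dimensional manifold (a, b) with rows (a, 1−a), (b, 1−b) and
|a − b| ≥ 0.2; a uniform candidate is rejected with probability 0.36.
Phases are explicit parameters of the source generator so training can
randomise them per trial.

The measured noise-free stimulus standard deviation under these defaults
is ≈ 0.8 (unit-variance sources through row-normalised positive
mixtures); the package reports the measured value wherever a
signal-to-noise ratio is quoted, SNR(dB) = 10 log₁₀(σ_s²/σ_n²).

The context grid used for context decoding is an endpoint-inclusive
linspace with 20 points per dimension; applying the determinant filter
leaves exactly 272 contexts.

## Network models

All dynamics are integrated with forward Euler at dt = 1 sample. The
modulator is an LSTM (forget gates, no peepholes; gate order input,
forget, cell, output) with N_h = 100 hidden units by default and a linear
readout of n_s² (simple model) or N_FB (population models) feedback
signals. Its hidden and cell states are zero-initialised at every trial
start during training and once per stream at test time, after which they
are carried continuously across context switches.

**Causality.** A simultaneous definition of modulation and output is
circular (the modulation at t would depend on the output at t, which
depends on the modulation at t). The modulator therefore receives the
one-step-delayed output y⃗(t−1) — the standard closed-loop convention —
and the modulation computed at t is applied to the stimulus at t.

**Simple model.** Without a filter (tau=None) the modulation matrix M is
the reshaped feedback readout at every step; with a filter it follows
τ dM/dt = −M + drive. M is initialised to ones (neutral modulation) at
state reset.

**Population model.** z⃗ = m⃗ ⊙ (W_x x⃗) is *not* rectified — the unit
activities may be negative. The von Mises kernel is by default
row-normalised to sum one so the total modulatory drive per unit is
independent of N_FB and σ_m² (the raw kernel, whose peak is exp(1/σ_m²),
is available via `normalize=False`; the modulator readout scale can
absorb either convention). σ_m² = ∞ gives identical modulation for all
units. m⃗ is initialised to zero.

**Dalean model.** Inter-population weights W_HL, W_IL, W_HI enter the
forward pass as absolute values; W_Lx and W_ro are unconstrained (only
the inter-population projections are sign-constrained). Gains
p = 1/(1 + exp(m)) are computed with the numerically stable sigmoid.
External manipulation adds a constant (±3 by default) to the drive of the
modulation-unit dynamics only; it never touches the weights.

Initial parameter distributions: W₀ ~ N(1, 0.001); W_x, W_Lx, W_ro ~
N(0, 0.5); W_HL ~ N(1, 0.5)·20/N_H; W_IL ~ N(1, 0.5)/N_I; W_HI ~
N(1, 1)·20/N_H; LSTM parameters (including biases) uniform on
[−1/N_h, 1/N_h]; modulator readout uniform on [−1/N_FB, 1/N_FB]. The
second Gaussian argument is read as a **variance**; a
`second_arg_is_std` flag switches to the standard-deviation reading
(the two differ only slightly for the near-one W₀).

`effective_weights` reports the end-to-end linear input→output map at the
current modulation state; for the rectified Dalean model it is the
Jacobian at the current operating point (active-unit masks of the last
step), verified against finite differences.

## Training

Each batch simulates 32 trials of n_t closed-loop steps; every trial
draws a fresh context and, independently per source, a random chunk
offset into a 16,000-sample source bank (phase randomisation). The loss
is the smooth L1 distance h(d) = ½d² for |d| < 1, |d| − ½ otherwise,
reduced by **mean** over elements and time (the sum convention differs
only by a scale that Adam's normalisation absorbs), plus
λ_out · Σ_j |l_j| averaged over time and trials with λ_out = 10⁻⁵.
Gradients flow through all n_t steps (full-trial BPTT, no truncation),
are clipped elementwise to [−1, 1], and applied with Adam (η = 10⁻³,
β₁ = 0.9, β₂ = 0.999, ε = 10⁻⁸ — conventional defaults). Modulator
parameters are always trained; the Dalean model additionally trains
W_HL, W_HI, W_IL, W_Lx and W_ro. Training is bit-for-bit reproducible
given (seed, config) on one platform; checkpoints are taken every 500
batches plus at the end.

Because no automatic-differentiation framework is a dependency, the
package implements a small reverse-mode engine over numpy
(`modinvar.autodiff`) with a fused LSTM-cell primitive; every primitive
and the full closed-loop unroll are validated against central finite
differences in the test suite (relative error < 10⁻⁵).

## Analyses

**Signal clarity** of channel j: c_j = ||r_1j| − |r_2j||, normalised by
|r_1j| + |r_2j| by default (both variants are computed; the normalised
one makes the raw-stimulus reference ≈ 0.5 analytically, since for a
mixture row (a, 1−a) of uncorrelated unit-variance sources it equals
|2a − 1|). Clarity is measured over the whole duration of each context;
onset transients are excluded only in context decoding (second 500
samples), where the protocol prescribes it. For n_s > 2 a
best-vs-second-best generalisation is exposed, without any claim of
equivalence to the two-source definition.

**Decoding.** Ordinary least squares with intercept, no regularisation;
sklearn's least-squares solver returns the least-norm solution for
rank-deficient designs. Source decoding fits one decoder on 10 contexts
(10,000 samples at defaults) and reports R² per held-out context.
Context decoding regresses the two context variables (or, in `inverse`
mode, the four entries of A⁻¹; in `quadratic` mode, on a full quadratic
feature expansion) on per-context mean activities with fivefold
cross-validation, shuffled folds seeded from the caller's generator.

**Subspace geometry.** Display coordinates are the projections on the two
QR-orthonormalised readout axes and on the first principal component of
the reference-condition activity *after removing its readout-axis
components* (so the three axes are non-redundant); the reference
condition is the first intact-feedback stage of the protocol under
analysis, and traces are centred on the reference mean. Planes are fitted
by total least squares (normal = smallest singular direction about the
centroid), and angles are folded, arccos|cos θ| ∈ [0°, 90°]. Per-neuron
readout magnitude is the Euclidean norm across the two output channels.

## Protocols

Evaluation uses fresh random contexts (20 by default) with the same
source family as training. The freeze protocol holds the modulation
variable (M, m⃗ or p⃗) bitwise constant for the first half of the
post-switch context by default while the modulator's hidden dynamics
continue unseen, then re-enables feedback; its default sources are pure
sines (100 and 150 Hz, taken from the chord set), following the
visualisation convention for this experiment. The modulator only tracks
contexts for the source family it was trained on, so the protocol
accepts the model's training waveform where that differs — the shipped
freeze check runs the chord-trained model with chord sources. The linear-regression control fits
1024 consecutive samples per context and tests on held-out 1024-sample
chunks over all context combinations; the multilayer control has
rectified hidden layers of 32, 16 and 8 units and is trained on batches
of 32 contexts with mean-squared error (sequence variant: flattened
windows of seq_len samples in and out — the simplest architecture
mapping an input sequence to an equal-length output).

## Problem sizes used in the shipped checks

The test suite trains two scaled-down models, one seed each: a simple
model (N_h = 64, n_t = 300, 1500 batches of 32 trials) and a population
model (same sizes but 3000 batches, keeping N_z = 100 and τ = 30 to
preserve the default relative timescale τ/n_t = 0.1; the closed-loop
manipulation protocols need the better-converged modulator). These
sizes were chosen as the smallest at which the qualitative signatures of
the full-scale setting (≈ 10⁴ batches, n_t = 1000, N_h = 100, 5 seeds)
are stable: falling loss, output clarity well above stimulus clarity,
within-context error decay, a cross-context decoding advantage for the
modulated population, and the freeze-then-recover deviation profile.
The acceptance script itself only runs the (fast) task-statistics and
analysis-bound checks.

## What the generator does and does not emulate

The synthetic task reproduces the stated stimulus statistics exactly —
deterministic periodic sources, piecewise-constant random row-normalised
mixtures, additive Gaussian noise. It does not contain natural-signal
structure (speech-like spectra, amplitude envelopes, nonstationary
sources), nonlinear or convolutive mixing, or sensor dynamics; passing
tests therefore certify the mechanism under the model's own stimulus
assumptions, not performance on natural audio.

A known behaviour of the freeze protocol at this scale: when the freeze
lasts much longer than the modulation time constant, the modulator —
whose feedback has no effect while frozen — integrates its error signal
up, and the re-enabled stage transiently overshoots before recovering
over a few context durations (modulator windup). Near-identical context
pairs, conversely, show little frozen-stage elevation at all, since the
clamped modulation still roughly inverts the new context. The shipped
freeze check therefore evaluates the signature on the median over eight
repeated context pairs, as in the original repeated-experiment design.

## Known limitations

* Training is CPU-bound pure numpy; full-scale runs (10⁴ batches at
  n_t = 1000) take hours, as expected for the method.
* The clarity measure is only defined up to source permutation and is
  undefined for silent channels (flagged and excluded, never imputed).
* The modulator's internal dynamics are treated as a black box; only its
  feedback output is analysed.
* For n_s > 2 the clarity generalisation and the context-variable
  parametrisation (first n_s − 1 entries per row) are natural but not
  canonical choices.
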