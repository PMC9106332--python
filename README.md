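# modinvar

Feedback-modulated feedforward networks that keep an **invariant source
representation** across changing stimulus contexts — a computational model
of how top-down gain modulation can solve flexible sensory processing, in
the concrete setting of **dynamic blind source separation**.

## The problem

Two periodic sources s⃗(t) (by default "chords", each a sum of two unit
sines: 100 + 125 Hz and 150 + 210 Hz at f_s = 8 kHz) are observed only
through a noisy, time-varying linear mixture

    x⃗(t) = A(t) s⃗(t) + σ_n ξ⃗(t),

where the mixing matrix A(t) — the *context*, think of moving speakers at
a cocktail party — is redrawn every n_t = 1000 samples from random
row-normalised matrices with |det A| ≥ 0.2, and σ_n = 0.001. A fixed
feedforward map cannot invert two different contexts, so the network must
*infer* the current context online and adapt.

## The model

A feedforward network with output y⃗(t) is multiplicatively modulated by a
recurrent *modulator* (an LSTM with forget gates, no peepholes, plus a
linear readout) that observes x⃗(t) and the one-step-delayed output
y⃗(t−1). Three architectures of increasing biological realism:

* **Simple**: y⃗ = (M ⊙ W₀) x⃗ — one multiplicative factor per weight,
  optionally low-pass filtered, τ dM/dt = −M + LSTM(x⃗, y⃗).
* **Population**: a ring of N_z = 100 units, z⃗ = m⃗ ⊙ (W_x x⃗),
  y⃗ = W_ro z⃗, where N_FB = 4 feedback signals are spread over the ring
  by a von Mises kernel K_ij = exp(cos(z_i − l_j)/σ_m²), τ dm⃗/dt = −m⃗ + K l⃗.
* **Dalean**: a two-stage hierarchy of positive rates with feedforward
  inhibition, sign-constrained weights, and sigmoidal per-neuron gains
  p_i = 1/(1 + exp(m_i)) ∈ (0, 1), so stronger feedback *decreases* gain.

The closed loop is trained end-to-end by backpropagation through time
(smooth-L1 reconstruction loss, L1 penalty λ_out = 10⁻⁵ on the feedback,
elementwise gradient clipping to [−1, 1], Adam at η = 10⁻³), with source
phases randomised per trial. Since no autodiff framework is among the
dependencies, the package ships its own compact reverse-mode engine
(`modinvar.autodiff`), validated against finite differences.

Analyses quantify the learned solution: **signal clarity** (normalised
absolute-correlation contrast of each output with the two sources; ≈ 0.5
for the raw stimuli, → 1 for a clean separation), cross-context **linear
decoding** of sources and contexts (invariant-subspace test), and the
geometry of population activity (plane fits in the space of the two
readout axes + residual PC1, folded angles in [0°, 90°]).

## Worked example

```python
import numpy as np
from modinvar import networks, task, training, experiments

rng = np.random.default_rng(11)
bank = task.generate_sources(T=16_000)                    # default chords
model = networks.SimpleModulatedNet(n_hidden=64, rng=rng)
cfg = training.TrainingConfig(n_batches=1500, n_t=300, seed=11)
model, history = training.train(model, cfg, bank=bank, rng=rng)
print(f"loss {np.mean(history.loss[:100]):.3f} -> {np.mean(history.loss[-100:]):.3f}")

res = experiments.evaluate(model, n_contexts=20, n_t=300,
                           rng=np.random.default_rng(123))
print(f"clarity(y) {res.metrics['clarity_y'].mean():.3f}  "
      f"clarity(x) {res.metrics['clarity_x'].mean():.3f}")
```

prints (one CPU, a few minutes):

```
loss 0.302 -> 0.100
clarity(y) 0.647  clarity(x) 0.461
```

The training loss falls by 3×, and the trained network's outputs separate
the sources far better (clarity 0.65) than the raw mixed stimuli (0.46,
the ≈ 0.5 chance reference): after each context switch the output error
spikes and then decays as the modulator re-infers the mixing matrix.

A command-line interface wraps the same pipeline:

```bash
modinvar train --config cfg.yaml --seed 11 --out results/run1
modinvar reproduce --seed 11 --out results/repro   # scaled-down end-to-end run
```

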