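"""Evaluation and manipulation protocols, plus unmodulated controls.

All protocols run the trained closed-loop model on fresh random contexts
(drawn as in training) with the modulator state carried continuously
across context switches, record the full traces, and report per-context
metrics.  Manipulations include freezing the feedback at its pre-switch
value after a context change and driving the Dalean modulation units with
a constant external input.  The unmodulated controls — a per-context
linear regression and a small rectified multilayer network — demonstrate
why a fixed feedforward map cannot solve the task.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.linear_model import LinearRegression
from sklearn.metrics import r2_score

from . import autodiff as ad
from . import task
from .analysis import clarity_by_context, signal_clarity
from .exceptions import InvalidParameterError, UnsupportedOperationError
from .networks import DaleanNet, PopulationNet, SimpleModulatedNet
from .training import Adam, TrainingConfig, train

__all__ = [
    "ProtocolResult",
    "simulate_stream",
    "evaluate",
    "sweep_noise",
    "sweep_timescale",
    "ablate_modulator_inputs",
    "freeze_feedback",
    "manipulate_modulation_units",
    "baseline_linear",
    "baseline_mlp",
    "MLP",
]

_RECORD_KEYS = ("l", "M", "m", "p", "z", "zL", "zI", "zH")


@dataclass
class ProtocolResult:
    """Traces, per-context metrics and metadata from one protocol run."""

    traces: dict
    metrics: pd.DataFrame
    meta: dict = field(default_factory=dict)


def simulate_stream(model, x, frozen=None, ext_drive: float = 0.0, reset: bool = True):
    """Run the closed loop over a (T, n_s) stimulus array without gradients.

    ``frozen`` may be a boolean array of length T clamping the modulation
    at the flagged samples.  Returns a dict of (T, ...) traces including
    the output ``y`` and whichever modulation variables the model exposes.
    """
    x = np.asarray(x, dtype=float)
    T = x.shape[0]
    if frozen is None:
        frozen = np.zeros(T, dtype=bool)
    recorded: dict[str, list] = {}
    ys = np.empty_like(x)
    with ad.no_grad():
        if reset:
            model.reset_state(1)
        for t in range(T):
            y, info = model.step(x[t : t + 1], frozen=bool(frozen[t]),
                                 ext_drive=ext_drive)
            ys[t] = y.data[0]
            for key in _RECORD_KEYS:
                if key in info:
                    recorded.setdefault(key, []).append(
                        np.array(info[key].data[0], copy=True)
                    )
    traces = {k: np.stack(v) for k, v in recorded.items()}
    traces["y"] = ys
    return traces


def _context_metrics(traces, stream: task.StimulusStream) -> pd.DataFrame:
    """Per-context clarity of output and stimuli plus deviation statistics."""
    y, x, s, ctx = traces["y"], stream.x, stream.s, stream.context_index
    clar_y = clarity_by_context(y, s, ctx)
    clar_x = clarity_by_context(x, s, ctx, stage="x")
    dev = np.abs(y - s).mean(axis=1)
    rows = []
    for k in np.unique(ctx):
        sel = np.flatnonzero(ctx == k)
        n = len(sel)
        first_decile = dev[sel[: max(1, n // 10)]].mean()
        last_decile = dev[sel[-max(1, n // 10) :]].mean()
        rows.append(
            {
                "context": int(k),
                "clarity_y": clar_y.values.loc[int(k)].mean(),
                "clarity_x": clar_x.values.loc[int(k)].mean(),
                "deviation": dev[sel].mean(),
                "deviation_first_decile": first_decile,
                "deviation_last_decile": last_decile,
            }
        )
    return pd.DataFrame(rows)


def evaluate(
    model,
    n_contexts: int = 20,
    n_t: int = task.DEFAULT_N_T,
    sigma_n: float = task.DEFAULT_SIGMA_N,
    rng: np.random.Generator | None = None,
    bank: task.SourceBank | None = None,
    det_threshold: float = task.DEFAULT_DET_THRESHOLD,
) -> ProtocolResult:
    """Test the model on an independent random set of contexts.

    Contexts are drawn as during training and switch every ``n_t``
    samples; the modulator state is zero-initialised once and then carried
    across the switches.
    """
    if rng is None:
        rng = np.random.default_rng()
    T = n_contexts * n_t
    if bank is None:
        bank = task.generate_sources(T=T)
    schedule = task.build_schedule(rng, n_contexts, n_t, bank.n_s, det_threshold)
    stream = task.mix_stream(bank, schedule, sigma_n, rng)
    traces = simulate_stream(model, stream.x)
    traces.update({"x": stream.x, "s": stream.s, "context_index": stream.context_index})
    metrics = _context_metrics(traces, stream)
    meta = {"n_contexts": n_contexts, "n_t": n_t, "sigma_n": sigma_n,
            "contexts": [c.A for c in schedule.contexts]}
    return ProtocolResult(traces=traces, metrics=metrics, meta=meta)


def sweep_noise(model, sigma_levels, n_contexts: int = 20,
                n_t: int = task.DEFAULT_N_T,
                rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Signal clarity for different additive-noise amplitudes."""
    if rng is None:
        rng = np.random.default_rng()
    rows = []
    for sigma in sigma_levels:
        res = evaluate(model, n_contexts, n_t, sigma, rng)
        # measured noise-free stimulus scale (noise variance subtracted)
        sigma_s = float(np.sqrt(max(np.var(res.traces["x"]) - sigma**2, 0.0)))
        rows.append(
            {
                "sigma_n": sigma,
                "sigma_s": sigma_s,
                "snr_db": task.snr_db(sigma_s, sigma) if sigma > 0 else np.inf,
                "clarity_y_mean": res.metrics["clarity_y"].mean(),
                "clarity_y_std": res.metrics["clarity_y"].std(),
                "clarity_x_mean": res.metrics["clarity_x"].mean(),
            }
        )
    return pd.DataFrame(rows)


def sweep_timescale(models: dict, n_contexts: int = 20,
                    n_t: int = task.DEFAULT_N_T,
                    sigma_n: float = task.DEFAULT_SIGMA_N,
                    rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Evaluate trained models across modulation timescales.

    ``models`` maps the relative timescale tau/n_t to a trained model.
    Reports clarity and the within-context fluctuation of the modulation
    variable in the second half of each context (slow modulation damps it).
    """
    if rng is None:
        rng = np.random.default_rng()
    rows = []
    for tau_rel, model in models.items():
        res = evaluate(model, n_contexts, n_t, sigma_n, rng)
        mod_key = "M" if "M" in res.traces else "m"
        mod = res.traces[mod_key].reshape(res.traces[mod_key].shape[0], -1)
        ctx = res.traces["context_index"]
        var_second_half = np.mean(
            [
                mod[np.flatnonzero(ctx == k)[n_t // 2 :]].var(axis=0).mean()
                for k in np.unique(ctx)
            ]
        )
        rows.append(
            {
                "tau_relative": tau_rel,
                "tau": None if getattr(model, "tau", None) is None else model.tau,
                "clarity_y_mean": res.metrics["clarity_y"].mean(),
                "clarity_y_std": res.metrics["clarity_y"].std(),
                "modulation_var_second_half": var_second_half,
            }
        )
    return pd.DataFrame(rows)


def ablate_modulator_inputs(
    variant: str,
    train_config: TrainingConfig,
    model_kwargs: dict | None = None,
    rng: np.random.Generator | None = None,
    n_eval_contexts: int = 20,
):
    """Train and evaluate a model whose modulator only sees the stated
    inputs (``x_and_y``, ``x_only`` or ``y_only``)."""
    if rng is None:
        rng = np.random.default_rng(train_config.seed)
    kwargs = dict(model_kwargs or {})
    kwargs["input_mode"] = variant
    model = SimpleModulatedNet(rng=rng, **kwargs)
    model, history = train(model, train_config, rng=rng)
    result = evaluate(model, n_eval_contexts, train_config.n_t,
                      train_config.sigma_n, rng)
    return model, history, result


def freeze_feedback(
    model,
    context_pair,
    freeze_duration: int | None = None,
    n_t: int = task.DEFAULT_N_T,
    waveform: str = "sine",
    freqs=(100.0, 150.0),
    sigma_n: float = task.DEFAULT_SIGMA_N,
    rng: np.random.Generator | None = None,
) -> ProtocolResult:
    """Three-stage freezing protocol around a context switch.

    Stage 1: context 1 with intact feedback (n_t samples).  Stage 2:
    context 2 with the modulation clamped at its pre-switch value for
    ``freeze_duration`` samples (default n_t // 2) while the modulator's
    hidden dynamics continue unseen.  Stage 3: context 2 with feedback
    re-enabled for the remaining samples.  Pure sine sources are the
    default (the visualisation convention for this protocol); pass the
    model's training waveform and frequencies when they differ, since the
    modulator only tracks contexts for the source family it learned.
    """
    if freeze_duration is None:
        freeze_duration = n_t // 2
    if freeze_duration > n_t:
        raise InvalidParameterError("freeze_duration must be <= n_t")
    if rng is None:
        rng = np.random.default_rng()
    ctx1, ctx2 = context_pair
    if waveform == "sine":
        freqs = [(f,) if np.ndim(f) == 0 else tuple(f) for f in freqs]
    bank = task.generate_sources(waveform, freqs, T=2 * n_t)
    schedule = task.ContextSchedule(contexts=[ctx1, ctx2], n_t=n_t)
    stream = task.mix_stream(bank, schedule, sigma_n, rng)
    frozen = np.zeros(2 * n_t, dtype=bool)
    frozen[n_t : n_t + freeze_duration] = True
    traces = simulate_stream(model, stream.x, frozen=frozen)
    traces.update({"x": stream.x, "s": stream.s,
                   "context_index": stream.context_index, "frozen": frozen})
    stage = np.zeros(2 * n_t, dtype=int)
    stage[n_t : n_t + freeze_duration] = 1
    stage[n_t + freeze_duration :] = 2
    traces["stage"] = stage
    dev = np.abs(traces["y"] - stream.s).mean(axis=1)
    rows = [
        {"stage": k, "label": lab, "start": int(np.flatnonzero(stage == k)[0]),
         "length": int((stage == k).sum()), "deviation": float(dev[stage == k].mean())}
        for k, lab in ((0, "context1_intact"), (1, "context2_frozen"),
                       (2, "context2_intact"))
        if (stage == k).any()
    ]
    meta = {"freeze_duration": freeze_duration, "n_t": n_t,
            "context_pair": (ctx1.A, ctx2.A)}
    return ProtocolResult(traces=traces, metrics=pd.DataFrame(rows), meta=meta)


def manipulate_modulation_units(
    model,
    delta: float = 3.0,
    n_contexts: int = 2,
    n_t: int = task.DEFAULT_N_T,
    sigma_n: float = task.DEFAULT_SIGMA_N,
    rng: np.random.Generator | None = None,
) -> ProtocolResult:
    """Drive the Dalean modulation units with a constant input delta
    (+3 activates them, lowering gains; -3 inactivates them)."""
    if not isinstance(model, DaleanNet):
        raise UnsupportedOperationError("unit manipulation requires the Dalean model")
    if rng is None:
        rng = np.random.default_rng()
    T = n_contexts * n_t
    bank = task.generate_sources(T=T)
    schedule = task.build_schedule(rng, n_contexts, n_t, bank.n_s)
    stream = task.mix_stream(bank, schedule, sigma_n, rng)
    traces = simulate_stream(model, stream.x, ext_drive=delta)
    traces.update({"x": stream.x, "s": stream.s, "context_index": stream.context_index})
    metrics = _context_metrics(traces, stream)
    metrics["delta"] = delta
    metrics["mean_gain"] = float(traces["p"].mean())
    return ProtocolResult(traces=traces, metrics=metrics, meta={"delta": delta})


# ---------------------------------------------------------------------------
# unmodulated controls


def baseline_linear(
    n_contexts: int = 20,
    n_train: int = 1024,
    n_test: int = 1024,
    sigma_n: float = 0.0,
    rng: np.random.Generator | None = None,
    contexts: list | None = None,
) -> pd.DataFrame:
    """Fixed linear readout control: ordinary least squares of s on x.

    A decoder is fitted on ``n_train`` consecutive samples of one context
    and tested on held-out samples of every context, over all train/test
    combinations.  Returns the R^2 matrix as a DataFrame (rows: training
    context, columns: test context).
    """
    if rng is None:
        rng = np.random.default_rng()
    if contexts is None:
        contexts = [task.sample_mixing_matrix(rng) for _ in range(n_contexts)]
    n_contexts = len(contexts)
    bank = task.generate_sources(T=n_train + n_test)
    s_train, s_test = bank.samples[:n_train], bank.samples[n_train:]

    def noisy(x):
        return x + sigma_n * rng.standard_normal(x.shape) if sigma_n else x

    x_train = [noisy(s_train @ c.A.T) for c in contexts]
    x_test = [noisy(s_test @ c.A.T) for c in contexts]
    R2 = np.empty((n_contexts, n_contexts))
    for i in range(n_contexts):
        w = LinearRegression().fit(x_train[i], s_train)
        for j in range(n_contexts):
            R2[i, j] = r2_score(s_test, w.predict(x_test[j]))
    return pd.DataFrame(R2,
                        index=pd.Index(range(n_contexts), name="train_context"),
                        columns=pd.Index(range(n_contexts), name="test_context"))


class MLP:
    """Rectified multilayer perceptron control (hidden layers 32/16/8)."""

    def __init__(self, n_in, n_out, hidden=(32, 16, 8), rng=None):
        rng = rng or np.random.default_rng()
        sizes = [n_in, *hidden, n_out]
        self.weights = []
        self.biases = []
        for a, b in zip(sizes[:-1], sizes[1:]):
            bound = 1.0 / np.sqrt(a)
            self.weights.append(ad.Tensor(rng.uniform(-bound, bound, (b, a)),
                                          requires_grad=True))
            self.biases.append(ad.Tensor(rng.uniform(-bound, bound, b),
                                         requires_grad=True))

    def parameters(self) -> dict:
        out = {}
        for k, (w, b) in enumerate(zip(self.weights, self.biases)):
            out[f"W{k}"] = w
            out[f"b{k}"] = b
        return out

    def forward(self, x):
        h = x if isinstance(x, ad.Tensor) else ad.Tensor(x)
        last = len(self.weights) - 1
        for k, (w, b) in enumerate(zip(self.weights, self.biases)):
            h = ad.linear(h, w, b)
            if k != last:
                h = ad.relu(h)
        return h

    def predict(self, x):
        with ad.no_grad():
            return self.forward(x).data


def baseline_mlp(
    seq_len: int = 1,
    n_batches: int = 5000,
    contexts_per_batch: int = 32,
    samples_per_context: int = 100,
    hidden=(32, 16, 8),
    learning_rate: float = 1e-3,
    sigma_n: float = task.DEFAULT_SIGMA_N,
    rng: np.random.Generator | None = None,
    bank: task.SourceBank | None = None,
):
    """Train the multilayer control on batches of random contexts.

    With ``seq_len > 1`` the network maps a flattened window of
    ``seq_len`` stimulus samples to the matching window of sources
    (mean-squared-error objective, Adam at the stated learning rate).
    Returns (mlp, loss_curve).
    """
    if seq_len < 1:
        raise InvalidParameterError("seq_len must be >= 1")
    if rng is None:
        rng = np.random.default_rng()
    if bank is None:
        bank = task.generate_sources(T=16_000)
    n_s = bank.n_s
    mlp = MLP(seq_len * n_s, seq_len * n_s, hidden, rng)
    opt = Adam(mlp.parameters(), lr=learning_rate)
    losses = []
    win = samples_per_context - samples_per_context % seq_len
    for _ in range(n_batches):
        X, Y = [], []
        for _ in range(contexts_per_batch):
            A = task.sample_mixing_matrix(rng, n_s).A
            off = rng.integers(0, bank.T - samples_per_context + 1)
            s = bank.samples[off : off + win]
            x = s @ A.T
            if sigma_n:
                x = x + sigma_n * rng.standard_normal(x.shape)
            X.append(x.reshape(-1, seq_len * n_s))
            Y.append(s.reshape(-1, seq_len * n_s))
        X = np.concatenate(X)
        Y = np.concatenate(Y)
        opt.zero_grad()
        pred = mlp.forward(X)
        err = ad.sub(pred, ad.Tensor(Y))
        loss = ad.mean(ad.mul(err, err))
        ad.backward(loss)
        opt.step()
        losses.append(loss.item())
    return mlp, np.asarray(losses)
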