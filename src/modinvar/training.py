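"""Closed-loop training of the modulator by backpropagation through time.

Each batch simulates 32 independent trials of n_t samples: every trial
draws a fresh mixing context and an independent random chunk of each
source from a long pre-generated bank (phase randomisation, so the
modulator cannot memorise the sequence).  The accumulated smooth-L1
reconstruction loss plus a small L1 penalty on the feedback signals is
backpropagated through all n_t closed-loop steps; gradients are clipped
elementwise to [-1, 1] and applied with Adam.

Modulator parameters are always trained; the Dalean model additionally
trains its feedforward weights (used as absolute values where
sign-constrained).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import autodiff as ad
from . import networks, task
from .exceptions import InvalidParameterError, TrainingError

__all__ = [
    "TrainingConfig",
    "TrainingHistory",
    "smooth_l1",
    "output_regulariser",
    "init_parameters",
    "make_training_batch",
    "Adam",
    "train",
]


@dataclass
class TrainingConfig:
    """Hyperparameters of one training run (defaults follow the task's
    stated training protocol)."""

    batch_size: int = 32
    n_batches: int = 10_000
    learning_rate: float = 1e-3
    lambda_out: float = 1e-5
    clip: float = 1.0
    n_t: int = task.DEFAULT_N_T
    bank_length: int = 16_000
    sigma_n: float = task.DEFAULT_SIGMA_N
    det_threshold: float = task.DEFAULT_DET_THRESHOLD
    seed: int | None = None
    log_every: int = 100
    checkpoint_every: int = 500

    def __post_init__(self):
        if self.batch_size < 1 or self.n_t < 1 or self.bank_length < 1:
            raise InvalidParameterError("counts must be >= 1")
        if self.n_batches < 0:
            raise InvalidParameterError("n_batches must be >= 0")
        if self.lambda_out < 0:
            raise InvalidParameterError("lambda_out must be >= 0")


@dataclass
class TrainingHistory:
    """Per-batch training diagnostics."""

    loss: list = field(default_factory=list)
    regulariser: list = field(default_factory=list)
    checkpoints: list = field(default_factory=list)

    @property
    def n_batches(self) -> int:
        return len(self.loss)


def smooth_l1(pred, target) -> float:
    """Smooth L1 (Huber-type) distance, reduced by mean over elements:
    h(d) = 0.5 d^2 for |d| < 1 and |d| - 0.5 otherwise."""
    pred = np.asarray(pred, dtype=float)
    target = np.asarray(target, dtype=float)
    if pred.shape != target.shape:
        raise InvalidParameterError("pred and target must have equal shapes")
    d = np.abs(pred - target)
    return float(np.where(d < 1.0, 0.5 * d * d, d - 0.5).mean())


def output_regulariser(feedback_trace, lambda_out: float) -> float:
    """L1 penalty on the feedback signals: lambda_out * sum_t sum_j |l_j(t)|."""
    return float(lambda_out * np.abs(np.asarray(feedback_trace, dtype=float)).sum())


def init_parameters(architecture: str, rng: np.random.Generator, **sizes) -> dict:
    """Draw an initial parameter set for an architecture (see
    :func:`modinvar.networks.default_parameters` for the distributions)."""
    return networks.default_parameters(architecture, rng, **sizes)


def make_training_batch(
    bank: task.SourceBank,
    rng: np.random.Generator,
    batch_size: int = 32,
    n_t: int = task.DEFAULT_N_T,
    sigma_n: float = task.DEFAULT_SIGMA_N,
    det_threshold: float = task.DEFAULT_DET_THRESHOLD,
):
    """One batch of trials.

    Per trial: a fresh mixing matrix and, independently for every source,
    a random chunk offset into the bank.  Returns ``(x, s, A)`` with
    ``x`` and ``s`` of shape (n_t, batch, n_s) and ``A`` (batch, n_s, n_s).
    """
    if bank.T < n_t:
        raise InvalidParameterError("source bank shorter than one trial")
    n_s = bank.n_s
    A = np.stack(
        [sample_A.A for sample_A in
         (task.sample_mixing_matrix(rng, n_s, det_threshold) for _ in range(batch_size))]
    )
    offsets = rng.integers(0, bank.T - n_t + 1, size=(batch_size, n_s))
    s = np.empty((n_t, batch_size, n_s))
    for b in range(batch_size):
        for j in range(n_s):
            s[:, b, j] = bank.samples[offsets[b, j] : offsets[b, j] + n_t, j]
    x = np.einsum("bij,tbj->tbi", A, s)
    if sigma_n:
        x = x + sigma_n * rng.standard_normal(x.shape)
    return x, s, A


class Adam:
    """Adam optimiser (beta1=0.9, beta2=0.999, eps=1e-8) over named tensors."""

    def __init__(self, params: dict, lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = dict(params)
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.t = 0
        self.m = {k: np.zeros_like(p.data) for k, p in self.params.items()}
        self.v = {k: np.zeros_like(p.data) for k, p in self.params.items()}

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for k, p in self.params.items():
            if p.grad is None:
                continue
            g = p.grad
            self.m[k] = b1 * self.m[k] + (1 - b1) * g
            self.v[k] = b2 * self.v[k] + (1 - b2) * g * g
            mhat = self.m[k] / (1 - b1**self.t)
            vhat = self.v[k] / (1 - b2**self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params.values():
            p.grad = None


def clip_gradients(params: dict, bound: float) -> None:
    """Clip every gradient element to [-bound, bound] in place."""
    for p in params.values():
        if p.grad is not None:
            np.clip(p.grad, -bound, bound, out=p.grad)


def simulate_trial_loss(model, x, s, lambda_out: float):
    """Simulate one batch of trials through the closed loop and return the
    (graph-carrying) objective, reconstruction loss and regulariser."""
    n_t, batch, _ = x.shape
    model.reset_state(batch)
    loss_sum = None
    reg_sum = None
    for t in range(n_t):
        y, info = model.step(x[t])
        step_loss = ad.smooth_l1(y, s[t])
        loss_sum = step_loss if loss_sum is None else ad.add(loss_sum, step_loss)
        if lambda_out:
            step_reg = ad.l1(info["l"])
            reg_sum = step_reg if reg_sum is None else ad.add(reg_sum, step_reg)
    loss = ad.scale(loss_sum, 1.0 / n_t)
    # the sum over feedback channels, averaged over time and trials, keeps
    # the penalty commensurate with the mean-reduced reconstruction loss
    reg = ad.scale(reg_sum, lambda_out / (n_t * batch)) if reg_sum is not None else ad.Tensor(0.0)
    objective = ad.add(loss, reg) if lambda_out else loss
    return objective, loss, reg


def train(
    model,
    config: TrainingConfig,
    bank: task.SourceBank | None = None,
    rng: np.random.Generator | None = None,
    on_batch=None,
    verbose: bool = False,
):
    """Train ``model`` in place; returns ``(model, TrainingHistory)``.

    ``on_batch(batch_index, model, params)`` — optional hook called after
    gradient clipping and before the optimiser update (used for
    instrumentation).
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    if bank is None:
        bank = task.generate_sources(T=config.bank_length)
    if bank.T < config.n_t:
        raise InvalidParameterError("bank_length must be >= n_t")
    history = TrainingHistory()
    if config.n_batches == 0:
        return model, history
    params = model.trainable_parameters()
    opt = Adam(params, lr=config.learning_rate)
    for k in range(config.n_batches):
        x, s, _ = make_training_batch(
            bank, rng, config.batch_size, config.n_t, config.sigma_n, config.det_threshold
        )
        opt.zero_grad()
        objective, loss, reg = simulate_trial_loss(model, x, s, config.lambda_out)
        if not np.isfinite(objective.data):
            raise TrainingError(f"non-finite loss at batch {k}", history=history)
        ad.backward(objective)
        clip_gradients(params, config.clip)
        if on_batch is not None:
            on_batch(k, model, params)
        opt.step()
        history.loss.append(loss.item())
        history.regulariser.append(reg.item())
        if config.checkpoint_every and (k + 1) % config.checkpoint_every == 0:
            history.checkpoints.append(
                (k + 1, {n: p.data.copy() for n, p in params.items()})
            )
        if verbose and config.log_every and (k + 1) % config.log_every == 0:
            print(f"batch {k + 1}/{config.n_batches}  loss {loss.item():.5f}")
    history.checkpoints.append(
        (config.n_batches, {n: p.data.copy() for n, p in params.items()})
    )
    return model, history
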