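"""The dynamic blind source separation task.

Sources are fixed periodic signals (by default two "chords", each the sum
of two unit sines).  The sensory stimuli are a linear mixture of the
sources through a mixing matrix A(t) — the *context* — that is piecewise
constant: it is redrawn every ``n_t`` samples from row-normalised random
matrices with a determinant bounded away from zero, plus additive white
Gaussian noise:

    x(t) = A(t) s(t) + sigma_n * xi(t)

Recovering s(t) from x(t) across contexts is the task the modulated
networks are trained on.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as _sig

from .exceptions import InvalidParameterError, SamplingError

__all__ = [
    "SourceBank",
    "MixingMatrix",
    "ContextSchedule",
    "StimulusStream",
    "generate_sources",
    "sample_mixing_matrix",
    "build_schedule",
    "mix_stream",
    "snr_db",
    "context_grid",
    "DEFAULT_CHORD_FREQS",
    "DEFAULT_FS",
    "DEFAULT_N_T",
    "DEFAULT_SIGMA_N",
    "DEFAULT_DET_THRESHOLD",
]

#: default chord frequencies (Hz): source 1 = 100 + 125 Hz, source 2 = 150 + 210 Hz
DEFAULT_CHORD_FREQS = ((100.0, 125.0), (150.0, 210.0))
DEFAULT_FS = 8000.0
DEFAULT_N_T = 1000
DEFAULT_SIGMA_N = 0.001
DEFAULT_DET_THRESHOLD = 0.2


@dataclass
class SourceBank:
    """Clean multichannel source signals with sampling metadata.

    ``samples`` has shape (T, n_s); chords are bounded in [-2, 2] and single
    waveforms in [-1, 1], with zero temporal mean over whole periods.
    """

    samples: np.ndarray
    fs: float
    waveform: str
    freqs: tuple
    phases: tuple = ()

    @property
    def T(self) -> int:
        return self.samples.shape[0]

    @property
    def n_s(self) -> int:
        return self.samples.shape[1]


@dataclass
class MixingMatrix:
    """A row-normalised mixing matrix; one context of the task."""

    A: np.ndarray

    @property
    def n_s(self) -> int:
        return self.A.shape[0]

    @property
    def context_vars(self) -> np.ndarray:
        """Free parameters after row normalisation: the first n_s - 1 entries
        of every row.  For n_s = 2 this is the pair (a, b) with rows
        (a, 1 - a) and (b, 1 - b)."""
        return self.A[:, : self.n_s - 1].ravel().copy()

    @property
    def det(self) -> float:
        return float(np.linalg.det(self.A))


@dataclass
class ContextSchedule:
    """Ordered mixing matrices, each active for ``n_t`` samples."""

    contexts: list
    n_t: int

    @property
    def n_contexts(self) -> int:
        return len(self.contexts)

    @property
    def total_length(self) -> int:
        return self.n_contexts * self.n_t

    def matrix_at(self, t: int) -> np.ndarray:
        return self.contexts[t // self.n_t].A


@dataclass
class StimulusStream:
    """Noisy mixed stimuli aligned with the sources that generated them."""

    x: np.ndarray
    s: np.ndarray
    context_index: np.ndarray
    sigma_n: float
    schedule: ContextSchedule | None = field(default=None, repr=False)

    @property
    def T(self) -> int:
        return self.x.shape[0]

    @property
    def n_s(self) -> int:
        return self.x.shape[1]


def _waveform_values(waveform: str, f: float, t: np.ndarray, fs: float, phase: float):
    arg = 2.0 * np.pi * f * t / fs + phase
    if waveform in ("chord", "sine"):
        return np.sin(arg)
    if waveform == "sawtooth":
        return _sig.sawtooth(arg)
    if waveform == "square":
        return _sig.square(arg)
    raise InvalidParameterError(f"unknown waveform {waveform!r}")


def generate_sources(
    waveform: str = "chord",
    freqs=DEFAULT_CHORD_FREQS,
    T: int = 16000,
    fs: float = DEFAULT_FS,
    phases=None,
) -> SourceBank:
    """Generate the task's source signals.

    Parameters
    ----------
    waveform:
        ``"chord"`` (sum of two unit sines per source, the default),
        ``"sine"``, ``"sawtooth"`` or ``"square"``.
    freqs:
        For chords, one pair of frequencies (Hz) per source; otherwise one
        frequency per source.
    T:
        Number of samples.
    fs:
        Sampling frequency in Hz.
    phases:
        Optional phase offsets (radians), matching the shape of ``freqs``.
        Explicit so that training can randomise them per trial.
    """
    if T < 1:
        raise InvalidParameterError("T must be >= 1")
    if fs <= 0:
        raise InvalidParameterError("fs must be positive")
    freqs = tuple(tuple(np.atleast_1d(f)) for f in freqs)
    for per_source in freqs:
        if any(f <= 0 for f in per_source):
            raise InvalidParameterError("frequencies must be positive")
        if waveform == "chord" and len(per_source) != 2:
            raise InvalidParameterError("chords need 2 frequencies per source")
        if waveform != "chord" and len(per_source) != 1:
            raise InvalidParameterError(f"{waveform} needs 1 frequency per source")
    if phases is None:
        phases = tuple(tuple(0.0 for _ in per_source) for per_source in freqs)
    else:
        phases = tuple(tuple(np.atleast_1d(p)) for p in phases)

    t = np.arange(T, dtype=float)
    cols = []
    for per_source, per_phase in zip(freqs, phases):
        col = np.zeros(T)
        for f, ph in zip(per_source, per_phase):
            col += _waveform_values(waveform, f, t, fs, ph)
        cols.append(col)
    return SourceBank(
        samples=np.column_stack(cols), fs=fs, waveform=waveform, freqs=freqs, phases=phases
    )


def sample_mixing_matrix(
    rng: np.random.Generator,
    n_s: int = 2,
    det_threshold: float = DEFAULT_DET_THRESHOLD,
    max_attempts: int = 10_000,
) -> MixingMatrix:
    """Draw a random context: uniform [0, 1] entries, rows normalised to sum
    one, rejection-sampled until ``|det A| >= det_threshold``."""
    if n_s < 2:
        raise InvalidParameterError("n_s must be >= 2")
    if not 0 <= det_threshold < 1:
        raise InvalidParameterError("det_threshold must be in [0, 1)")
    for _ in range(max_attempts):
        A = rng.uniform(0.0, 1.0, size=(n_s, n_s))
        A /= A.sum(axis=1, keepdims=True)
        if abs(np.linalg.det(A)) >= det_threshold:
            return MixingMatrix(A=A)
    raise SamplingError(
        f"no mixing matrix with |det| >= {det_threshold} found in {max_attempts} attempts"
    )


def build_schedule(
    rng: np.random.Generator,
    n_contexts: int,
    n_t: int = DEFAULT_N_T,
    n_s: int = 2,
    det_threshold: float = DEFAULT_DET_THRESHOLD,
) -> ContextSchedule:
    """Draw ``n_contexts`` independent mixing matrices, each held for
    ``n_t`` samples."""
    if n_contexts < 1 or n_t < 1:
        raise InvalidParameterError("n_contexts and n_t must be >= 1")
    contexts = [sample_mixing_matrix(rng, n_s, det_threshold) for _ in range(n_contexts)]
    return ContextSchedule(contexts=contexts, n_t=n_t)


def mix_stream(
    bank: SourceBank,
    schedule: ContextSchedule,
    sigma_n: float = DEFAULT_SIGMA_N,
    rng: np.random.Generator | None = None,
) -> StimulusStream:
    """Mix the sources through the schedule: x(t) = A(t) s(t) + sigma_n xi(t),
    with xi i.i.d. standard normal per sample and channel."""
    T = schedule.total_length
    if bank.T < T:
        raise InvalidParameterError(
            f"source bank has {bank.T} samples but the schedule needs {T}"
        )
    s = bank.samples[:T]
    n_t = schedule.n_t
    x = np.empty_like(s)
    for k, ctx in enumerate(schedule.contexts):
        seg = slice(k * n_t, (k + 1) * n_t)
        x[seg] = s[seg] @ ctx.A.T
    if sigma_n:
        if rng is None:
            raise InvalidParameterError("rng required when sigma_n > 0")
        x = x + sigma_n * rng.standard_normal(x.shape)
    context_index = np.repeat(np.arange(schedule.n_contexts), n_t)
    return StimulusStream(
        x=x, s=s.copy(), context_index=context_index, sigma_n=sigma_n, schedule=schedule
    )


def snr_db(sigma_s: float, sigma_n: float) -> float:
    """Signal-to-noise ratio 10 log10(sigma_s^2 / sigma_n^2) in decibels."""
    if sigma_s <= 0 or sigma_n <= 0:
        raise InvalidParameterError("sigma_s and sigma_n must be positive")
    return float(10.0 * np.log10(sigma_s**2 / sigma_n**2))


def context_grid(
    n_per_dim: int = 20, det_threshold: float = DEFAULT_DET_THRESHOLD
) -> list[MixingMatrix]:
    """Evenly spaced grid of 2x2 contexts on the (a, b) square.

    Row-normalised matrices [[a, 1-a], [b, 1-b]] are built from an
    endpoint-inclusive ``n_per_dim``-point grid on [0, 1] per dimension;
    points with |det A| = |a - b| below the threshold are excluded.  At the
    defaults (20 points, threshold 0.2) this leaves 272 contexts.
    """
    if n_per_dim < 2:
        raise InvalidParameterError("n_per_dim must be >= 2")
    pts = np.linspace(0.0, 1.0, n_per_dim)
    out = []
    for a in pts:
        for b in pts:
            A = np.array([[a, 1.0 - a], [b, 1.0 - b]])
            if abs(np.linalg.det(A)) >= det_threshold:
                out.append(MixingMatrix(A=A))
    return out
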