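"""Feedback-modulated feedforward network architectures.

Three feedforward variants share one closed-loop layout: a recurrent
*modulator* (an LSTM with forget gates and no peephole connections, plus a
linear readout) observes the sensory stimuli x(t) and the network's own
output y(t-1) and emits a low-dimensional feedback vector that changes the
feedforward computation multiplicatively:

* ``SimpleModulatedNet`` — y = (M ⊙ W0) x, one multiplicative factor per
  baseline weight; optionally low-pass filtered with time constant tau.
* ``PopulationNet`` — a ring of N_z units z = m ⊙ (Wx x), y = Wro z, where
  the per-unit modulation m follows tau dm/dt = -m + K l and K is a
  von Mises kernel mapping N_FB feedback signals onto the ring.
* ``DaleanNet`` — a two-stage hierarchy of positive rates with feedforward
  inhibition and sign-constrained inter-population weights; feedback sets
  per-neuron gains p = 1 / (1 + exp(m)) in (0, 1), so stronger feedback
  *decreases* the gain.

The modulator receives the one-step-delayed output y(t-1), which removes
the algebraic loop of simultaneous modulation and readout.  All dynamics
are integrated with forward Euler at dt = 1 sample.
"""

from __future__ import annotations

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor
from .exceptions import InvalidParameterError

__all__ = [
    "Modulator",
    "SimpleModulatedNet",
    "PopulationNet",
    "DaleanNet",
    "default_parameters",
    "modulator_step",
    "forward_simple",
    "step_filtered_modulation",
    "von_mises_kernel",
    "step_population_modulation",
    "forward_population",
    "gain_from_modulation",
    "forward_dalean",
    "effective_weights",
    "build_model",
]

INPUT_MODES = ("x_and_y", "x_only", "y_only")


# ---------------------------------------------------------------------------
# parameter initialisation


def default_parameters(
    architecture: str,
    rng: np.random.Generator,
    n_s: int = 2,
    n_hidden: int = 100,
    n_fb: int = 4,
    n_z: int = 100,
    n_l: int = 40,
    n_h: int = 100,
    n_i: int = 20,
    second_arg_is_std: bool = False,
) -> dict:
    """Draw the initial parameter arrays for one architecture.

    Gaussian entries are written N(mu, v); ``v`` is read as a variance by
    default (``second_arg_is_std=True`` switches to the standard-deviation
    reading).  LSTM parameters (weights and biases) are uniform in
    [-1/n_hidden, 1/n_hidden] and the modulator readout is uniform in
    [-1/n_out, 1/n_out] with ``n_out`` the number of feedback signals.
    """

    def normal(mu, v, size):
        sd = v if second_arg_is_std else np.sqrt(v)
        return rng.normal(mu, sd, size=size)

    if architecture == "simple":
        n_out = n_s * n_s
        params = {"W0": normal(1.0, 0.001, (n_s, n_s))}
    elif architecture == "population":
        n_out = n_fb
        params = {
            "Wx": normal(0.0, 0.5, (n_z, n_s)),
            "Wro": normal(0.0, 0.5, (n_s, n_z)),
        }
    elif architecture == "dalean":
        n_out = n_fb
        params = {
            "WLx": normal(0.0, 0.5, (n_l, n_s)),
            "WHL": normal(1.0, 0.5, (n_h, n_l)) * 20.0 / n_h,
            "WIL": normal(1.0, 0.5, (n_i, n_l)) / n_i,
            "WHI": normal(1.0, 1.0, (n_h, n_i)) * 20.0 / n_h,
            "Wro": normal(0.0, 0.5, (n_s, n_h)),
        }
    else:
        raise InvalidParameterError(f"unknown architecture {architecture!r}")

    n_in = 2 * n_s
    bh = 1.0 / n_hidden
    bo = 1.0 / n_out
    params.update(
        {
            "lstm_W": rng.uniform(-bh, bh, (4 * n_hidden, n_in)),
            "lstm_R": rng.uniform(-bh, bh, (4 * n_hidden, n_hidden)),
            "lstm_b": rng.uniform(-bh, bh, 4 * n_hidden),
            "ro_W": rng.uniform(-bo, bo, (n_out, n_hidden)),
            "ro_b": rng.uniform(-bo, bo, n_out),
        }
    )
    return params


# ---------------------------------------------------------------------------
# the modulator (LSTM + linear readout)


class Modulator:
    """Recurrent modulatory system: LSTM cell plus linear feedback readout.

    ``input_mode`` selects which of (x, y) the modulator sees; the omitted
    input is zero-masked so ablations leave parameter counts unchanged.
    """

    def __init__(self, n_s, n_hidden, n_out, input_mode="x_and_y", params=None, rng=None):
        if input_mode not in INPUT_MODES:
            raise InvalidParameterError(f"input_mode must be one of {INPUT_MODES}")
        self.n_s = n_s
        self.n_hidden = n_hidden
        self.n_out = n_out
        self.input_mode = input_mode
        if params is None:
            if rng is None:
                raise InvalidParameterError("provide params or rng")
            params = default_parameters("simple", rng, n_s=n_s, n_hidden=n_hidden)
            params = {k: v for k, v in params.items() if k != "W0"}
            if n_out != n_s * n_s:  # re-draw readout at the requested width
                bo = 1.0 / n_out
                params["ro_W"] = rng.uniform(-bo, bo, (n_out, n_hidden))
                params["ro_b"] = rng.uniform(-bo, bo, n_out)
        self.W = Tensor(params["lstm_W"], requires_grad=True)
        self.R = Tensor(params["lstm_R"], requires_grad=True)
        self.b = Tensor(params["lstm_b"], requires_grad=True)
        self.ro_W = Tensor(params["ro_W"], requires_grad=True)
        self.ro_b = Tensor(params["ro_b"], requires_grad=True)

    def parameters(self) -> dict:
        return {
            "lstm_W": self.W,
            "lstm_R": self.R,
            "lstm_b": self.b,
            "ro_W": self.ro_W,
            "ro_b": self.ro_b,
        }

    def init_state(self, batch_size: int = 1):
        """Hidden and cell state, zero-initialised at trial start."""
        h = Tensor(np.zeros((batch_size, self.n_hidden)))
        c = Tensor(np.zeros((batch_size, self.n_hidden)))
        return (h, c)

    def step(self, x_t, y_prev, state):
        """One LSTM update; returns (feedback_vector, new_state).

        Gate order is (input, forget, cell, output); the cell has forget
        gates but no peephole connections.  The feedback vector is a linear
        readout of the new hidden state.
        """
        h, c = state
        x_t = x_t if isinstance(x_t, Tensor) else Tensor(x_t)
        y_prev = y_prev if isinstance(y_prev, Tensor) else Tensor(y_prev)
        if x_t.data.shape[-1] != self.n_s or y_prev.data.shape[-1] != self.n_s:
            raise InvalidParameterError("modulator inputs must have n_s entries each")
        if self.input_mode == "x_only":
            y_prev = ad.scale(y_prev, 0.0)
        elif self.input_mode == "y_only":
            x_t = ad.scale(x_t, 0.0)
        u = ad.concat([x_t, y_prev], axis=-1)
        H = self.n_hidden
        hc = ad.lstm_cell(u, h, c, self.W, self.R, self.b)
        h_new = ad.narrow(hc, 0, H)
        c_new = ad.narrow(hc, H, 2 * H)
        feedback = ad.linear(h_new, self.ro_W, self.ro_b)
        return feedback, (h_new, c_new)


# ---------------------------------------------------------------------------
# feedforward variants


class _ModulatedModel:
    """Shared state handling for the closed-loop models."""

    architecture = ""

    def __init__(self):
        self.batch_size = 0

    def reset_state(self, batch_size: int = 1) -> None:
        self.batch_size = batch_size
        self._mod_state = self.modulator.init_state(batch_size)
        self._y_prev = Tensor(np.zeros((batch_size, self.n_s)))
        self._reset_modulation(batch_size)

    def trainable_parameters(self) -> dict:
        return dict(self.modulator.parameters())

    def parameters(self) -> dict:
        return self.trainable_parameters()

    def step(self, x_t, frozen: bool = False, ext_drive: float = 0.0):
        """Advance the closed loop by one sample.

        ``frozen`` clamps the modulation variables at their current value
        while the modulator's hidden dynamics continue unseen.
        ``ext_drive`` adds a constant input to the modulation-unit dynamics
        (Dalean model only).
        """
        raise NotImplementedError


class SimpleModulatedNet(_ModulatedModel):
    """y = (M ⊙ W0) x with M supplied (optionally low-pass filtered) by the
    modulator; baseline weights W0 are drawn near one and stay fixed."""

    architecture = "simple"

    def __init__(self, n_s=2, n_hidden=100, tau=None, dt=1.0, input_mode="x_and_y",
                 params=None, rng=None):
        super().__init__()
        if tau is not None and tau <= 0:
            raise InvalidParameterError("tau must be positive or None")
        self.n_s = n_s
        self.tau = tau
        self.dt = dt
        if params is None:
            if rng is None:
                raise InvalidParameterError("provide params or rng")
            params = default_parameters("simple", rng, n_s=n_s, n_hidden=n_hidden)
        self.W0 = Tensor(params["W0"])
        self.modulator = Modulator(n_s, n_hidden, n_s * n_s, input_mode, params=params)
        self.reset_state()

    def _reset_modulation(self, batch_size):
        # neutral modulation: with M = 1 the net is the linear map W0
        self.M = Tensor(np.ones((batch_size, self.n_s, self.n_s)))

    def step(self, x_t, frozen=False, ext_drive=0.0):
        x_t = x_t if isinstance(x_t, Tensor) else Tensor(x_t)
        l, self._mod_state = self.modulator.step(x_t, self._y_prev, self._mod_state)
        if not frozen:
            drive = ad.reshape(l, (self.batch_size, self.n_s, self.n_s))
            if self.tau is None:
                self.M = drive
            else:
                self.M = ad.add(self.M, ad.scale(ad.sub(drive, self.M), self.dt / self.tau))
        y = ad.modmix(ad.mul(self.M, self.W0), x_t)
        self._y_prev = y
        return y, {"l": l, "M": self.M}


class PopulationNet(_ModulatedModel):
    """Ring population z = m ⊙ (Wx x) with spatially diffuse modulation.

    The N_FB feedback signals are spread over the ring by a von Mises
    kernel; Wx and the readout Wro are fixed, only the modulator learns.
    """

    architecture = "population"

    def __init__(self, n_s=2, n_hidden=100, n_z=100, n_fb=4, sigma_m_sq=0.2,
                 tau=100.0, dt=1.0, input_mode="x_and_y", normalize_kernel=True,
                 params=None, rng=None):
        super().__init__()
        if tau is None or tau <= 0:
            raise InvalidParameterError("tau must be positive")
        self.n_s = n_s
        self.n_z = n_z
        self.n_fb = n_fb
        self.sigma_m_sq = sigma_m_sq
        self.tau = tau
        self.dt = dt
        if params is None:
            if rng is None:
                raise InvalidParameterError("provide params or rng")
            params = default_parameters(
                "population", rng, n_s=n_s, n_hidden=n_hidden, n_fb=n_fb, n_z=n_z
            )
        self.Wx = Tensor(params["Wx"])
        self.Wro = Tensor(params["Wro"])
        self.K = Tensor(von_mises_kernel(n_z, n_fb, sigma_m_sq, normalize=normalize_kernel))
        self.unit_locations = 2.0 * np.pi * np.arange(n_z) / n_z
        self.modulator = Modulator(n_s, n_hidden, n_fb, input_mode, params=params)
        self.reset_state()

    def _reset_modulation(self, batch_size):
        self.m = Tensor(np.zeros((batch_size, self.n_z)))

    def step(self, x_t, frozen=False, ext_drive=0.0):
        x_t = x_t if isinstance(x_t, Tensor) else Tensor(x_t)
        l, self._mod_state = self.modulator.step(x_t, self._y_prev, self._mod_state)
        if not frozen:
            drive = ad.linear(l, self.K)  # K l on the ring
            self.m = ad.add(self.m, ad.scale(ad.sub(drive, self.m), self.dt / self.tau))
        z = ad.mul(self.m, ad.linear(x_t, self.Wx))
        y = ad.linear(z, self.Wro)
        self._y_prev = y
        return y, {"l": l, "m": self.m, "z": z}


class DaleanNet(_ModulatedModel):
    """Hierarchical rate network obeying Dale's principle.

    zL = [WLx x]+ feeds a higher-level population both directly and through
    feedforward inhibition, zH = [p ⊙ (|WHL| zL − |WHI| zI)]+ with
    zI = [|WIL| zL]+.  Inter-population weights enter as absolute values;
    feedback drives modulation units m whose sigmoidal gains
    p = 1/(1 + exp(m)) stay in (0, 1).  Feedforward weights are trained
    together with the modulator.
    """

    architecture = "dalean"

    def __init__(self, n_s=2, n_hidden=100, n_l=40, n_h=100, n_i=20, n_fb=4,
                 sigma_m_sq=0.2, tau=100.0, dt=1.0, input_mode="x_and_y",
                 normalize_kernel=True, params=None, rng=None):
        super().__init__()
        if tau is None or tau <= 0:
            raise InvalidParameterError("tau must be positive")
        self.n_s = n_s
        self.n_l, self.n_h, self.n_i, self.n_fb = n_l, n_h, n_i, n_fb
        self.sigma_m_sq = sigma_m_sq
        self.tau = tau
        self.dt = dt
        if params is None:
            if rng is None:
                raise InvalidParameterError("provide params or rng")
            params = default_parameters(
                "dalean", rng, n_s=n_s, n_hidden=n_hidden, n_fb=n_fb,
                n_l=n_l, n_h=n_h, n_i=n_i,
            )
        for name in ("WLx", "WHL", "WIL", "WHI", "Wro"):
            setattr(self, name, Tensor(params[name], requires_grad=True))
        self.K = Tensor(von_mises_kernel(n_h, n_fb, sigma_m_sq, normalize=normalize_kernel))
        self.unit_locations = 2.0 * np.pi * np.arange(n_h) / n_h
        self.modulator = Modulator(n_s, n_hidden, n_fb, input_mode, params=params)
        self.reset_state()

    def trainable_parameters(self) -> dict:
        out = dict(self.modulator.parameters())
        out.update(
            {n: getattr(self, n) for n in ("WLx", "WHL", "WIL", "WHI", "Wro")}
        )
        return out

    def _reset_modulation(self, batch_size):
        self.m = Tensor(np.zeros((batch_size, self.n_h)))
        # |W| nodes are rebuilt whenever parameters may have changed
        self._aWHL = ad.absolute(self.WHL)
        self._aWIL = ad.absolute(self.WIL)
        self._aWHI = ad.absolute(self.WHI)
        self._masks = None

    @property
    def p(self) -> Tensor:
        return ad.sigmoid(ad.scale(self.m, -1.0))

    def step(self, x_t, frozen=False, ext_drive=0.0):
        x_t = x_t if isinstance(x_t, Tensor) else Tensor(x_t)
        l, self._mod_state = self.modulator.step(x_t, self._y_prev, self._mod_state)
        if not frozen:
            drive = ad.linear(l, self.K)
            if ext_drive:
                drive = ad.add(drive, float(ext_drive))
            self.m = ad.add(self.m, ad.scale(ad.sub(drive, self.m), self.dt / self.tau))
        p = ad.sigmoid(ad.scale(self.m, -1.0))
        zL = ad.relu(ad.linear(x_t, self.WLx))
        zI = ad.relu(ad.linear(zL, self._aWIL))
        hH = ad.mul(p, ad.sub(ad.linear(zL, self._aWHL), ad.linear(zI, self._aWHI)))
        zH = ad.relu(hH)
        y = ad.linear(zH, self.Wro)
        self._y_prev = y
        self._masks = (zL.data > 0, zI.data > 0, hH.data > 0)
        return y, {"l": l, "m": self.m, "p": p, "zL": zL, "zI": zI, "zH": zH}


def build_model(architecture: str, rng: np.random.Generator, **kwargs):
    """Construct a model of the given architecture with default-initialised
    parameters."""
    cls = {"simple": SimpleModulatedNet, "population": PopulationNet,
           "dalean": DaleanNet}.get(architecture)
    if cls is None:
        raise InvalidParameterError(f"unknown architecture {architecture!r}")
    return cls(rng=rng, **kwargs)


# ---------------------------------------------------------------------------
# stateless building blocks (numpy in / numpy out)


def modulator_step(modulator: Modulator, x_t, y_prev, state=None):
    """One recurrent update; numpy convenience wrapper around
    :meth:`Modulator.step`."""
    if state is None:
        batch = np.atleast_2d(x_t).shape[0]
        state = modulator.init_state(batch)
    with ad.no_grad():
        feedback, new_state = modulator.step(
            np.atleast_2d(x_t), np.atleast_2d(y_prev), state
        )
    return feedback.data, new_state


def forward_simple(net: SimpleModulatedNet, x_t):
    """y = (M ⊙ W0) x at the network's current modulation."""
    x = np.atleast_2d(x_t)
    y = np.einsum("bij,bj->bi", net.M.data * net.W0.data, x)
    return y[0] if np.ndim(x_t) == 1 else y


def step_filtered_modulation(M, drive, tau, dt: float = 1.0):
    """Forward-Euler step of tau dM/dt = -M + drive."""
    if tau <= 0 or dt <= 0:
        raise InvalidParameterError("tau and dt must be positive")
    M = np.asarray(M, dtype=float)
    return M + (dt / tau) * (np.asarray(drive, dtype=float) - M)


def von_mises_kernel(n_units: int, n_fb: int, sigma_m_sq: float, normalize: bool = True):
    """Von Mises kernel K_ij = exp(cos(z_i - l_j) / sigma_m^2) on the ring.

    Unit locations z_i and preferred feedback locations l_j are evenly
    spaced on [0, 2 pi).  ``sigma_m_sq = inf`` yields a uniform kernel
    (identical modulation across the population).  With ``normalize`` each
    row is rescaled to sum one so the overall modulation drive is
    independent of n_fb and the kernel width.
    """
    if n_fb < 1:
        raise InvalidParameterError("n_fb must be >= 1")
    if not (sigma_m_sq > 0):
        raise InvalidParameterError("sigma_m_sq must be positive (may be inf)")
    z_loc = 2.0 * np.pi * np.arange(n_units) / n_units
    l_loc = 2.0 * np.pi * np.arange(n_fb) / n_fb
    if np.isinf(sigma_m_sq):
        K = np.ones((n_units, n_fb))
    else:
        K = np.exp(np.cos(z_loc[:, None] - l_loc[None, :]) / sigma_m_sq)
    if normalize:
        K = K / K.sum(axis=1, keepdims=True)
    return K


def step_population_modulation(m, feedback, K, tau, dt: float = 1.0):
    """Forward-Euler step of tau dm/dt = -m + K l for the ring modulation."""
    if tau <= 0 or dt <= 0:
        raise InvalidParameterError("tau and dt must be positive")
    m = np.asarray(m, dtype=float)
    drive = np.asarray(feedback, dtype=float) @ np.asarray(K).T
    return m + (dt / tau) * (drive - m)


def forward_population(net: PopulationNet, x_t):
    """(z, y) at the network's current modulation state."""
    x = np.atleast_2d(x_t)
    z = net.m.data * (x @ net.Wx.data.T)
    y = z @ net.Wro.data.T
    if np.ndim(x_t) == 1:
        return z[0], y[0]
    return z, y


def gain_from_modulation(m):
    """Sigmoidal gain p = 1 / (1 + exp(m)); decreasing in m, bounded in (0, 1)."""
    from scipy.special import expit

    return expit(-np.asarray(m, dtype=float))


def forward_dalean(net: DaleanNet, x_t):
    """(zL, zI, zH, y) at the network's current gains."""
    x = np.atleast_2d(x_t)
    p = gain_from_modulation(net.m.data)
    zL = np.maximum(x @ net.WLx.data.T, 0.0)
    zI = np.maximum(zL @ np.abs(net.WIL.data).T, 0.0)
    zH = np.maximum(p * (zL @ np.abs(net.WHL.data).T - zI @ np.abs(net.WHI.data).T), 0.0)
    y = zH @ net.Wro.data.T
    if np.ndim(x_t) == 1:
        return zL[0], zI[0], zH[0], y[0]
    return zL, zI, zH, y


def effective_weights(net, batch_index: int = 0):
    """The end-to-end linear input-to-output map implied by the current
    modulation state (for rectified models: linearised at the current
    operating point using the active-unit masks of the last step)."""
    if isinstance(net, SimpleModulatedNet):
        return net.M.data[batch_index] * net.W0.data
    if isinstance(net, PopulationNet):
        return net.Wro.data @ (net.m.data[batch_index][:, None] * net.Wx.data)
    if isinstance(net, DaleanNet):
        if net._masks is None:
            raise InvalidParameterError("run a forward step before linearising")
        mL, mI, mH = (m[batch_index] for m in net._masks)
        p = gain_from_modulation(net.m.data[batch_index])
        L = mL[:, None] * net.WLx.data  # d zL / d x
        I = mI[:, None] * (np.abs(net.WIL.data) @ L)
        H = mH[:, None] * (p[:, None] * (np.abs(net.WHL.data) @ L - np.abs(net.WHI.data) @ I))
        return net.Wro.data @ H
    raise InvalidParameterError(f"unsupported model type {type(net).__name__}")
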