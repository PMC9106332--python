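"""Reverse-mode automatic differentiation over numpy arrays.

A deliberately small tape-based engine providing exactly the operations
needed to backpropagate through the closed-loop network simulations:
affine maps, the LSTM nonlinearities, elementwise arithmetic with
broadcasting, slicing/concatenation, and the training losses.  Gradients
are accumulated into :class:`Tensor` leaves created with
``requires_grad=True``; everything is validated against central finite
differences in the test suite.

The engine is graph-free when no input requires a gradient (or inside a
:func:`no_grad` block), so the same model code serves both training and
plain simulation at numpy speed.
"""

from __future__ import annotations

import contextlib

import numpy as np

__all__ = [
    "Tensor",
    "no_grad",
    "add",
    "sub",
    "mul",
    "scale",
    "linear",
    "modmix",
    "sigmoid",
    "tanh",
    "relu",
    "absolute",
    "concat",
    "narrow",
    "reshape",
    "total",
    "mean",
    "l1",
    "smooth_l1",
    "backward",
]

_grad_enabled = True


@contextlib.contextmanager
def no_grad():
    """Disable graph construction within the block (pure numpy execution)."""
    global _grad_enabled
    prev = _grad_enabled
    _grad_enabled = False
    try:
        yield
    finally:
        _grad_enabled = prev


class Tensor:
    """An array node of the computation graph."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_bwd")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=float)
        self.grad = None
        self.requires_grad = bool(requires_grad) and _grad_enabled
        self._parents: tuple = ()
        self._bwd = None

    @property
    def shape(self):
        return self.data.shape

    def zero_grad(self) -> None:
        self.grad = None

    def item(self) -> float:
        return float(self.data)

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"


def _as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def _node(data, parents, bwd) -> Tensor:
    out = Tensor(data)
    if _grad_enabled and any(p.requires_grad for p in parents):
        out.requires_grad = True
        out._parents = tuple(parents)
        out._bwd = bwd
    return out


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Reduce ``grad`` back to ``shape`` after numpy broadcasting."""
    if grad.shape == shape:
        return grad
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, n in enumerate(shape) if n == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad


def _accum(t: Tensor, g: np.ndarray) -> None:
    if not t.requires_grad:
        return
    g = _unbroadcast(np.asarray(g), t.data.shape)
    t.grad = g if t.grad is None else t.grad + g


# ---------------------------------------------------------------------------
# primitives


def add(a, b) -> Tensor:
    a, b = _as_tensor(a), _as_tensor(b)
    out_data = a.data + b.data

    def bwd(g):
        _accum(a, g)
        _accum(b, g)

    return _node(out_data, (a, b), bwd)


def sub(a, b) -> Tensor:
    a, b = _as_tensor(a), _as_tensor(b)
    out_data = a.data - b.data

    def bwd(g):
        _accum(a, g)
        _accum(b, -g)

    return _node(out_data, (a, b), bwd)


def mul(a, b) -> Tensor:
    a, b = _as_tensor(a), _as_tensor(b)
    out_data = a.data * b.data

    def bwd(g):
        _accum(a, g * b.data)
        _accum(b, g * a.data)

    return _node(out_data, (a, b), bwd)


def scale(a, c: float) -> Tensor:
    """Multiply by a python constant."""
    a = _as_tensor(a)
    c = float(c)

    def bwd(g):
        _accum(a, g * c)

    return _node(a.data * c, (a,), bwd)


def linear(x, W, b=None) -> Tensor:
    """Affine map ``y = x @ W.T + b`` with ``W`` of shape (out, in)."""
    x, W = _as_tensor(x), _as_tensor(W)
    out_data = x.data @ W.data.T
    if b is not None:
        b = _as_tensor(b)
        out_data = out_data + b.data
        parents = (x, W, b)
    else:
        parents = (x, W)

    def bwd(g):
        _accum(x, g @ W.data)
        if x.data.ndim == 1:
            _accum(W, np.outer(g, x.data))
        else:
            _accum(W, g.T @ x.data)
        if b is not None:
            _accum(b, g.sum(axis=0) if g.ndim > 1 else g)

    return _node(out_data, parents, bwd)


def modmix(Mw, x) -> Tensor:
    """Batched matrix-vector product ``y_bi = sum_j Mw_bij x_bj``.

    Used for the modulated readout (M ⊙ W0) x with a batch of modulation
    matrices.
    """
    Mw, x = _as_tensor(Mw), _as_tensor(x)
    out_data = np.einsum("bij,bj->bi", Mw.data, x.data)

    def bwd(g):
        _accum(Mw, g[:, :, None] * x.data[:, None, :])
        _accum(x, np.einsum("bij,bi->bj", Mw.data, g))

    return _node(out_data, (Mw, x), bwd)


def _stable_sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def sigmoid(a) -> Tensor:
    a = _as_tensor(a)
    s = _stable_sigmoid(a.data)

    def bwd(g):
        _accum(a, g * s * (1.0 - s))

    return _node(s, (a,), bwd)


def tanh(a) -> Tensor:
    a = _as_tensor(a)
    t = np.tanh(a.data)

    def bwd(g):
        _accum(a, g * (1.0 - t * t))

    return _node(t, (a,), bwd)


def relu(a) -> Tensor:
    a = _as_tensor(a)
    out_data = np.maximum(a.data, 0.0)

    def bwd(g):
        _accum(a, g * (a.data > 0))

    return _node(out_data, (a,), bwd)


def absolute(a) -> Tensor:
    a = _as_tensor(a)

    def bwd(g):
        _accum(a, g * np.sign(a.data))

    return _node(np.abs(a.data), (a,), bwd)


def concat(parts, axis: int = -1) -> Tensor:
    parts = [_as_tensor(p) for p in parts]
    out_data = np.concatenate([p.data for p in parts], axis=axis)
    sizes = [p.data.shape[axis] for p in parts]
    offsets = np.cumsum([0] + sizes)

    def bwd(g):
        for p, i0, i1 in zip(parts, offsets[:-1], offsets[1:]):
            idx = [slice(None)] * g.ndim
            idx[axis if axis >= 0 else g.ndim + axis] = slice(i0, i1)
            _accum(p, g[tuple(idx)])

    return _node(out_data, tuple(parts), bwd)


def narrow(a, i0: int, i1: int, axis: int = -1) -> Tensor:
    """Contiguous slice ``a[..., i0:i1]`` along ``axis``."""
    a = _as_tensor(a)
    idx = [slice(None)] * a.data.ndim
    ax = axis if axis >= 0 else a.data.ndim + axis
    idx[ax] = slice(i0, i1)
    idx = tuple(idx)

    def bwd(g):
        full = np.zeros_like(a.data)
        full[idx] = g
        _accum(a, full)

    return _node(a.data[idx], (a,), bwd)


def reshape(a, shape) -> Tensor:
    a = _as_tensor(a)

    def bwd(g):
        _accum(a, g.reshape(a.data.shape))

    return _node(a.data.reshape(shape), (a,), bwd)


def total(a) -> Tensor:
    """Sum of all elements (scalar node)."""
    a = _as_tensor(a)

    def bwd(g):
        _accum(a, np.broadcast_to(g, a.data.shape))

    return _node(a.data.sum(), (a,), bwd)


def mean(a) -> Tensor:
    a = _as_tensor(a)
    n = a.data.size

    def bwd(g):
        _accum(a, np.broadcast_to(g / n, a.data.shape))

    return _node(a.data.mean(), (a,), bwd)


def l1(a) -> Tensor:
    """Sum of absolute values (scalar node)."""
    a = _as_tensor(a)

    def bwd(g):
        _accum(a, g * np.sign(a.data))

    return _node(np.abs(a.data).sum(), (a,), bwd)


def lstm_cell(u, h, c, W, R, b) -> Tensor:
    """Fused LSTM cell update (forget gates, no peepholes).

    ``W``/``R`` stack the (input, forget, cell, output) gate blocks along
    the first axis.  Returns the concatenated new state [h'; c'] of shape
    (batch, 2H); split it with :func:`narrow`.  Fusing the cell into one
    graph node keeps the per-step tape short, which matters when
    backpropagating through thousands of closed-loop steps.
    """
    u, h, c = _as_tensor(u), _as_tensor(h), _as_tensor(c)
    W, R, b = _as_tensor(W), _as_tensor(R), _as_tensor(b)
    H = h.data.shape[-1]
    pre = u.data @ W.data.T + h.data @ R.data.T + b.data
    zi = 1.0 / (1.0 + np.exp(-pre[:, :H]))
    zf = 1.0 / (1.0 + np.exp(-pre[:, H : 2 * H]))
    zg = np.tanh(pre[:, 2 * H : 3 * H])
    zo = 1.0 / (1.0 + np.exp(-pre[:, 3 * H :]))
    c_new = zf * c.data + zi * zg
    tc = np.tanh(c_new)
    h_new = zo * tc

    def bwd(g):
        gh, gc = g[:, :H], g[:, H:]
        dc = gc + gh * zo * (1.0 - tc * tc)
        dpre = np.empty_like(pre)
        dpre[:, :H] = dc * zg * zi * (1.0 - zi)
        dpre[:, H : 2 * H] = dc * c.data * zf * (1.0 - zf)
        dpre[:, 2 * H : 3 * H] = dc * zi * (1.0 - zg * zg)
        dpre[:, 3 * H :] = gh * tc * zo * (1.0 - zo)
        _accum(u, dpre @ W.data)
        _accum(h, dpre @ R.data)
        _accum(c, dc * zf)
        _accum(W, dpre.T @ u.data)
        _accum(R, dpre.T @ h.data)
        _accum(b, dpre.sum(axis=0))

    return _node(np.concatenate([h_new, c_new], axis=1), (u, h, c, W, R, b), bwd)


def smooth_l1(pred, target) -> Tensor:
    """Mean Huber-type loss: 0.5 d² for |d| < 1, |d| − 0.5 otherwise."""
    pred = _as_tensor(pred)
    tgt = np.asarray(target.data if isinstance(target, Tensor) else target, dtype=float)
    d = pred.data - tgt
    absd = np.abs(d)
    h = np.where(absd < 1.0, 0.5 * d * d, absd - 0.5)
    n = d.size

    def bwd(g):
        _accum(pred, g * np.clip(d, -1.0, 1.0) / n)

    return _node(h.mean(), (pred,), bwd)


# ---------------------------------------------------------------------------
# backward pass


def backward(root: Tensor) -> None:
    """Backpropagate from a scalar ``root`` through the recorded graph."""
    if root.data.ndim != 0:
        raise ValueError("backward() requires a scalar root")
    if not root.requires_grad:
        return
    # iterative post-order topological sort (graphs can be ~1e4 nodes deep)
    topo: list[Tensor] = []
    seen: set[int] = set()
    stack: list[tuple[Tensor, bool]] = [(root, False)]
    while stack:
        node, processed = stack.pop()
        if processed:
            topo.append(node)
            continue
        if id(node) in seen:
            continue
        seen.add(id(node))
        stack.append((node, True))
        for p in node._parents:
            if p.requires_grad and id(p) not in seen:
                stack.append((p, False))
    root.grad = np.ones_like(root.data)
    for node in reversed(topo):
        if node._bwd is not None and node.grad is not None:
            node._bwd(node.grad)
            # free the tape as we go; leaves keep their grads
            node._bwd = None
            node._parents = ()
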