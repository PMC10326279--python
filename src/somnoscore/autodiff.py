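"""Minimal reverse-mode automatic differentiation on numpy arrays.

Implements exactly the operator set the sleep-staging network needs
(1-d convolution, affine layers, ReLU, softmax, axis reductions,
concatenation, label gathering) with a tape-free graph of closures, in
the style of micrograd scaled up to ndarray operands.  Gradients follow
the dtype of the forward data, so float64 finite-difference checks and
float32 training share one code path.

Not a general framework: ops are total functions on finite inputs and
no in-place mutation of tracked tensors is supported.
"""

from __future__ import annotations

from contextlib import contextmanager

import numpy as np

_GRAD_ENABLED = True


@contextmanager
def no_grad():
    """Disable graph construction inside the context (pure forward)."""
    global _GRAD_ENABLED
    prev = _GRAD_ENABLED
    _GRAD_ENABLED = False
    try:
        yield
    finally:
        _GRAD_ENABLED = prev


def grad_enabled() -> bool:
    return _GRAD_ENABLED


class Tensor:
    """An ndarray plus (optionally) a node in the backward graph."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data)
        self.grad = None
        self.requires_grad = bool(requires_grad)
        self._parents: tuple = ()
        self._backward = None

    # -- introspection -------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def dtype(self):
        return self.data.dtype

    def __repr__(self):  # pragma: no cover
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    def item(self) -> float:
        return float(self.data)

    def detach(self) -> "Tensor":
        return Tensor(self.data, requires_grad=False)

    def zero_grad(self) -> None:
        self.grad = None

    # -- operator sugar ------------------------------------------------
    def __add__(self, other):
        return add(self, other)

    __radd__ = __add__

    def __mul__(self, other):
        return mul(self, other)

    __rmul__ = __mul__

    def __sub__(self, other):
        return sub(self, other)

    def __rsub__(self, other):
        return sub(other, self)

    def __truediv__(self, other):
        return div(self, other)

    def __neg__(self):
        return mul(self, -1.0)

    # -- backward pass -------------------------------------------------
    def backward(self) -> None:
        """Accumulate gradients of ``self`` (summed to a scalar seed)
        into every reachable tensor with ``requires_grad``."""
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:
            node, expanded = stack.pop()
            if expanded:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                if id(p) not in seen:
                    stack.append((p, False))
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)


# ---------------------------------------------------------------------
# graph plumbing
# ---------------------------------------------------------------------

def _as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(np.asarray(x))


def _as_pair(a, b) -> tuple[Tensor, Tensor]:
    """Wrap operands; python scalars adopt the other operand's dtype so
    float32 graphs are not silently promoted to float64."""
    if isinstance(a, Tensor) and isinstance(b, (int, float)):
        return a, Tensor(np.asarray(b, dtype=a.data.dtype))
    if isinstance(b, Tensor) and isinstance(a, (int, float)):
        return Tensor(np.asarray(a, dtype=b.data.dtype)), b
    return _as_tensor(a), _as_tensor(b)


def _tracked(*tensors: Tensor) -> bool:
    if not _GRAD_ENABLED:
        return False
    return any(t.requires_grad or t._parents for t in tensors)


def _make(data, parents, backward_fn) -> Tensor:
    out = Tensor(data)
    if _tracked(*parents):
        out.requires_grad = True
        out._parents = tuple(parents)
        out._backward = backward_fn
    return out


def _accum(t: Tensor, g: np.ndarray) -> None:
    # grad buffers are never mutated in place (accumulation rebinds), so
    # storing the producer's array directly is safe and saves a copy
    if not (t.requires_grad or t._parents):
        return
    if t.grad is None:
        t.grad = g if isinstance(g, np.ndarray) else np.asarray(g)
    else:
        t.grad = t.grad + g


def _unbroadcast(g: np.ndarray, shape: tuple) -> np.ndarray:
    """Reduce a broadcast gradient back to ``shape``."""
    if g.shape == shape:
        return g
    extra = g.ndim - len(shape)
    if extra > 0:
        g = g.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and g.shape[i] != 1)
    if axes:
        g = g.sum(axis=axes, keepdims=True)
    return g


# ---------------------------------------------------------------------
# elementwise / arithmetic ops
# ---------------------------------------------------------------------

def add(a, b) -> Tensor:
    a, b = _as_pair(a, b)
    data = a.data + b.data

    def bw(g):
        _accum(a, _unbroadcast(g, a.data.shape))
        _accum(b, _unbroadcast(g, b.data.shape))

    return _make(data, (a, b), bw)


def sub(a, b) -> Tensor:
    a, b = _as_pair(a, b)
    data = a.data - b.data

    def bw(g):
        _accum(a, _unbroadcast(g, a.data.shape))
        _accum(b, _unbroadcast(-g, b.data.shape))

    return _make(data, (a, b), bw)


def mul(a, b) -> Tensor:
    a, b = _as_pair(a, b)
    data = a.data * b.data

    def bw(g):
        _accum(a, _unbroadcast(g * b.data, a.data.shape))
        _accum(b, _unbroadcast(g * a.data, b.data.shape))

    return _make(data, (a, b), bw)


def div(a, b) -> Tensor:
    a, b = _as_pair(a, b)
    data = a.data / b.data

    def bw(g):
        _accum(a, _unbroadcast(g / b.data, a.data.shape))
        _accum(b, _unbroadcast(-g * a.data / (b.data * b.data), b.data.shape))

    return _make(data, (a, b), bw)


def log(a) -> Tensor:
    a = _as_tensor(a)
    data = np.log(a.data)

    def bw(g):
        _accum(a, g / a.data)

    return _make(data, (a,), bw)


def sqrt(a) -> Tensor:
    a = _as_tensor(a)
    data = np.sqrt(a.data)

    def bw(g):
        _accum(a, g * (0.5 / data))

    return _make(data, (a,), bw)


def relu(a) -> Tensor:
    a = _as_tensor(a)
    data = np.maximum(a.data, 0)

    def bw(g):
        _accum(a, g * (a.data > 0))

    return _make(data, (a,), bw)


def clip_min(a, lo: float) -> Tensor:
    """max(a, lo); gradient passes only where a > lo."""
    a = _as_tensor(a)
    data = np.maximum(a.data, lo)

    def bw(g):
        _accum(a, g * (a.data > lo))

    return _make(data, (a,), bw)


# ---------------------------------------------------------------------
# reductions
# ---------------------------------------------------------------------

def sum_(a, axis=None, keepdims: bool = False) -> Tensor:
    a = _as_tensor(a)
    data = a.data.sum(axis=axis, keepdims=keepdims)

    def bw(g):
        gg = g
        if not keepdims and axis is not None:
            gg = np.expand_dims(gg, axis)
        _accum(a, np.broadcast_to(gg, a.data.shape).astype(a.data.dtype, copy=False))

    return _make(data, (a,), bw)


def mean(a, axis=None, keepdims: bool = False) -> Tensor:
    a = _as_tensor(a)
    data = a.data.mean(axis=axis, keepdims=keepdims)
    if axis is None:
        n = a.data.size
    else:
        axes = (axis,) if isinstance(axis, int) else axis
        n = 1
        for ax in axes:
            n *= a.data.shape[ax]

    def bw(g):
        gg = g
        if not keepdims and axis is not None:
            gg = np.expand_dims(gg, axis)
        _accum(a, (np.broadcast_to(gg, a.data.shape) / n).astype(a.data.dtype, copy=False))

    return _make(data, (a,), bw)


def amax(a, axis: int, keepdims: bool = False) -> Tensor:
    """Max over one axis; gradient routed to the first argmax (ties broken
    toward the lowest index, matching ``np.argmax``)."""
    a = _as_tensor(a)
    data = a.data.max(axis=axis, keepdims=keepdims)
    idx = np.argmax(a.data, axis=axis)

    def bw(g):
        gg = g if keepdims else np.expand_dims(g, axis)
        out = np.zeros_like(a.data)
        np.put_along_axis(out, np.expand_dims(idx, axis), gg, axis=axis)
        _accum(a, out)

    return _make(data, (a,), bw)


def softmax(a, axis: int = -1) -> Tensor:
    a = _as_tensor(a)
    z = a.data - a.data.max(axis=axis, keepdims=True)
    e = np.exp(z)
    s = e / e.sum(axis=axis, keepdims=True)

    def bw(g):
        dot = (g * s).sum(axis=axis, keepdims=True)
        _accum(a, (g - dot) * s)

    return _make(s, (a,), bw)


# ---------------------------------------------------------------------
# shape ops
# ---------------------------------------------------------------------

def reshape(a, shape) -> Tensor:
    a = _as_tensor(a)
    data = a.data.reshape(shape)

    def bw(g):
        _accum(a, g.reshape(a.data.shape))

    return _make(data, (a,), bw)


def concat(tensors, axis: int = -1) -> Tensor:
    tensors = [_as_tensor(t) for t in tensors]
    data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.data.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def bw(g):
        for t, piece in zip(tensors, np.split(g, splits, axis=axis)):
            _accum(t, piece)

    return _make(data, tuple(tensors), bw)


def gather_labels(p, labels) -> Tensor:
    """p[i, labels[i]] for a (B, C) tensor and integer labels (B,)."""
    p = _as_tensor(p)
    labels = np.asarray(labels)
    rows = np.arange(p.data.shape[0])
    data = p.data[rows, labels]

    def bw(g):
        out = np.zeros_like(p.data)
        out[rows, labels] = g
        _accum(p, out)

    return _make(data, (p,), bw)


def batchnorm(x, gamma, beta, eps: float = 1e-5):
    """Fused training-mode batch normalisation over axes (0, 2).

    x is (B, C, T); gamma/beta are (C,).  Returns (y, mean, var) where
    mean/var are the plain per-channel batch statistics (for running
    averages).  The closed-form backward avoids the ~10 elementwise
    graph nodes of the composite formulation.
    """
    x, gamma, beta = _as_tensor(x), _as_tensor(gamma), _as_tensor(beta)
    mu = x.data.mean(axis=(0, 2), keepdims=True)
    d = x.data - mu
    var = np.mean(d * d, axis=(0, 2), keepdims=True)
    inv = 1.0 / np.sqrt(var + np.asarray(eps, dtype=x.data.dtype))
    xhat = d * inv
    g3 = gamma.data.reshape(1, -1, 1)
    y = g3 * xhat + beta.data.reshape(1, -1, 1)

    def bw(g):
        _accum(beta, g.sum(axis=(0, 2)))
        gx = g * xhat
        _accum(gamma, gx.sum(axis=(0, 2)))
        if x.requires_grad or x._parents:
            t1 = g.mean(axis=(0, 2), keepdims=True)
            t2 = gx.mean(axis=(0, 2), keepdims=True)
            _accum(x, (g3 * inv) * (g - t1 - xhat * t2))

    out = _make(y, (x, gamma, beta), bw)
    return out, mu.reshape(-1), var.reshape(-1)


# ---------------------------------------------------------------------
# linear algebra / convolution
# ---------------------------------------------------------------------

def matmul(a, b) -> Tensor:
    a, b = _as_tensor(a), _as_tensor(b)
    data = a.data @ b.data

    def bw(g):
        _accum(a, g @ b.data.T)
        _accum(b, a.data.T @ g)

    return _make(data, (a, b), bw)


def linear(x, w, b) -> Tensor:
    """x (B, F) @ w (F, O) + b (O,)."""
    return add(matmul(x, w), b)


def conv1d(x, w, b, stride: int = 1, pad: int = 0) -> Tensor:
    """1-d cross-correlation: x (B, Cin, T), w (Cout, Cin, k), b (Cout,).

    Lowered to an im2col matmul so both passes run on BLAS.
    """
    x, w, b = _as_tensor(x), _as_tensor(w), _as_tensor(b)
    B, Cin, T = x.data.shape
    Cout, Cin_w, k = w.data.shape
    if Cin_w != Cin:
        raise ValueError(f"conv1d channel mismatch: input {Cin}, weight {Cin_w}")
    if pad:
        xp = np.zeros((B, Cin, T + 2 * pad), dtype=x.data.dtype)
        xp[:, :, pad:pad + T] = x.data
    else:
        xp = x.data
    Tp = xp.shape[2]
    To = (Tp - k) // stride + 1
    if To < 1:
        raise ValueError("conv1d: input shorter than kernel")
    win = np.lib.stride_tricks.sliding_window_view(xp, k, axis=2)[:, :, ::stride, :]
    cols = np.ascontiguousarray(win.transpose(0, 2, 1, 3)).reshape(B * To, Cin * k)
    wm = w.data.reshape(Cout, Cin * k)
    out = cols @ wm.T + b.data
    data = out.reshape(B, To, Cout).transpose(0, 2, 1)

    def bw(g):
        gm = np.ascontiguousarray(g.transpose(0, 2, 1)).reshape(B * To, Cout)
        _accum(w, (gm.T @ cols).reshape(Cout, Cin, k))
        _accum(b, gm.sum(axis=0))
        if x.requires_grad or x._parents:
            # scatter in (B, T, Cin) layout: the per-offset slices are
            # then nearly contiguous, transpose back once at the end
            dcols = (gm @ wm).reshape(B, To, Cin, k)
            dxp_t = np.zeros((B, Tp, Cin), dtype=g.dtype)
            for j in range(k):
                dxp_t[:, j:j + stride * To:stride, :] += dcols[:, :, :, j]
            dxp = np.ascontiguousarray(dxp_t.transpose(0, 2, 1))
            _accum(x, dxp[:, :, pad:Tp - pad] if pad else dxp)

    return _make(data, (x, w, b), bw)
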