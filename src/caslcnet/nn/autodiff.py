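"""Minimal reverse-mode automatic differentiation over numpy arrays.

The package needs gradients with respect to both network parameters (training)
and network inputs (gradient-based attacks).  This module provides a small
dynamic computation graph: a :class:`Tensor` wraps an ``ndarray``; operations
record closures that propagate adjoints.  Only the primitives the models and
attacks actually use are implemented: broadcasting arithmetic, matmul,
reductions, leaky rectifiers, a stabilised log-sum-exp, strided 1-D
convolution, column gathering, and p-norm / l-infinity distance layers.

All arithmetic is float64; graphs are built eagerly and freed after
``backward``.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Tensor",
    "as_tensor",
    "add",
    "mul",
    "matmul",
    "conv1d",
    "pnorm_dist",
    "gather_cols",
    "logsumexp",
    "softmax",
    "log_softmax",
]


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` to undo numpy broadcasting."""
    if grad.shape == shape:
        return grad
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, n in enumerate(shape) if n == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad


class Tensor:
    """A node in the computation graph holding a float64 array."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._backward = None
        self._parents: tuple = ()

    # -- graph bookkeeping -------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def detach(self) -> "Tensor":
        return Tensor(self.data.copy())

    def zero_grad(self):
        self.grad = None

    def _accumulate(self, g: np.ndarray):
        # grads are never mutated in place, so aliasing the incoming array is safe
        self.grad = g if self.grad is None else self.grad + g

    def backward(self, grad: np.ndarray | None = None):
        """Reverse sweep from this node; seeds with ones if no grad given."""
        topo: list[Tensor] = []
        seen = set()
        stack = [(self, False)]
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
                if id(p) not in seen:
                    stack.append((p, False))
        if grad is None:
            grad = np.ones_like(self.data)
        self.grad = np.asarray(grad, dtype=np.float64)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)
            # free graph references as we go
            node._backward = None
            node._parents = ()

    # -- operator sugar ----------------------------------------------------
    def __add__(self, other):
        return add(self, other)

    __radd__ = __add__

    def __mul__(self, other):
        return mul(self, other)

    __rmul__ = __mul__

    def __neg__(self):
        return mul(self, -1.0)

    def __sub__(self, other):
        return add(self, mul(as_tensor(other), -1.0))

    def __rsub__(self, other):
        return add(as_tensor(other), mul(self, -1.0))

    def __truediv__(self, other):
        other = as_tensor(other)
        return mul(self, power(other, -1.0))

    def __rtruediv__(self, other):
        return mul(as_tensor(other), power(self, -1.0))

    def __matmul__(self, other):
        return matmul(self, other)

    def __pow__(self, exponent):
        return power(self, exponent)

    def sum(self, axis=None, keepdims=False):
        return tsum(self, axis=axis, keepdims=keepdims)

    def mean(self, axis=None, keepdims=False):
        return tmean(self, axis=axis, keepdims=keepdims)

    def reshape(self, *shape):
        return reshape(self, shape if len(shape) > 1 else shape[0])

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def _make(data, parents, backward) -> Tensor:
    out = Tensor(data)
    if any(p.requires_grad or p._parents for p in parents):
        out.requires_grad = any(p.requires_grad for p in parents)
        out._parents = tuple(parents)
        out._backward = backward
    return out


def _needs(t: Tensor) -> bool:
    return t.requires_grad or bool(t._parents)


# -- elementwise arithmetic ----------------------------------------------


def add(a, b) -> Tensor:
    a, b = as_tensor(a), as_tensor(b)
    data = a.data + b.data

    def backward(g):
        if _needs(a):
            a._accumulate(_unbroadcast(g, a.data.shape))
        if _needs(b):
            b._accumulate(_unbroadcast(g, b.data.shape))

    return _make(data, (a, b), backward)


def mul(a, b) -> Tensor:
    a, b = as_tensor(a), as_tensor(b)
    data = a.data * b.data

    def backward(g):
        if _needs(a):
            a._accumulate(_unbroadcast(g * b.data, a.data.shape))
        if _needs(b):
            b._accumulate(_unbroadcast(g * a.data, b.data.shape))

    return _make(data, (a, b), backward)


def power(a, exponent: float) -> Tensor:
    a = as_tensor(a)
    data = a.data ** exponent

    def backward(g):
        if _needs(a):
            a._accumulate(g * exponent * a.data ** (exponent - 1.0))

    return _make(data, (a,), backward)


def exp(a) -> Tensor:
    a = as_tensor(a)
    data = np.exp(a.data)

    def backward(g):
        if _needs(a):
            a._accumulate(g * data)

    return _make(data, (a,), backward)


def log(a) -> Tensor:
    a = as_tensor(a)
    data = np.log(a.data)

    def backward(g):
        if _needs(a):
            a._accumulate(g / a.data)

    return _make(data, (a,), backward)


def sqrt(a) -> Tensor:
    return power(a, 0.5)


def tanh(a) -> Tensor:
    a = as_tensor(a)
    data = np.tanh(a.data)

    def backward(g):
        if _needs(a):
            a._accumulate(g * (1.0 - data * data))

    return _make(data, (a,), backward)


def clip_floor(a, floor: float) -> Tensor:
    """Elementwise max(a, floor); gradient flows only where a > floor."""
    a = as_tensor(a)
    data = np.maximum(a.data, floor)
    pass_mask = a.data > floor

    def backward(g):
        if _needs(a):
            a._accumulate(g * pass_mask)

    return _make(data, (a,), backward)


def leaky_relu(a, slope: float = 0.01) -> Tensor:
    a = as_tensor(a)
    pos = a.data > 0
    data = np.where(pos, a.data, slope * a.data)

    def backward(g):
        if _needs(a):
            a._accumulate(g * np.where(pos, 1.0, slope))

    return _make(data, (a,), backward)


def relu(a) -> Tensor:
    return clip_floor(a, 0.0)


# -- shape ops ------------------------------------------------------------


def reshape(a, shape) -> Tensor:
    a = as_tensor(a)
    old = a.data.shape
    data = a.data.reshape(shape)

    def backward(g):
        if _needs(a):
            a._accumulate(g.reshape(old))

    return _make(data, (a,), backward)


def tsum(a, axis=None, keepdims=False) -> Tensor:
    a = as_tensor(a)
    data = a.data.sum(axis=axis, keepdims=keepdims)

    def backward(g):
        if _needs(a):
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            a._accumulate(np.broadcast_to(g, a.data.shape).copy())

    return _make(data, (a,), backward)


def tmean(a, axis=None, keepdims=False) -> Tensor:
    a = as_tensor(a)
    n = a.data.size if axis is None else np.prod(
        [a.data.shape[ax] for ax in (axis if isinstance(axis, tuple) else (axis,))]
    )
    return mul(tsum(a, axis=axis, keepdims=keepdims), 1.0 / float(n))


def matmul(a, b) -> Tensor:
    a, b = as_tensor(a), as_tensor(b)
    data = a.data @ b.data

    def backward(g):
        if _needs(a):
            ga = g @ np.swapaxes(b.data, -1, -2)
            a._accumulate(_unbroadcast(ga, a.data.shape))
        if _needs(b):
            gb = np.swapaxes(a.data, -1, -2) @ g
            b._accumulate(_unbroadcast(gb, b.data.shape))

    return _make(data, (a, b), backward)


# -- softmax family -------------------------------------------------------


def logsumexp(a, axis: int = -1) -> Tensor:
    a = as_tensor(a)
    m = np.max(a.data, axis=axis, keepdims=True)
    s = np.exp(a.data - m).sum(axis=axis, keepdims=True)
    data = np.squeeze(m + np.log(s), axis=axis)
    soft = np.exp(a.data - m) / s

    def backward(g):
        if _needs(a):
            a._accumulate(np.expand_dims(g, axis) * soft)

    return _make(data, (a,), backward)


def log_softmax(a, axis: int = -1) -> Tensor:
    a = as_tensor(a)
    lse = logsumexp(a, axis=axis)
    return a - expand_dims(lse, axis)


def softmax(a, axis: int = -1) -> Tensor:
    return exp(log_softmax(a, axis=axis))


def expand_dims(a, axis: int) -> Tensor:
    a = as_tensor(a)
    data = np.expand_dims(a.data, axis)

    def backward(g):
        if _needs(a):
            a._accumulate(np.squeeze(g, axis=axis))

    return _make(data, (a,), backward)


# -- gather ---------------------------------------------------------------


def gather_cols(h, idx) -> Tensor:
    """Select one column of ``h`` [C, M] per row index: out[n, :] = h[:, idx[n]]."""
    h = as_tensor(h)
    idx = np.asarray(idx, dtype=np.intp)
    data = h.data[:, idx].T

    def backward(g):
        if _needs(h):
            gh = np.zeros_like(h.data)
            np.add.at(gh.T, idx, g)
            h._accumulate(gh)

    return _make(data, (h,), backward)


def gather_rows_at(a, idx) -> Tensor:
    """out[n] = a[n, idx[n]] for a 2-D tensor (per-sample class pick)."""
    a = as_tensor(a)
    idx = np.asarray(idx, dtype=np.intp)
    rows = np.arange(a.data.shape[0])
    data = a.data[rows, idx]

    def backward(g):
        if _needs(a):
            ga = np.zeros_like(a.data)
            np.add.at(ga, (rows, idx), g)
            a._accumulate(ga)

    return _make(data, (a,), backward)


# -- convolution ----------------------------------------------------------


def conv1d(x, w, b=None, stride: int = 1, padding: int = 0) -> Tensor:
    """Strided 1-D convolution (cross-correlation).

    x: [N, C_in, W], w: [C_out, C_in, k], b: [C_out] or None.
    Implemented as a short loop over kernel taps; each tap is a strided
    slice contracted with an einsum, which keeps both passes vectorised.
    """
    x, w = as_tensor(x), as_tensor(w)
    if b is not None:
        b = as_tensor(b)
    n, cin, width = x.data.shape
    cout, cin_w, k = w.data.shape
    if cin != cin_w:
        raise ValueError(f"conv1d channel mismatch: input {cin}, weight {cin_w}")
    w_out = (width + 2 * padding - k) // stride + 1
    if w_out <= 0:
        raise ValueError(
            f"conv1d output width collapsed to {w_out} "
            f"(input width {width}, kernel {k}, stride {stride}, padding {padding})"
        )
    xp = np.pad(x.data, ((0, 0), (0, 0), (padding, padding))) if padding else x.data
    out = np.zeros((n, cout, w_out))
    for j in range(k):
        sl = xp[:, :, j : j + stride * w_out : stride]
        out += np.einsum("ncw,oc->now", sl, w.data[:, :, j], optimize=True)
    if b is not None:
        out += b.data[None, :, None]

    def backward(g):
        if _needs(x):
            gxp = np.zeros_like(xp)
            for j in range(k):
                gxp[:, :, j : j + stride * w_out : stride] += np.einsum(
                    "now,oc->ncw", g, w.data[:, :, j], optimize=True
                )
            gx = gxp[:, :, padding : padding + width] if padding else gxp
            x._accumulate(gx)
        if _needs(w):
            gw = np.empty_like(w.data)
            for j in range(k):
                sl = xp[:, :, j : j + stride * w_out : stride]
                gw[:, :, j] = np.einsum("now,ncw->oc", g, sl, optimize=True)
            w._accumulate(gw)
        if b is not None and _needs(b):
            b._accumulate(g.sum(axis=(0, 2)))

    parents = (x, w) if b is None else (x, w, b)
    return _make(out, parents, backward)


# -- p-norm / l-inf distance layer ----------------------------------------

_CHUNK = 512


def pnorm_dist(x, w, b, p: float = np.inf) -> Tensor:
    """Distance layer: out[n, u] = ||x[n] - w[u]||_p + b[u].

    ``p=inf`` gives the exact l-infinity distance (subgradient at the first
    maximal coordinate); finite ``p`` is the smooth relaxation used during
    training.  The [N, U, D] difference tensor is processed in batch chunks
    to bound memory.
    """
    x, w, b = as_tensor(x), as_tensor(w), as_tensor(b)
    n, d = x.data.shape
    u, dw = w.data.shape
    if d != dw:
        raise ValueError(f"pnorm_dist width mismatch: input {d}, weights {dw}")
    dist = np.empty((n, u))
    for lo in range(0, n, _CHUNK):
        hi = min(lo + _CHUNK, n)
        diff = np.abs(x.data[lo:hi, None, :] - w.data[None, :, :])
        if np.isinf(p):
            dist[lo:hi] = diff.max(axis=-1)
        else:
            m = np.maximum(diff.max(axis=-1, keepdims=True), 1e-300)
            dist[lo:hi] = m[..., 0] * ((diff / m) ** p).sum(axis=-1) ** (1.0 / p)
    out_data = dist + b.data[None, :]

    def backward(g):
        need_x, need_w = _needs(x), _needs(w)
        gx = np.zeros_like(x.data) if need_x else None
        gw = np.zeros_like(w.data) if need_w else None
        for lo in range(0, n, _CHUNK):
            hi = min(lo + _CHUNK, n)
            delta = x.data[lo:hi, None, :] - w.data[None, :, :]
            adiff = np.abs(delta)
            if np.isinf(p):
                # subgradient concentrated on the first maximal coordinate
                arg = adiff.argmax(axis=-1)
                coef = np.zeros_like(adiff)
                ii, jj = np.meshgrid(
                    np.arange(hi - lo), np.arange(u), indexing="ij"
                )
                coef[ii, jj, arg] = np.sign(delta[ii, jj, arg])
            else:
                dloc = np.maximum(dist[lo:hi][..., None], 1e-300)
                coef = np.sign(delta) * (adiff / dloc) ** (p - 1.0)
            gg = g[lo:hi, :, None] * coef
            if need_x:
                gx[lo:hi] = gg.sum(axis=1)
            if need_w:
                gw -= gg.sum(axis=0)
        if need_x:
            x._accumulate(gx)
        if need_w:
            w._accumulate(gw)
        if _needs(b):
            b._accumulate(g.sum(axis=0))

    return _make(out_data, (x, w, b), backward)
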