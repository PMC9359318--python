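"""Minimal reverse-mode automatic differentiation over numpy arrays.

The moment-propagation formulas in this package are plain algebraic
expressions (matmuls, Hadamard products, exp/log, gathers).  This module
provides a small tape-based :class:`Tensor` so the same formulas can be
differentiated for gradient-descent training of the variational parameters
and for crafting gradient-sign adversarial inputs.  Only the operations the
package actually uses are implemented.

Module-level helpers (:func:`exp`, :func:`log`, ...) dispatch on type: given
a plain ``numpy`` array they call numpy, given a :class:`Tensor` they build
the tape.  Formula code written against these helpers therefore runs
unchanged in both worlds.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Tensor",
    "exp",
    "log",
    "relu",
    "matmul",
    "transpose",
    "reshape",
    "tsum",
    "softmax",
    "pad2d",
    "crop2d",
    "take",
    "select_last",
]


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of numpy broadcasting)."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for axis, size in enumerate(shape):
        if size == 1 and grad.shape[axis] != 1:
            grad = grad.sum(axis=axis, keepdims=True)
    return grad


class Tensor:
    """A numpy array with a gradient and a backward closure."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    # keep numpy from broadcasting over Tensor objects; reflected ops apply
    __array_ufunc__ = None

    def __init__(self, data, requires_grad=False, _parents=(), _backward=None):
        self.data = np.asarray(data)
        self.grad = None
        self.requires_grad = bool(requires_grad) or any(
            p.requires_grad for p in _parents
        )
        self._parents = _parents
        self._backward = _backward

    # -- infrastructure -------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def detach(self) -> np.ndarray:
        return self.data

    def zero_grad(self):
        self.grad = None

    def _accumulate(self, g):
        if self.grad is None:
            self.grad = np.zeros_like(self.data, dtype=np.result_type(self.data, g))
        self.grad += g

    def backward(self, grad=None):
        if grad is None:
            grad = np.ones_like(self.data)
        topo, seen = [], set()

        def visit(node):
            if id(node) in seen or not node.requires_grad:
                return
            seen.add(id(node))
            for p in node._parents:
                visit(p)
            topo.append(node)

        visit(self)
        self._accumulate(np.asarray(grad))
        for node in reversed(topo):
            if node._backward is not None:
                node._backward(node.grad)

    # -- arithmetic ------------------------------------------------------
    @staticmethod
    def _lift(other):
        return other.data if isinstance(other, Tensor) else np.asarray(other)

    def __add__(self, other):
        a, b = self, other
        bd = Tensor._lift(b)
        parents = (a,) + ((b,) if isinstance(b, Tensor) else ())
        out = Tensor(a.data + bd, _parents=parents)

        def bw(g):
            a._accumulate(_unbroadcast(g, a.shape))
            if isinstance(b, Tensor):
                b._accumulate(_unbroadcast(g, b.shape))

        out._backward = bw
        return out

    __radd__ = __add__

    def __neg__(self):
        out = Tensor(-self.data, _parents=(self,))
        out._backward = lambda g: self._accumulate(-g)
        return out

    def __sub__(self, other):
        return self + (-other if isinstance(other, Tensor) else -np.asarray(other))

    def __rsub__(self, other):
        return (-self) + other

    def __mul__(self, other):
        a, b = self, other
        bd = Tensor._lift(b)
        parents = (a,) + ((b,) if isinstance(b, Tensor) else ())
        out = Tensor(a.data * bd, _parents=parents)

        def bw(g):
            a._accumulate(_unbroadcast(g * bd, a.shape))
            if isinstance(b, Tensor):
                b._accumulate(_unbroadcast(g * a.data, b.shape))

        out._backward = bw
        return out

    __rmul__ = __mul__

    def __truediv__(self, other):
        a, b = self, other
        bd = Tensor._lift(b)
        parents = (a,) + ((b,) if isinstance(b, Tensor) else ())
        out = Tensor(a.data / bd, _parents=parents)

        def bw(g):
            a._accumulate(_unbroadcast(g / bd, a.shape))
            if isinstance(b, Tensor):
                b._accumulate(_unbroadcast(-g * a.data / (bd * bd), b.shape))

        out._backward = bw
        return out

    def __rtruediv__(self, other):
        od = np.asarray(other)
        out = Tensor(od / self.data, _parents=(self,))
        out._backward = lambda g: self._accumulate(
            _unbroadcast(-g * od / (self.data * self.data), self.shape)
        )
        return out

    def __pow__(self, p: float):
        out = Tensor(self.data**p, _parents=(self,))
        out._backward = lambda g: self._accumulate(g * p * self.data ** (p - 1))
        return out

    def __matmul__(self, other):
        return matmul(self, other)


# -- dispatched helpers --------------------------------------------------


def exp(x):
    if not isinstance(x, Tensor):
        return np.exp(x)
    out = Tensor(np.exp(x.data), _parents=(x,))
    out._backward = lambda g: x._accumulate(g * out.data)
    return out


def log(x):
    if not isinstance(x, Tensor):
        return np.log(x)
    out = Tensor(np.log(x.data), _parents=(x,))
    out._backward = lambda g: x._accumulate(g / x.data)
    return out


def relu(x):
    if not isinstance(x, Tensor):
        return np.maximum(x, 0.0)
    mask = x.data > 0
    out = Tensor(np.where(mask, x.data, 0.0), _parents=(x,))
    out._backward = lambda g: x._accumulate(g * mask)
    return out


def matmul(a, b):
    if not isinstance(a, Tensor) and not isinstance(b, Tensor):
        return a @ b
    a_t, b_t = isinstance(a, Tensor), isinstance(b, Tensor)
    ad = a.data if a_t else np.asarray(a)
    bd = b.data if b_t else np.asarray(b)
    parents = tuple(t for t in (a, b) if isinstance(t, Tensor))
    out = Tensor(ad @ bd, _parents=parents)

    def bw(g):
        if a_t:
            ga = g @ np.swapaxes(bd, -1, -2) if bd.ndim > 1 else np.outer(g, bd).reshape(ad.shape)
            a._accumulate(_unbroadcast(ga, ad.shape))
        if b_t:
            gb = np.swapaxes(ad, -1, -2) @ g if ad.ndim > 1 else np.outer(ad, g)
            b._accumulate(_unbroadcast(gb, bd.shape))

    out._backward = bw
    return out


def transpose(x, axes=None):
    if not isinstance(x, Tensor):
        return np.transpose(x, axes)
    out = Tensor(np.transpose(x.data, axes), _parents=(x,))
    inv = None if axes is None else np.argsort(axes)
    out._backward = lambda g: x._accumulate(np.transpose(g, inv))
    return out


def reshape(x, shape):
    if not isinstance(x, Tensor):
        return np.reshape(x, shape)
    old = x.shape
    out = Tensor(x.data.reshape(shape), _parents=(x,))
    out._backward = lambda g: x._accumulate(g.reshape(old))
    return out


def tsum(x, axis=None, keepdims=False):
    """Sum (named to avoid shadowing the builtin)."""
    if not isinstance(x, Tensor):
        return np.sum(x, axis=axis, keepdims=keepdims)
    out = Tensor(x.data.sum(axis=axis, keepdims=keepdims), _parents=(x,))

    def bw(g):
        if axis is not None and not keepdims:
            g = np.expand_dims(g, axis)
        x._accumulate(np.broadcast_to(g, x.shape).copy())

    out._backward = bw
    return out


def softmax(x, axis=-1):
    """Numerically stable softmax; the max-shift is treated as a constant."""
    xd = x.data if isinstance(x, Tensor) else x
    shift = xd.max(axis=axis, keepdims=True)
    e = exp(x - shift)
    return e / tsum(e, axis=axis, keepdims=True)


def pad2d(x, pad: int):
    """Zero-pad the last two axes."""
    if pad == 0:
        return x
    width = [(0, 0)] * (x.ndim - 2) + [(pad, pad), (pad, pad)]
    if not isinstance(x, Tensor):
        return np.pad(x, width)
    out = Tensor(np.pad(x.data, width), _parents=(x,))
    sl = (Ellipsis, slice(pad, -pad), slice(pad, -pad))
    out._backward = lambda g: x._accumulate(g[sl])
    return out


def crop2d(x, height: int, width: int):
    """Keep the leading ``height`` x ``width`` window of the last two axes."""
    sl = (Ellipsis, slice(0, height), slice(0, width))
    if not isinstance(x, Tensor):
        return x[sl]
    out = Tensor(x.data[sl], _parents=(x,))

    def bw(g):
        buf = np.zeros_like(x.data)
        buf[sl] = g
        x._accumulate(buf)

    out._backward = bw
    return out


def take(x, idx: np.ndarray):
    """Gather from the flattened array; output has ``idx``'s shape."""
    if not isinstance(x, Tensor):
        return np.reshape(x, -1)[idx]
    out = Tensor(x.data.reshape(-1)[idx], _parents=(x,))

    def bw(g):
        # bincount is much faster than np.add.at for dense scatters
        buf = np.bincount(
            idx.reshape(-1), weights=g.reshape(-1).astype(np.float64), minlength=x.data.size
        )
        x._accumulate(buf.astype(g.dtype).reshape(x.shape))

    out._backward = bw
    return out


def select_last(x, idx: np.ndarray):
    """Pick one element along the last axis per leading index (argmax gather)."""
    if not isinstance(x, Tensor):
        return np.take_along_axis(x, idx[..., None], axis=-1)[..., 0]
    out = Tensor(
        np.take_along_axis(x.data, idx[..., None], axis=-1)[..., 0], _parents=(x,)
    )

    def bw(g):
        buf = np.zeros_like(x.data)
        np.put_along_axis(buf, idx[..., None], g[..., None], axis=-1)
        x._accumulate(buf)

    out._backward = bw
    return out
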