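"""Minimal reverse-mode automatic differentiation on numpy arrays.

Only the operations the CNN + selective-SSM classifier needs are provided.
Gradients flow through a tape of ``Tensor`` nodes; broadcasting follows numpy
semantics with gradients summed back to the parent shape.
"""

from __future__ import annotations

import numpy as np


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    if grad.shape == shape:
        return grad
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad = None
        self.requires_grad = requires_grad
        self._backward = None
        self._parents: tuple[Tensor, ...] = ()

    # -- graph plumbing ----------------------------------------------------
    @staticmethod
    def _make(data, parents, backward):
        out = Tensor(data)
        if any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._parents = tuple(parents)
            out._backward = backward
        return out

    def backward(self, grad=None):
        if grad is None:
            grad = np.ones_like(self.data)
        topo, seen = [], set()

        def visit(t):
            if id(t) in seen or not t.requires_grad:
                return
            seen.add(id(t))
            for p in t._parents:
                visit(p)
            topo.append(t)

        visit(self)
        for t in topo:
            t.grad = None
        self.grad = np.asarray(grad, dtype=np.float64)
        for t in reversed(topo):
            if t._backward is not None and t.grad is not None:
                t._backward(t.grad)

    def _accum(self, g):
        g = _unbroadcast(np.asarray(g), self.data.shape)
        self.grad = g if self.grad is None else self.grad + g

    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    # -- arithmetic --------------------------------------------------------
    def __add__(self, other):
        o = other if isinstance(other, Tensor) else Tensor(other)

        def bw(g):
            self._accum(g)
            o._accum(g)
        return Tensor._make(self.data + o.data, (self, o), bw)

    __radd__ = __add__

    def __neg__(self):
        def bw(g):
            self._accum(-g)
        return Tensor._make(-self.data, (self,), bw)

    def __sub__(self, other):
        o = other if isinstance(other, Tensor) else Tensor(other)

        def bw(g):
            self._accum(g)
            o._accum(-g)
        return Tensor._make(self.data - o.data, (self, o), bw)

    def __rsub__(self, other):
        return Tensor(other) - self

    def __mul__(self, other):
        o = other if isinstance(other, Tensor) else Tensor(other)

        def bw(g):
            self._accum(g * o.data)
            o._accum(g * self.data)
        return Tensor._make(self.data * o.data, (self, o), bw)

    __rmul__ = __mul__

    def __truediv__(self, other):
        o = other if isinstance(other, Tensor) else Tensor(other)

        def bw(g):
            self._accum(g / o.data)
            o._accum(-g * self.data / (o.data ** 2))
        return Tensor._make(self.data / o.data, (self, o), bw)

    def __rtruediv__(self, other):
        return Tensor(other) / self

    def __pow__(self, p: float):
        def bw(g):
            self._accum(g * p * self.data ** (p - 1))
        return Tensor._make(self.data ** p, (self,), bw)

    def __matmul__(self, other):
        o = other if isinstance(other, Tensor) else Tensor(other)
        out = np.matmul(self.data, o.data)

        def bw(g):
            a, b = self.data, o.data
            ga = np.matmul(g, np.swapaxes(b, -1, -2))
            gb = np.matmul(np.swapaxes(a, -1, -2), g)
            self._accum(_unbroadcast(ga, a.shape))
            o._accum(_unbroadcast(gb, b.shape))
        return Tensor._make(out, (self, o), bw)

    # -- elementwise nonlinearities ---------------------------------------
    def exp(self):
        out = np.exp(self.data)

        def bw(g):
            self._accum(g * out)
        return Tensor._make(out, (self,), bw)

    def log(self):
        def bw(g):
            self._accum(g / self.data)
        return Tensor._make(np.log(self.data), (self,), bw)

    def tanh(self):
        out = np.tanh(self.data)

        def bw(g):
            self._accum(g * (1.0 - out ** 2))
        return Tensor._make(out, (self,), bw)

    def sigmoid(self):
        out = 1.0 / (1.0 + np.exp(-np.clip(self.data, -60, 60)))

        def bw(g):
            self._accum(g * out * (1.0 - out))
        return Tensor._make(out, (self,), bw)

    def softplus(self):
        """Overflow-safe log(1 + e^x)."""
        z = self.data
        out = np.maximum(z, 0.0) + np.log1p(np.exp(-np.abs(z)))
        sig = 1.0 / (1.0 + np.exp(-np.clip(z, -60, 60)))

        def bw(g):
            self._accum(g * sig)
        return Tensor._make(out, (self,), bw)

    def sqrt(self):
        out = np.sqrt(self.data)

        def bw(g):
            self._accum(g * 0.5 / out)
        return Tensor._make(out, (self,), bw)

    # -- reductions / shape ------------------------------------------------
    def sum(self, axis=None, keepdims=False):
        out = self.data.sum(axis=axis, keepdims=keepdims)

        def bw(g):
            gg = np.asarray(g)
            if axis is not None and not keepdims:
                gg = np.expand_dims(gg, axis)
            self._accum(np.broadcast_to(gg, self.data.shape))
        return Tensor._make(out, (self,), bw)

    def mean(self, axis=None, keepdims=False):
        n = self.data.size if axis is None else np.prod(
            [self.data.shape[a] for a in np.atleast_1d(axis)])
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(n))

    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        old = self.data.shape

        def bw(g):
            self._accum(np.asarray(g).reshape(old))
        return Tensor._make(self.data.reshape(shape), (self,), bw)

    def transpose(self, axes):
        inv = np.argsort(axes)

        def bw(g):
            self._accum(np.transpose(np.asarray(g), inv))
        return Tensor._make(np.transpose(self.data, axes), (self,), bw)

    def __getitem__(self, idx):
        def bw(g):
            full = np.zeros_like(self.data)
            np.add.at(full, idx, g)
            self._accum(full)
        return Tensor._make(self.data[idx], (self,), bw)

    def pad(self, pad_width):
        """Zero padding; ``pad_width`` as for ``np.pad``."""
        slices = tuple(slice(a, a + s) for (a, _), s in
                       zip(pad_width, self.data.shape))

        def bw(g):
            self._accum(np.asarray(g)[slices])
        return Tensor._make(np.pad(self.data, pad_width), (self,), bw)


def concatenate(tensors, axis=0):
    datas = [t.data for t in tensors]
    out = np.concatenate(datas, axis=axis)
    sizes = [d.shape[axis] for d in datas]
    offsets = np.cumsum([0] + sizes)

    def bw(g):
        g = np.asarray(g)
        for t, a, b in zip(tensors, offsets[:-1], offsets[1:]):
            sl = [slice(None)] * g.ndim
            sl[axis] = slice(a, b)
            t._accum(g[tuple(sl)])
    return Tensor._make(out, tuple(tensors), bw)


def stack_detached(x) -> np.ndarray:
    return x.data if isinstance(x, Tensor) else np.asarray(x)
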