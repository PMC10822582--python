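"""Minimal reverse-mode automatic differentiation over numpy arrays.

Supports exactly the operations the tagging and linking networks need:
broadcast arithmetic, (batched) matmul, relu, log-softmax, reductions,
row gathering for embeddings, concatenation, reshape/transpose, layer
normalisation, and Adam. Gradients are checked against central finite
differences in the test suite.
"""

from __future__ import annotations

import math
from typing import Callable, Iterable, Sequence

import numpy as np

__all__ = [
    "Tensor",
    "concat",
    "gather_rows",
    "Adam",
    "Linear",
    "Embedding",
    "LayerNorm",
]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of numpy broadcasting)."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, size in enumerate(shape):
        if size == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(
        self,
        data,
        requires_grad: bool = False,
        parents: tuple = (),
        backward: Callable[[np.ndarray], None] | None = None,
    ):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad
        self._parents = parents
        self._backward = backward

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    # --- graph construction -------------------------------------------------

    @staticmethod
    def _lift(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(x)

    def _make(self, data, parents, backward) -> "Tensor":
        rg = any(p.requires_grad or p._parents for p in parents)
        return Tensor(data, requires_grad=False, parents=parents if rg else (),
                      backward=backward if rg else None)

    def __add__(self, other):
        other = self._lift(other)

        def backward(g):
            _accum(self, _unbroadcast(g, self.data.shape))
            _accum(other, _unbroadcast(g, other.data.shape))

        return self._make(self.data + other.data, (self, other), backward)

    __radd__ = __add__

    def __neg__(self):
        def backward(g):
            _accum(self, -g)

        return self._make(-self.data, (self,), backward)

    def __sub__(self, other):
        return self + (-self._lift(other))

    def __rsub__(self, other):
        return self._lift(other) + (-self)

    def __mul__(self, other):
        other = self._lift(other)

        def backward(g):
            _accum(self, _unbroadcast(g * other.data, self.data.shape))
            _accum(other, _unbroadcast(g * self.data, other.data.shape))

        return self._make(self.data * other.data, (self, other), backward)

    __rmul__ = __mul__

    def __truediv__(self, other):
        return self * self._lift(other).pow(-1.0)

    def pow(self, exponent: float):
        def backward(g):
            _accum(self, g * exponent * self.data ** (exponent - 1.0))

        return self._make(self.data**exponent, (self,), backward)

    def matmul(self, other: "Tensor"):
        other = self._lift(other)

        def backward(g):
            ga = g @ np.swapaxes(other.data, -1, -2)
            gb = np.swapaxes(self.data, -1, -2) @ g
            _accum(self, _unbroadcast(ga, self.data.shape))
            _accum(other, _unbroadcast(gb, other.data.shape))

        return self._make(self.data @ other.data, (self, other), backward)

    __matmul__ = matmul

    def relu(self):
        mask = self.data > 0

        def backward(g):
            _accum(self, g * mask)

        return self._make(self.data * mask, (self,), backward)

    def exp(self):
        out_data = np.exp(self.data)

        def backward(g):
            _accum(self, g * out_data)

        return self._make(out_data, (self,), backward)

    def log(self):
        def backward(g):
            _accum(self, g / self.data)

        return self._make(np.log(self.data), (self,), backward)

    def sum(self, axis=None, keepdims: bool = False):
        def backward(g):
            if axis is None:
                _accum(self, np.broadcast_to(g, self.data.shape).copy())
            else:
                gg = g if keepdims else np.expand_dims(g, axis)
                _accum(self, np.broadcast_to(gg, self.data.shape).copy())

        return self._make(
            self.data.sum(axis=axis, keepdims=keepdims), (self,), backward
        )

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def reshape(self, *shape):
        def backward(g):
            _accum(self, g.reshape(self.data.shape))

        return self._make(self.data.reshape(*shape), (self,), backward)

    def transpose(self, *axes):
        inverse = np.argsort(axes)

        def backward(g):
            _accum(self, g.transpose(*inverse))

        return self._make(self.data.transpose(*axes), (self,), backward)

    def log_softmax(self, axis: int = -1):
        x = self.data
        m = x.max(axis=axis, keepdims=True)
        lse = m + np.log(np.exp(x - m).sum(axis=axis, keepdims=True))
        out_data = x - lse
        soft = np.exp(out_data)

        def backward(g):
            _accum(self, g - soft * g.sum(axis=axis, keepdims=True))

        return self._make(out_data, (self,), backward)

    def softmax(self, axis: int = -1):
        return self.log_softmax(axis=axis).exp()

    def take_rows(self, indices: np.ndarray):
        """Select rows (axis 0) by integer index, with gradient scatter-add."""
        indices = np.asarray(indices, dtype=np.intp)

        def backward(g):
            full = np.zeros_like(self.data)
            np.add.at(full, indices, g)
            _accum(self, full)

        return self._make(self.data[indices], (self,), backward)

    # --- backprop -----------------------------------------------------------

    def backward(self):
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar loss")
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
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
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    def item(self) -> float:
        return float(self.data)


def _accum(t: Tensor, g: np.ndarray) -> None:
    if not (t.requires_grad or t._parents):
        return
    if t.grad is None:
        t.grad = np.array(g, dtype=np.float64)
    else:
        t.grad = t.grad + g


def concat(tensors: Sequence[Tensor], axis: int = -1) -> Tensor:
    datas = [t.data for t in tensors]
    sizes = [d.shape[axis] for d in datas]
    offsets = np.cumsum([0] + sizes)

    def backward(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            sl = [slice(None)] * g.ndim
            sl[axis if axis >= 0 else g.ndim + axis] = slice(lo, hi)
            _accum(t, g[tuple(sl)])

    out = Tensor(np.concatenate(datas, axis=axis))
    if any(t.requires_grad or t._parents for t in tensors):
        out._parents = tuple(tensors)
        out._backward = backward
    return out


def gather_rows(t: Tensor, indices: np.ndarray) -> Tensor:
    return t.take_rows(indices)


# --- layers -----------------------------------------------------------------


class Linear:
    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator,
                 zero_init: bool = False):
        if zero_init:
            self.W = Tensor(np.zeros((d_in, d_out)), requires_grad=True)
        else:
            scale = math.sqrt(2.0 / (d_in + d_out))
            self.W = Tensor(rng.normal(0.0, scale, (d_in, d_out)), requires_grad=True)
        self.b = Tensor(np.zeros(d_out), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return x @ self.W + self.b

    def parameters(self) -> list[Tensor]:
        return [self.W, self.b]


class Embedding:
    def __init__(self, n: int, d: int, rng: np.random.Generator):
        self.W = Tensor(rng.normal(0.0, 0.02, (n, d)), requires_grad=True)

    def __call__(self, indices: np.ndarray) -> Tensor:
        return self.W.take_rows(indices)

    def parameters(self) -> list[Tensor]:
        return [self.W]


class LayerNorm:
    def __init__(self, d: int, eps: float = 1e-5):
        self.gamma = Tensor(np.ones(d), requires_grad=True)
        self.beta = Tensor(np.zeros(d), requires_grad=True)
        self.eps = eps

    def __call__(self, x: Tensor) -> Tensor:
        mu = x.mean(axis=-1, keepdims=True)
        centred = x - mu
        var = (centred * centred).mean(axis=-1, keepdims=True)
        inv = (var + self.eps).pow(-0.5)
        return centred * inv * self.gamma + self.beta

    def parameters(self) -> list[Tensor]:
        return [self.gamma, self.beta]


class Adam:
    def __init__(self, params: Iterable[Tensor], lr: float = 1e-3,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self) -> None:
        self.t += 1
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1**self.t)
            vhat = self.v[i] / (1 - self.b2**self.t)
            p.data = p.data - self.lr * mhat / (np.sqrt(vhat) + self.eps)
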