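"""Reverse-mode automatic differentiation on NumPy arrays.

A deliberately small tape-based engine sufficient for the models in this
package: dense affine maps, graph/hypergraph message passing (gather and
segment-sum), attention softmax, pooling and binary cross-entropy.  Every
public function dispatches on its argument types — called with plain
``numpy`` arrays it returns an array, called with (or mixed with)
:class:`Tensor` it returns a ``Tensor`` wired into the tape.  This lets the
mathematical operations in the modelling modules be written once and used
both for inference/tests (arrays) and training (tensors).

All data is kept in ``float64``; gradients are accumulated, so parameters
must be zeroed between steps (the optimizer does this).
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Tensor", "as_tensor", "matmul", "add", "sub", "mul", "div", "neg",
    "relu", "sigmoid", "exp", "log", "softplus", "tsum", "tmean",
    "max_over_rows", "concat", "take_rows", "segment_sum", "reshape",
    "AdamW",
]


class Tensor:
    """A node in the computation tape wrapping a float64 ndarray."""

    __slots__ = ("data", "grad", "_parents", "_backward")

    def __init__(self, data, parents=(), backward=None):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self._parents = parents
        self._backward = backward

    @property
    def shape(self):
        return self.data.shape

    def zero_grad(self) -> None:
        self.grad = None

    def backward(self) -> None:
        """Backpropagate from this (scalar) tensor through the tape."""
        if self.data.ndim != 0 and self.data.size != 1:
            raise ValueError("backward() requires a scalar tensor")
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

    # Operator sugar so model code reads naturally.
    def __add__(self, other):
        return add(self, other)

    __radd__ = __add__

    def __sub__(self, other):
        return sub(self, other)

    def __rsub__(self, other):
        return sub(other, self)

    def __mul__(self, other):
        return mul(self, other)

    __rmul__ = __mul__

    def __truediv__(self, other):
        return div(self, other)

    def __neg__(self):
        return neg(self)

    def __matmul__(self, other):
        return matmul(self, other)

    def __rmatmul__(self, other):
        return matmul(other, self)

    def __repr__(self):  # pragma: no cover - debugging aid
        return f"Tensor(shape={self.data.shape})"


def _is_tensor(*xs) -> bool:
    return any(isinstance(x, Tensor) for x in xs)


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def _accum(t: Tensor, g: np.ndarray) -> None:
    if t.grad is None:
        t.grad = np.zeros_like(t.data)
    t.grad += g


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of NumPy broadcasting)."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad.reshape(shape)


# ---------------------------------------------------------------------------
# elementwise / linear algebra


def matmul(a, b):
    if not _is_tensor(a, b):
        return np.asarray(a) @ np.asarray(b)
    a, b = as_tensor(a), as_tensor(b)
    out = Tensor(a.data @ b.data, parents=(a, b))

    def bwd(g):
        _accum(a, g @ b.data.T)
        _accum(b, a.data.T @ g)

    out._backward = bwd
    return out


def add(a, b):
    if not _is_tensor(a, b):
        return np.asarray(a) + np.asarray(b)
    a, b = as_tensor(a), as_tensor(b)
    out = Tensor(a.data + b.data, parents=(a, b))

    def bwd(g):
        _accum(a, _unbroadcast(g, a.data.shape))
        _accum(b, _unbroadcast(g, b.data.shape))

    out._backward = bwd
    return out


def sub(a, b):
    if not _is_tensor(a, b):
        return np.asarray(a) - np.asarray(b)
    return add(a, neg(as_tensor(b)))


def mul(a, b):
    if not _is_tensor(a, b):
        return np.asarray(a) * np.asarray(b)
    a, b = as_tensor(a), as_tensor(b)
    out = Tensor(a.data * b.data, parents=(a, b))

    def bwd(g):
        _accum(a, _unbroadcast(g * b.data, a.data.shape))
        _accum(b, _unbroadcast(g * a.data, b.data.shape))

    out._backward = bwd
    return out


def div(a, b):
    if not _is_tensor(a, b):
        return np.asarray(a) / np.asarray(b)
    a, b = as_tensor(a), as_tensor(b)
    out = Tensor(a.data / b.data, parents=(a, b))

    def bwd(g):
        _accum(a, _unbroadcast(g / b.data, a.data.shape))
        _accum(b, _unbroadcast(-g * a.data / b.data**2, b.data.shape))

    out._backward = bwd
    return out


def neg(a):
    if not _is_tensor(a):
        return -np.asarray(a)
    out = Tensor(-a.data, parents=(a,))
    out._backward = lambda g: _accum(a, -g)
    return out


def relu(a):
    if not _is_tensor(a):
        return np.maximum(np.asarray(a), 0.0)
    out = Tensor(np.maximum(a.data, 0.0), parents=(a,))
    out._backward = lambda g: _accum(a, g * (a.data > 0))
    return out


def _sigmoid(x: np.ndarray) -> np.ndarray:
    # numerically stable logistic
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def sigmoid(a):
    if not _is_tensor(a):
        return _sigmoid(np.asarray(a, dtype=np.float64))
    s = _sigmoid(a.data)
    out = Tensor(s, parents=(a,))
    out._backward = lambda g: _accum(a, g * s * (1.0 - s))
    return out


def exp(a):
    if not _is_tensor(a):
        return np.exp(np.asarray(a))
    e = np.exp(a.data)
    out = Tensor(e, parents=(a,))
    out._backward = lambda g: _accum(a, g * e)
    return out


def log(a):
    if not _is_tensor(a):
        return np.log(np.asarray(a))
    out = Tensor(np.log(a.data), parents=(a,))
    out._backward = lambda g: _accum(a, g / a.data)
    return out


def softplus(a):
    """log(1 + e^x), computed stably."""
    if not _is_tensor(a):
        x = np.asarray(a, dtype=np.float64)
        return np.logaddexp(0.0, x)
    val = np.logaddexp(0.0, a.data)
    s = _sigmoid(a.data)
    out = Tensor(val, parents=(a,))
    out._backward = lambda g: _accum(a, g * s)
    return out


# ---------------------------------------------------------------------------
# reductions / shaping


def tsum(a, axis=None, keepdims=False):
    if not _is_tensor(a):
        return np.asarray(a).sum(axis=axis, keepdims=keepdims)
    out = Tensor(a.data.sum(axis=axis, keepdims=keepdims), parents=(a,))

    def bwd(g):
        if axis is None:
            _accum(a, np.broadcast_to(g, a.data.shape).copy())
            return
        if not keepdims:
            g = np.expand_dims(g, axis)
        _accum(a, np.broadcast_to(g, a.data.shape).copy())

    out._backward = bwd
    return out


def tmean(a, axis=None, keepdims=False):
    if not _is_tensor(a):
        return np.asarray(a).mean(axis=axis, keepdims=keepdims)
    n = a.data.size if axis is None else a.data.shape[axis]
    return div(tsum(a, axis=axis, keepdims=keepdims), float(n))


def max_over_rows(a):
    """Columnwise maximum over axis 0 (permutation-invariant readout)."""
    if not _is_tensor(a):
        return np.asarray(a).max(axis=0)
    idx = a.data.argmax(axis=0)
    out = Tensor(a.data.max(axis=0), parents=(a,))

    def bwd(g):
        ga = np.zeros_like(a.data)
        ga[idx, np.arange(a.data.shape[1])] = g
        _accum(a, ga)

    out._backward = bwd
    return out


def concat(parts, axis=0):
    if not _is_tensor(*parts):
        return np.concatenate([np.asarray(p) for p in parts], axis=axis)
    parts = [as_tensor(p) for p in parts]
    out = Tensor(np.concatenate([p.data for p in parts], axis=axis),
                 parents=tuple(parts))
    sizes = [p.data.shape[axis] for p in parts]
    offsets = np.cumsum([0] + sizes)

    def bwd(g):
        for p, lo, hi in zip(parts, offsets[:-1], offsets[1:]):
            sl = [slice(None)] * g.ndim
            sl[axis] = slice(lo, hi)
            _accum(p, g[tuple(sl)])

    out._backward = bwd
    return out


def take_rows(a, idx):
    """Row gather ``a[idx]``; gradient scatter-adds back."""
    idx = np.asarray(idx, dtype=np.intp)
    if not _is_tensor(a):
        return np.asarray(a)[idx]
    out = Tensor(a.data[idx], parents=(a,))

    def bwd(g):
        ga = np.zeros_like(a.data)
        np.add.at(ga, idx, g)
        _accum(a, ga)

    out._backward = bwd
    return out


def segment_sum(a, idx, n_segments: int):
    """Sum rows of ``a`` into ``n_segments`` bins given per-row bin ids."""
    idx = np.asarray(idx, dtype=np.intp)
    if not _is_tensor(a):
        a = np.asarray(a)
        out = np.zeros((n_segments,) + a.shape[1:], dtype=np.float64)
        np.add.at(out, idx, a)
        return out
    val = np.zeros((n_segments,) + a.data.shape[1:], dtype=np.float64)
    np.add.at(val, idx, a.data)
    out = Tensor(val, parents=(a,))
    out._backward = lambda g: _accum(a, g[idx])
    return out


def reshape(a, shape):
    if not _is_tensor(a):
        return np.asarray(a).reshape(shape)
    out = Tensor(a.data.reshape(shape), parents=(a,))
    out._backward = lambda g: _accum(a, g.reshape(a.data.shape))
    return out


# ---------------------------------------------------------------------------
# optimization


class AdamW:
    """Adaptive moment estimation with decoupled weight decay.

    Decay is applied directly to the parameter (``p -= lr * wd * p``), not
    through the gradient, so it is independent of the adaptive scaling.
    Biases and other parameters registered with ``decay=False`` are exempt.
    """

    def __init__(self, params, lr: float, weight_decay: float = 0.0,
                 betas=(0.9, 0.999), eps: float = 1e-8,
                 no_decay: set[int] | None = None):
        self.params: list[Tensor] = list(params)
        self.lr = float(lr)
        self.weight_decay = float(weight_decay)
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self._m = [np.zeros_like(p.data) for p in self.params]
        self._v = [np.zeros_like(p.data) for p in self.params]
        self._no_decay = no_decay or set()

    def zero_grad(self) -> None:
        for p in self.params:
            p.zero_grad()

    def step(self) -> None:
        self.t += 1
        bc1 = 1.0 - self.b1**self.t
        bc2 = 1.0 - self.b2**self.t
        for i, p in enumerate(self.params):
            g = p.grad
            if g is None:
                continue
            m = self._m[i]
            v = self._v[i]
            m *= self.b1
            m += (1.0 - self.b1) * g
            v *= self.b2
            v += (1.0 - self.b2) * g * g
            update = (m / bc1) / (np.sqrt(v / bc2) + self.eps)
            if self.weight_decay and id(p) not in self._no_decay:
                p.data -= self.lr * self.weight_decay * p.data
            p.data -= self.lr * update
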