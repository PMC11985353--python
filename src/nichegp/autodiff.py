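"""Minimal reverse-mode automatic differentiation on NumPy arrays.

The model in this package is a conditional variational graph autoencoder
whose forward pass mixes message passing, masked linear maps, softmax
link functions and negative-binomial log-likelihoods.  Rather than
hand-deriving gradients for every composition, this module provides a
small tape-based autodiff engine: a :class:`Tensor` wraps an
``ndarray``, records the operations applied to it, and
:meth:`Tensor.backward` replays the tape in reverse topological order.

Only the operations the model needs are implemented.  Gradients are
checked against central finite differences in the test suite.
"""

from __future__ import annotations

from typing import Callable, Iterable, Sequence

import numpy as np
from scipy import special as _sp

__all__ = [
    "Tensor",
    "Parameter",
    "concat",
    "stack_rows",
    "log_softmax",
    "softmax",
    "logsigmoid",
    "gammaln",
    "segment_sum",
    "segment_softmax",
    "AdamW",
]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of NumPy broadcasting)."""
    if grad.shape == shape:
        return grad
    # sum over leading dims added by broadcasting
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    """An ndarray with an attached gradient tape."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._backward: Callable[[np.ndarray], None] | None = None
        self._parents: tuple[Tensor, ...] = ()

    # -- construction helpers -------------------------------------------------
    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def ndim(self) -> int:
        return self.data.ndim

    def item(self) -> float:
        return float(self.data)

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"Tensor(shape={self.shape}, grad={self.requires_grad})"

    # -- tape machinery -------------------------------------------------------
    @staticmethod
    def _lift(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(x)

    def _make(self, data: np.ndarray, parents: Sequence["Tensor"],
              backward: Callable[[np.ndarray], None]) -> "Tensor":
        out = Tensor(data)
        if any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._parents = tuple(parents)
            out._backward = backward
        return out

    def backward(self, grad: np.ndarray | None = None) -> None:
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without a gradient requires a scalar")
            grad = np.ones_like(self.data)
        # reverse topological order over the tape
        order: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                order.append(node)
                continue
            if id(node) in seen or not node.requires_grad:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                stack.append((p, False))
        self.grad = np.asarray(grad, dtype=np.float64)
        for node in reversed(order):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    def _accumulate(self, grad: np.ndarray) -> None:
        # accumulation allocates a fresh array, so sharing `grad` with a
        # sibling branch is safe: gradients are never mutated in place
        if not self.requires_grad:
            return
        if self.grad is None:
            self.grad = grad
        else:
            self.grad = self.grad + grad

    # -- arithmetic -----------------------------------------------------------
    def __add__(self, other) -> "Tensor":
        other = self._lift(other)
        out_data = self.data + other.data

        def bw(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g, self.data.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(g, other.data.shape))

        return self._make(out_data, (self, other), bw)

    __radd__ = __add__

    def __neg__(self) -> "Tensor":
        def bw(g):
            self._accumulate(-g)

        return self._make(-self.data, (self,), bw)

    def __sub__(self, other) -> "Tensor":
        return self + (-self._lift(other))

    def __rsub__(self, other) -> "Tensor":
        return self._lift(other) + (-self)

    def __mul__(self, other) -> "Tensor":
        other = self._lift(other)
        out_data = self.data * other.data

        def bw(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g * other.data, self.data.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(g * self.data, other.data.shape))

        return self._make(out_data, (self, other), bw)

    __rmul__ = __mul__

    def __truediv__(self, other) -> "Tensor":
        other = self._lift(other)
        out_data = self.data / other.data

        def bw(g):
            self._accumulate(_unbroadcast(g / other.data, self.data.shape))
            other._accumulate(
                _unbroadcast(-g * self.data / other.data**2, other.data.shape))

        return self._make(out_data, (self, other), bw)

    def __rtruediv__(self, other) -> "Tensor":
        return self._lift(other) / self

    def __matmul__(self, other) -> "Tensor":
        other = self._lift(other)
        out_data = self.data @ other.data

        def bw(g):
            if self.requires_grad:
                self._accumulate(g @ other.data.T)
            if other.requires_grad:
                other._accumulate(self.data.T @ g)

        return self._make(out_data, (self, other), bw)

    def __pow__(self, p: float) -> "Tensor":
        out_data = self.data**p

        def bw(g):
            self._accumulate(g * p * self.data ** (p - 1))

        return self._make(out_data, (self,), bw)

    # -- elementwise functions ------------------------------------------------
    def exp(self) -> "Tensor":
        out_data = np.exp(self.data)

        def bw(g):
            self._accumulate(g * out_data)

        return self._make(out_data, (self,), bw)

    def log(self) -> "Tensor":
        def bw(g):
            self._accumulate(g / self.data)

        return self._make(np.log(self.data), (self,), bw)

    def abs(self) -> "Tensor":
        def bw(g):
            self._accumulate(g * np.sign(self.data))

        return self._make(np.abs(self.data), (self,), bw)

    def sqrt(self) -> "Tensor":
        out_data = np.sqrt(self.data)

        def bw(g):
            self._accumulate(g * 0.5 / out_data)

        return self._make(out_data, (self,), bw)

    def relu(self) -> "Tensor":
        mask = self.data > 0

        def bw(g):
            self._accumulate(g * mask)

        return self._make(self.data * mask, (self,), bw)

    def leaky_relu(self, slope: float = 0.2) -> "Tensor":
        scale = np.where(self.data > 0, 1.0, slope)

        def bw(g):
            self._accumulate(g * scale)

        return self._make(self.data * scale, (self,), bw)

    def clamp(self, lo: float, hi: float) -> "Tensor":
        inside = (self.data >= lo) & (self.data <= hi)

        def bw(g):
            self._accumulate(g * inside)

        return self._make(np.clip(self.data, lo, hi), (self,), bw)

    def softplus(self) -> "Tensor":
        out_data = np.logaddexp(0.0, self.data)
        sig = _sp.expit(self.data)

        def bw(g):
            self._accumulate(g * sig)

        return self._make(out_data, (self,), bw)

    # -- reductions & shaping -------------------------------------------------
    def sum(self, axis=None, keepdims: bool = False) -> "Tensor":
        out_data = self.data.sum(axis=axis, keepdims=keepdims)

        def bw(g):
            gg = np.asarray(g)
            if axis is not None and not keepdims:
                gg = np.expand_dims(gg, axis)
            self._accumulate(np.broadcast_to(gg, self.data.shape).copy())

        return self._make(out_data, (self,), bw)

    def mean(self, axis=None, keepdims: bool = False) -> "Tensor":
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def reshape(self, *shape) -> "Tensor":
        old = self.data.shape

        def bw(g):
            self._accumulate(g.reshape(old))

        return self._make(self.data.reshape(*shape), (self,), bw)

    @property
    def T(self) -> "Tensor":
        def bw(g):
            self._accumulate(g.T)

        return self._make(self.data.T, (self,), bw)

    def take_rows(self, idx: np.ndarray) -> "Tensor":
        """Gather rows (axis 0); duplicates allowed, gradients accumulate."""
        idx = np.asarray(idx, dtype=np.intp)

        def bw(g):
            out = np.zeros_like(self.data)
            np.add.at(out, idx, g)
            self._accumulate(out)

        return self._make(self.data[idx], (self,), bw)

    def take_cols(self, idx: np.ndarray) -> "Tensor":
        idx = np.asarray(idx, dtype=np.intp)

        def bw(g):
            out = np.zeros_like(self.data)
            np.add.at(out.T, idx, g.T)
            self._accumulate(out)

        return self._make(self.data[:, idx], (self,), bw)

    def layer_norm(self, eps: float = 1e-5) -> "Tensor":
        """Normalize each row to zero mean / unit variance (no affine)."""
        mu = self.data.mean(axis=-1, keepdims=True)
        xc = self.data - mu
        var = (xc**2).mean(axis=-1, keepdims=True)
        inv = 1.0 / np.sqrt(var + eps)
        out_data = xc * inv

        def bw(g):
            # d/dx of (x - mu) / sqrt(var + eps); row size folds into means
            term = inv * (g - g.mean(axis=-1, keepdims=True)
                          - out_data * (g * out_data).mean(axis=-1,
                                                           keepdims=True))
            self._accumulate(term)

        return self._make(out_data, (self,), bw)


class Parameter(Tensor):
    """A trainable tensor."""

    def __init__(self, data):
        super().__init__(np.array(data, dtype=np.float64), requires_grad=True)

    def zero_grad(self) -> None:
        self.grad = None


# -- free functions -----------------------------------------------------------

def concat(tensors: Sequence[Tensor], axis: int = -1) -> Tensor:
    tensors = [Tensor._lift(t) for t in tensors]
    out_data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.data.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def bw(g):
        for t, piece in zip(tensors, np.split(g, splits, axis=axis)):
            t._accumulate(piece)

    return tensors[0]._make(out_data, tensors, bw)


def stack_rows(tensors: Sequence[Tensor]) -> Tensor:
    return concat([t.reshape(1, -1) for t in tensors], axis=0)


def log_softmax(x: Tensor, axis: int = -1) -> Tensor:
    m = x.data.max(axis=axis, keepdims=True)
    lse = m + np.log(np.exp(x.data - m).sum(axis=axis, keepdims=True))
    out_data = x.data - lse
    p = np.exp(out_data)

    def bw(g):
        x._accumulate(g - p * g.sum(axis=axis, keepdims=True))

    return x._make(out_data, (x,), bw)


def softmax(x: Tensor, axis: int = -1) -> Tensor:
    return log_softmax(x, axis=axis).exp()


def logsigmoid(x: Tensor) -> Tensor:
    """log σ(x), numerically stable: -softplus(-x)."""
    return -((-x).softplus())


def gammaln(x: Tensor) -> Tensor:
    """Log-gamma with digamma gradient (negative-binomial likelihoods)."""
    def bw(g):
        x._accumulate(g * _sp.digamma(x.data))

    return x._make(_sp.gammaln(x.data), (x,), bw)


def sparse_matmul(s, x: Tensor) -> Tensor:
    """Product of a constant scipy sparse matrix with a tensor.

    Backs the gather (rows of ``x`` indexed with duplicates) and
    segment-sum patterns of message passing; the backward pass is a
    single transposed sparse product instead of a scatter-add.
    """
    st = s.T.tocsr()

    def bw(g):
        x._accumulate(st @ g)

    return x._make(s @ x.data, (x,), bw)


def segment_sum(x: Tensor, segments: np.ndarray, n_segments: int) -> Tensor:
    """Sum rows of ``x`` into ``n_segments`` buckets given by ``segments``."""
    segments = np.asarray(segments, dtype=np.intp)
    out_data = np.zeros((n_segments,) + x.data.shape[1:])
    np.add.at(out_data, segments, x.data)

    def bw(g):
        x._accumulate(g[segments])

    return x._make(out_data, (x,), bw)


def segment_softmax(scores: Tensor, segments: np.ndarray,
                    n_segments: int) -> Tensor:
    """Softmax of per-edge scores within destination-node segments.

    Used for graph attention: ``scores`` is a 1-D tensor of raw
    attention scores per edge, ``segments`` the destination node of
    each edge.
    """
    segments = np.asarray(segments, dtype=np.intp)
    s = scores.data
    m = np.full(n_segments, -np.inf)
    np.maximum.at(m, segments, s)
    e = np.exp(s - m[segments])
    denom = np.zeros(n_segments)
    np.add.at(denom, segments, e)
    alpha = e / denom[segments]

    def bw(g):
        dot = np.zeros(n_segments)
        np.add.at(dot, segments, g * alpha)
        scores._accumulate(alpha * (g - dot[segments]))

    return scores._make(alpha, (scores,), bw)


class AdamW:
    """Adam with decoupled weight decay."""

    def __init__(self, params: Iterable[Parameter], lr: float = 1e-3,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8,
                 weight_decay: float = 0.0):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.weight_decay = weight_decay
        self.t = 0
        self._m = [np.zeros_like(p.data) for p in self.params]
        self._v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self) -> None:
        self.t += 1
        b1t = 1.0 - self.b1**self.t
        b2t = 1.0 - self.b2**self.t
        for p, m, v in zip(self.params, self._m, self._v):
            if p.grad is None:
                continue
            g = p.grad
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * g * g
            if self.weight_decay:
                p.data -= self.lr * self.weight_decay * p.data
            p.data -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)
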