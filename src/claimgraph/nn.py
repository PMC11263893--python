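"""Minimal reverse-mode automatic differentiation over numpy arrays.

Only the handful of operations the graph model needs: broadcasting
arithmetic, batched matmul, embedding gather, masked softmax and the usual
activations.  Everything is float64 so finite-difference gradient checks
are meaningful.
"""

from __future__ import annotations

from typing import Callable

import numpy as np

Array = np.ndarray


def _unbroadcast(grad: Array, shape: tuple[int, ...]) -> Array:
    """Sum ``grad`` down to ``shape`` (reverse of numpy broadcasting)."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, size in enumerate(shape):
        if size == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: Array | None = None
        self.requires_grad = requires_grad
        self._backward: Callable[[Array], None] | None = None
        self._parents: tuple[Tensor, ...] = ()

    @property
    def shape(self):
        return self.data.shape

    # -- graph bookkeeping -------------------------------------------------
    def _accumulate(self, g: Array) -> None:
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad += g

    def backward(self, grad: Array | None = None) -> None:
        topo: list[Tensor] = []
        seen: set[int] = set()
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
                stack.append((p, False))
        if grad is None:
            grad = np.ones_like(self.data)
        self._accumulate(np.asarray(grad, dtype=np.float64))
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    # -- operator sugar ----------------------------------------------------
    def __add__(self, other):
        return add(self, as_tensor(other))

    __radd__ = __add__

    def __mul__(self, other):
        return mul(self, as_tensor(other))

    __rmul__ = __mul__

    def __sub__(self, other):
        return add(self, mul(as_tensor(other), Tensor(-1.0)))

    def __rsub__(self, other):
        return add(as_tensor(other), mul(self, Tensor(-1.0)))

    def __neg__(self):
        return mul(self, Tensor(-1.0))

    def __matmul__(self, other):
        return matmul(self, as_tensor(other))


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def _make(data: Array, parents: tuple[Tensor, ...], backward) -> Tensor:
    out = Tensor(data)
    if any(p.requires_grad for p in parents):
        out.requires_grad = True
        out._parents = tuple(p for p in parents if p.requires_grad)
        out._backward = backward
    return out


# -- primitives ------------------------------------------------------------

def add(a: Tensor, b: Tensor) -> Tensor:
    def backward(g: Array) -> None:
        if a.requires_grad:
            a._accumulate(_unbroadcast(g, a.shape))
        if b.requires_grad:
            b._accumulate(_unbroadcast(g, b.shape))

    return _make(a.data + b.data, (a, b), backward)


def mul(a: Tensor, b: Tensor) -> Tensor:
    def backward(g: Array) -> None:
        if a.requires_grad:
            a._accumulate(_unbroadcast(g * b.data, a.shape))
        if b.requires_grad:
            b._accumulate(_unbroadcast(g * a.data, b.shape))

    return _make(a.data * b.data, (a, b), backward)


def matmul(a: Tensor, b: Tensor) -> Tensor:
    def backward(g: Array) -> None:
        if a.requires_grad:
            ga = g @ np.swapaxes(b.data, -1, -2)
            a._accumulate(_unbroadcast(ga, a.shape))
        if b.requires_grad:
            gb = np.swapaxes(a.data, -1, -2) @ g
            b._accumulate(_unbroadcast(gb, b.shape))

    return _make(a.data @ b.data, (a, b), backward)


def exp(a: Tensor) -> Tensor:
    out_data = np.exp(a.data)

    def backward(g: Array) -> None:
        a._accumulate(g * out_data)

    return _make(out_data, (a,), backward)


def log(a: Tensor) -> Tensor:
    def backward(g: Array) -> None:
        a._accumulate(g / a.data)

    return _make(np.log(a.data), (a,), backward)


def tsum(a: Tensor, axis=None, keepdims: bool = False) -> Tensor:
    def backward(g: Array) -> None:
        if axis is None:
            a._accumulate(np.broadcast_to(g, a.shape).copy())
            return
        if not keepdims:
            g = np.expand_dims(g, axis)
        a._accumulate(np.broadcast_to(g, a.shape).copy())

    return _make(a.data.sum(axis=axis, keepdims=keepdims), (a,), backward)


def mean(a: Tensor, axis=None, keepdims: bool = False) -> Tensor:
    n = a.data.size if axis is None else a.data.shape[axis]
    return mul(tsum(a, axis=axis, keepdims=keepdims), Tensor(1.0 / n))


def leaky_relu(a: Tensor, slope: float = 0.2) -> Tensor:
    mask = np.where(a.data > 0, 1.0, slope)

    def backward(g: Array) -> None:
        a._accumulate(g * mask)

    return _make(a.data * mask, (a,), backward)


def elu(a: Tensor, alpha: float = 1.0) -> Tensor:
    neg = alpha * (np.exp(np.minimum(a.data, 0.0)) - 1.0)
    out_data = np.where(a.data > 0, a.data, neg)

    def backward(g: Array) -> None:
        a._accumulate(g * np.where(a.data > 0, 1.0, neg + alpha))

    return _make(out_data, (a,), backward)


def sigmoid(a: Tensor) -> Tensor:
    out_data = 0.5 * (1.0 + np.tanh(0.5 * a.data))  # numerically stable

    def backward(g: Array) -> None:
        a._accumulate(g * out_data * (1.0 - out_data))

    return _make(out_data, (a,), backward)


def masked_softmax(scores: Tensor, valid: Array) -> Tensor:
    """Row-wise softmax over the last axis, restricted to ``valid`` entries.

    Invalid entries get probability exactly 0; fully invalid rows are all 0.
    """
    neg = np.where(valid, scores.data, -np.inf)
    m = np.max(neg, axis=-1, keepdims=True)
    m = np.where(np.isfinite(m), m, 0.0)
    e = np.where(valid, np.exp(neg - m), 0.0)
    denom = e.sum(axis=-1, keepdims=True)
    out_data = np.divide(e, denom, out=np.zeros_like(e), where=denom > 0)

    def backward(g: Array) -> None:
        dot = (g * out_data).sum(axis=-1, keepdims=True)
        scores._accumulate(out_data * (g - dot))

    return _make(out_data, (scores,), backward)


def gather_rows(table: Tensor, idx: Array) -> Tensor:
    """Embedding lookup: ``out[...] = table[idx[...], :]``."""
    def backward(g: Array) -> None:
        gt = np.zeros_like(table.data)
        np.add.at(gt, idx.reshape(-1), g.reshape(-1, table.data.shape[-1]))
        table._accumulate(gt)

    return _make(table.data[idx], (table,), backward)


def select_rows(a: Tensor, batch_idx: Array, row_idx: Array) -> Tensor:
    """out[b] = a[b, row_idx[b], :] — per-graph readout-node extraction."""
    def backward(g: Array) -> None:
        ga = np.zeros_like(a.data)
        ga[batch_idx, row_idx] = g
        a._accumulate(ga)

    return _make(a.data[batch_idx, row_idx], (a,), backward)


def swap_last2(a: Tensor) -> Tensor:
    def backward(g: Array) -> None:
        a._accumulate(np.swapaxes(g, -1, -2))

    return _make(np.swapaxes(a.data, -1, -2), (a,), backward)


def dropout(a: Tensor, rate: float, rng: np.random.Generator) -> Tensor:
    if rate <= 0:
        return a
    keep = (rng.random(a.shape) >= rate) / (1.0 - rate)

    def backward(g: Array) -> None:
        a._accumulate(g * keep)

    return _make(a.data * keep, (a,), backward)


def bce_with_logits(logits: Tensor, targets: Array) -> Tensor:
    """Elementwise binary cross-entropy from logits (log-sum-exp stable)."""
    x = logits.data
    out_data = np.maximum(x, 0) - x * targets + np.log1p(np.exp(-np.abs(x)))
    p = 0.5 * (1.0 + np.tanh(0.5 * x))

    def backward(g: Array) -> None:
        logits._accumulate(g * (p - targets))

    return _make(out_data, (logits,), backward)


# -- optimizer -------------------------------------------------------------

class Adam:
    def __init__(
        self,
        params: dict[str, Tensor],
        lr: float = 1e-4,
        betas: tuple[float, float] = (0.9, 0.999),
        eps: float = 1e-8,
    ):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = {k: np.zeros_like(p.data) for k, p in params.items()}
        self.v = {k: np.zeros_like(p.data) for k, p in params.items()}

    def zero_grad(self) -> None:
        for p in self.params.values():
            p.grad = None

    def step(self) -> None:
        self.t += 1
        for k, p in self.params.items():
            if p.grad is None:
                continue
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * p.grad
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * p.grad**2
            mhat = self.m[k] / (1 - self.b1**self.t)
            vhat = self.v[k] / (1 - self.b2**self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
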