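"""Minimal reverse-mode automatic differentiation on NumPy arrays.

Implements exactly the operator set the aligner needs: broadcasting
arithmetic, dense and (constant-)sparse matrix products, exp/log/relu/sqrt,
axis reductions, row gathering, concatenation, dropout, and a numerically
stable binary cross-entropy on logits.  Everything is float64.

A :class:`Tensor` wraps an ndarray plus a closure that maps the output
gradient to the parents' gradients.  ``Tensor.backward()`` runs a
topological sweep and accumulates ``.grad`` on every tensor that
``requires_grad``.  Gradient correctness is enforced end-to-end by a
finite-difference check in the test suite.
"""

from __future__ import annotations

from typing import Callable, Sequence

import numpy as np
import scipy.sparse as sp

__all__ = ["Tensor", "astensor", "concat", "rows", "spmm", "dropout",
           "bce_with_logits", "sigmoid", "Adam"]


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of numpy broadcasting)."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for axis, size in enumerate(shape):
        if size == 1 and grad.shape[axis] != 1:
            grad = grad.sum(axis=axis, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    __slots__ = ("v", "grad", "requires_grad", "_parents", "_bw")

    def __init__(self, value, requires_grad: bool = False,
                 parents: Sequence["Tensor"] = (),
                 bw: Callable[[np.ndarray], Sequence] | None = None):
        self.v = np.asarray(value, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad) or any(
            p.requires_grad for p in parents)
        self._parents = tuple(parents)
        self._bw = bw

    # ------------------------------------------------------------------
    @property
    def shape(self):
        return self.v.shape

    @property
    def ndim(self):
        return self.v.ndim

    def __repr__(self):
        return f"Tensor(shape={self.v.shape}, requires_grad={self.requires_grad})"

    # --- arithmetic ----------------------------------------------------
    def __add__(self, other):
        other = astensor(other)
        a, b = self, other
        return Tensor(a.v + b.v, parents=(a, b),
                      bw=lambda g: (_unbroadcast(g, a.v.shape),
                                    _unbroadcast(g, b.v.shape)))

    __radd__ = __add__

    def __neg__(self):
        a = self
        return Tensor(-a.v, parents=(a,), bw=lambda g: (-g,))

    def __sub__(self, other):
        other = astensor(other)
        a, b = self, other
        return Tensor(a.v - b.v, parents=(a, b),
                      bw=lambda g: (_unbroadcast(g, a.v.shape),
                                    _unbroadcast(-g, b.v.shape)))

    def __rsub__(self, other):
        return astensor(other) - self

    def __mul__(self, other):
        other = astensor(other)
        a, b = self, other
        return Tensor(a.v * b.v, parents=(a, b),
                      bw=lambda g: (_unbroadcast(g * b.v, a.v.shape),
                                    _unbroadcast(g * a.v, b.v.shape)))

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = astensor(other)
        a, b = self, other
        return Tensor(a.v / b.v, parents=(a, b),
                      bw=lambda g: (_unbroadcast(g / b.v, a.v.shape),
                                    _unbroadcast(-g * a.v / (b.v * b.v),
                                                 b.v.shape)))

    def __rtruediv__(self, other):
        return astensor(other) / self

    def __matmul__(self, other):
        other = astensor(other)
        a, b = self, other
        return Tensor(a.v @ b.v, parents=(a, b),
                      bw=lambda g: (g @ b.v.T, a.v.T @ g))

    # --- elementwise ---------------------------------------------------
    def exp(self):
        a = self
        out_v = np.exp(a.v)
        return Tensor(out_v, parents=(a,), bw=lambda g: (g * out_v,))

    def log(self):
        a = self
        return Tensor(np.log(a.v), parents=(a,), bw=lambda g: (g / a.v,))

    def relu(self):
        a = self
        mask = a.v > 0
        return Tensor(a.v * mask, parents=(a,), bw=lambda g: (g * mask,))

    def sqrt(self):
        a = self
        out_v = np.sqrt(a.v)
        return Tensor(out_v, parents=(a,), bw=lambda g: (g * 0.5 / out_v,))

    # --- reductions ----------------------------------------------------
    def sum(self, axis=None, keepdims=False):
        a = self

        def bw(g):
            if axis is None:
                return (np.broadcast_to(g, a.v.shape).copy(),)
            gg = g if keepdims else np.expand_dims(g, axis)
            return (np.broadcast_to(gg, a.v.shape).copy(),)

        return Tensor(a.v.sum(axis=axis, keepdims=keepdims),
                      parents=(a,), bw=bw)

    def mean(self, axis=None, keepdims=False):
        if axis is None:
            n = self.v.size
        else:
            n = self.v.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    # --- autodiff ------------------------------------------------------
    def backward(self, grad: np.ndarray | None = None):
        if grad is None:
            if self.v.size != 1:
                raise ValueError("backward() without grad requires a scalar")
            grad = np.ones_like(self.v)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:
            node, done = stack.pop()
            if done:
                topo.append(node)
                continue
            if id(node) in seen or not node.requires_grad:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                stack.append((p, False))
        grads: dict[int, np.ndarray] = {id(self): np.asarray(grad, float)}
        for node in reversed(topo):
            g = grads.pop(id(node), None)
            if g is None:
                continue
            if node._bw is None:
                node.grad = g if node.grad is None else node.grad + g
                continue
            for parent, pg in zip(node._parents, node._bw(g)):
                if pg is None or not parent.requires_grad:
                    continue
                if id(parent) in grads:
                    grads[id(parent)] = grads[id(parent)] + pg
                else:
                    grads[id(parent)] = pg


def astensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


# ---------------------------------------------------------------------------
# free functions
# ---------------------------------------------------------------------------

def concat(tensors: Sequence[Tensor], axis: int = 1) -> Tensor:
    tensors = [astensor(t) for t in tensors]
    sizes = [t.v.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def bw(g):
        return tuple(np.split(g, splits, axis=axis))

    return Tensor(np.concatenate([t.v for t in tensors], axis=axis),
                  parents=tensors, bw=bw)


def rows(t: Tensor, idx: np.ndarray) -> Tensor:
    """Gather rows ``t[idx]`` (idx may repeat; gradients accumulate)."""
    t = astensor(t)
    idx = np.asarray(idx, dtype=np.intp)

    def bw(g):
        out = np.zeros_like(t.v)
        np.add.at(out, idx, g)
        return (out,)

    return Tensor(t.v[idx], parents=(t,), bw=bw)


def spmm(mat: sp.spmatrix, t: Tensor) -> Tensor:
    """Product of a constant sparse matrix with a differentiable tensor."""
    t = astensor(t)
    mat = mat.tocsr()
    mat_t = mat.T.tocsr()
    return Tensor(mat @ t.v, parents=(t,), bw=lambda g: (mat_t @ g,))


def dropout(t: Tensor, p: float, rng: np.random.Generator) -> Tensor:
    """Inverted dropout; identity when p == 0."""
    if p <= 0.0:
        return t
    mask = (rng.random(t.v.shape) >= p) / (1.0 - p)
    return t * Tensor(mask)


def sigmoid(t: Tensor) -> Tensor:
    t = astensor(t)
    out_v = np.where(t.v >= 0, 1.0 / (1.0 + np.exp(-np.abs(t.v))),
                     np.exp(-np.abs(t.v)) / (1.0 + np.exp(-np.abs(t.v))))
    return Tensor(out_v, parents=(t,), bw=lambda g: (g * out_v * (1 - out_v),))


def bce_with_logits(logits: Tensor, labels: np.ndarray) -> Tensor:
    """Mean binary cross-entropy on raw scores, stable for large |logit|."""
    logits = astensor(logits)
    y = np.asarray(labels, dtype=np.float64)
    if y.shape != logits.v.shape:
        raise ValueError("logits/labels shape mismatch")
    z = logits.v
    # softplus(z) - y*z  ==  max(z,0) - y*z + log1p(exp(-|z|))
    loss = np.maximum(z, 0) - y * z + np.log1p(np.exp(-np.abs(z)))
    n = y.size
    p = np.where(z >= 0, 1.0 / (1.0 + np.exp(-np.abs(z))),
                 np.exp(-np.abs(z)) / (1.0 + np.exp(-np.abs(z))))

    def bw(g):
        return (g * (p - y) / n,)

    return Tensor(loss.mean(), parents=(logits,), bw=bw)


# ---------------------------------------------------------------------------
# optimisation
# ---------------------------------------------------------------------------

class Adam:
    """Adam on a name->Tensor parameter dict (first-moment/second-moment)."""

    def __init__(self, params: dict[str, Tensor], lr: float = 1e-3,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = {k: np.zeros_like(p.v) for k, p in params.items()}
        self.s = {k: np.zeros_like(p.v) for k, p in params.items()}

    def zero_grad(self):
        for p in self.params.values():
            p.grad = None

    def step(self):
        self.t += 1
        for k, p in self.params.items():
            if p.grad is None:
                continue
            g = p.grad
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.s[k] = self.b2 * self.s[k] + (1 - self.b2) * g * g
            mhat = self.m[k] / (1 - self.b1 ** self.t)
            shat = self.s[k] / (1 - self.b2 ** self.t)
            p.v -= self.lr * mhat / (np.sqrt(shat) + self.eps)
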