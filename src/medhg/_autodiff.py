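"""Minimal reverse-mode automatic differentiation on dense numpy arrays.

Supports exactly the operations the heterogeneous graph convolution needs:
matrix products (including products with constant sparse adjacency
matrices), broadcast add/multiply, concatenation, ELU, row softmax, row
selection, reductions and elementwise transcendentals.  Everything is
float64; gradients are accumulated into ``Tensor.grad`` by ``backward()``
over a topologically ordered tape.
"""

from __future__ import annotations

import numpy as np
from scipy import sparse as sp

__all__ = ["Tensor", "spmm", "concat", "Adam"]


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    # leading broadcast axes
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


class Tensor:
    """A node in the computation tape.

    Parameters with ``requires_grad=True`` accumulate gradients; constants
    do not.  Operations build the tape lazily; ``backward()`` runs reverse
    accumulation from a scalar output.
    """

    __slots__ = ("value", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, value, requires_grad: bool = False):
        self.value = np.asarray(value, dtype=np.float64)
        self.grad = None
        self.requires_grad = requires_grad
        self._parents: tuple = ()
        self._backward = None

    # -- construction helpers ------------------------------------------------
    @staticmethod
    def _make(value, parents, backward):
        out = Tensor(value)
        out.requires_grad = any(p.requires_grad for p in parents)
        if out.requires_grad:
            out._parents = tuple(parents)
            out._backward = backward
        return out

    @staticmethod
    def _lift(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(x)

    @property
    def shape(self):
        return self.value.shape

    # -- arithmetic ----------------------------------------------------------
    def __add__(self, other):
        other = Tensor._lift(other)

        def backward(g, a=self, b=other):
            if a.requires_grad:
                a._accum(_unbroadcast(g, a.value.shape))
            if b.requires_grad:
                b._accum(_unbroadcast(g, b.value.shape))

        return Tensor._make(self.value + other.value, (self, other), backward)

    __radd__ = __add__

    def __neg__(self):
        def backward(g, a=self):
            if a.requires_grad:
                a._accum(-g)

        return Tensor._make(-self.value, (self,), backward)

    def __sub__(self, other):
        return self + (-Tensor._lift(other))

    def __rsub__(self, other):
        return Tensor._lift(other) + (-self)

    def __mul__(self, other):
        other = Tensor._lift(other)

        def backward(g, a=self, b=other):
            if a.requires_grad:
                a._accum(_unbroadcast(g * b.value, a.value.shape))
            if b.requires_grad:
                b._accum(_unbroadcast(g * a.value, b.value.shape))

        return Tensor._make(self.value * other.value, (self, other), backward)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = Tensor._lift(other)
        return self * other ** -1.0

    def __rtruediv__(self, other):
        return Tensor._lift(other) * self ** -1.0

    def __pow__(self, p: float):
        def backward(g, a=self):
            if a.requires_grad:
                a._accum(g * p * a.value ** (p - 1.0))

        return Tensor._make(self.value ** p, (self,), backward)

    def __matmul__(self, other):
        other = Tensor._lift(other)

        def backward(g, a=self, b=other):
            if a.requires_grad:
                a._accum(g @ b.value.T)
            if b.requires_grad:
                b._accum(a.value.T @ g)

        return Tensor._make(self.value @ other.value, (self, other), backward)

    # -- nonlinearities ------------------------------------------------------
    def elu(self, alpha: float = 1.0):
        x = self.value
        y = np.where(x > 0, x, alpha * np.expm1(np.minimum(x, 0.0)))

        def backward(g, a=self, y=y):
            if a.requires_grad:
                a._accum(g * np.where(a.value > 0, 1.0, y + alpha))

        return Tensor._make(y, (self,), backward)

    def relu(self):
        def backward(g, a=self):
            if a.requires_grad:
                a._accum(g * (a.value > 0))

        return Tensor._make(np.maximum(self.value, 0.0), (self,), backward)

    def exp(self):
        y = np.exp(self.value)

        def backward(g, a=self, y=y):
            if a.requires_grad:
                a._accum(g * y)

        return Tensor._make(y, (self,), backward)

    def log(self):
        def backward(g, a=self):
            if a.requires_grad:
                a._accum(g / a.value)

        return Tensor._make(np.log(self.value), (self,), backward)

    def softmax(self, axis: int = 1):
        z = self.value - self.value.max(axis=axis, keepdims=True)
        e = np.exp(z)
        y = e / e.sum(axis=axis, keepdims=True)

        def backward(g, a=self, y=y):
            if a.requires_grad:
                dot = (g * y).sum(axis=axis, keepdims=True)
                a._accum(y * (g - dot))

        return Tensor._make(y, (self,), backward)

    def clip(self, lo: float, hi: float):
        """Clamp values; gradient passes through only inside the interval."""
        inside = (self.value > lo) & (self.value < hi)

        def backward(g, a=self, inside=inside):
            if a.requires_grad:
                a._accum(g * inside)

        return Tensor._make(np.clip(self.value, lo, hi), (self,), backward)

    # -- reductions & shaping ------------------------------------------------
    def sum(self, axis=None, keepdims: bool = False):
        def backward(g, a=self):
            if a.requires_grad:
                gg = np.asarray(g)
                if axis is not None and not keepdims:
                    gg = np.expand_dims(gg, axis)
                a._accum(np.broadcast_to(gg, a.value.shape).copy())

        return Tensor._make(self.value.sum(axis=axis, keepdims=keepdims), (self,), backward)

    def mean(self, axis=None, keepdims: bool = False):
        n = self.value.size if axis is None else self.value.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def take_rows(self, idx: np.ndarray):
        idx = np.asarray(idx)

        def backward(g, a=self, idx=idx):
            if a.requires_grad:
                out = np.zeros_like(a.value)
                np.add.at(out, idx, g)
                a._accum(out)

        return Tensor._make(self.value[idx], (self,), backward)

    def col(self, j: int):
        """Column ``j`` kept 2-D (n, 1)."""

        def backward(g, a=self, j=j):
            if a.requires_grad:
                out = np.zeros_like(a.value)
                out[:, j : j + 1] = g
                a._accum(out)

        return Tensor._make(self.value[:, j : j + 1], (self,), backward)

    # -- autograd machinery --------------------------------------------------
    def _accum(self, g):
        if self.grad is None:
            self.grad = np.array(g, dtype=np.float64)
        else:
            self.grad = self.grad + g

    def backward(self):
        if self.value.size != 1:
            raise ValueError("backward() requires a scalar output")
        topo, seen = [], set()

        def visit(t):
            if id(t) in seen or not t.requires_grad:
                return
            seen.add(id(t))
            for p in t._parents:
                visit(p)
            topo.append(t)

        visit(self)
        self.grad = np.ones_like(self.value)
        for t in reversed(topo):
            if t._backward is not None:
                t._backward(t.grad)


def spmm(A, X: Tensor) -> Tensor:
    """Product of a *constant* (sparse or dense) matrix with a Tensor."""
    A = sp.csr_matrix(A) if sp.issparse(A) else np.asarray(A, dtype=np.float64)

    def backward(g, X=X, A=A):
        if X.requires_grad:
            X._accum(A.T @ g)

    return Tensor._make(A @ X.value, (X,), backward)


def concat(tensors, axis: int = 1) -> Tensor:
    tensors = list(tensors)
    sizes = [t.value.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def backward(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                sl = [slice(None)] * g.ndim
                sl[axis] = slice(lo, hi)
                t._accum(g[tuple(sl)])

    return Tensor._make(np.concatenate([t.value for t in tensors], axis=axis), tensors, backward)


class Adam:
    """Adam optimizer over a list of parameter Tensors."""

    def __init__(self, params, lr: float = 1e-3, betas=(0.9, 0.999),
                 eps: float = 1e-8, weight_decay=0.0):
        """``weight_decay`` may be a scalar or a per-parameter sequence."""
        self.params = list(params)
        self.lr, self.eps = lr, eps
        if np.isscalar(weight_decay):
            self.weight_decay = [float(weight_decay)] * len(self.params)
        else:
            self.weight_decay = [float(w) for w in weight_decay]
            if len(self.weight_decay) != len(self.params):
                raise ValueError("weight_decay list must match params")
        self.b1, self.b2 = betas
        self.t = 0
        self.m = [np.zeros_like(p.value) for p in self.params]
        self.v = [np.zeros_like(p.value) for p in self.params]

    def zero_grad(self):
        for p in self.params:
            p.grad = None

    def step(self):
        self.t += 1
        for i, p in enumerate(self.params):
            g = p.grad if p.grad is not None else np.zeros_like(p.value)
            if self.weight_decay[i]:
                g = g + self.weight_decay[i] * p.value
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1 ** self.t)
            vhat = self.v[i] / (1 - self.b2 ** self.t)
            p.value = p.value - self.lr * mhat / (np.sqrt(vhat) + self.eps)
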