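"""Minimal reverse-mode automatic differentiation over numpy arrays.

The model in this package is small (full-batch training on a few thousand
spots) and has a fixed computation graph, so a compact tape-based autodiff
engine over float64 ndarrays is sufficient and keeps the package free of a
deep-learning framework dependency.  Supported operations are exactly those
the model needs: broadcasting arithmetic, matmul, elementwise nonlinearities,
log-gamma, reductions, row gathers and a sparse(pattern) @ dense product.

All functions accept either :class:`Tensor` or plain ndarrays/scalars;
ndarrays are wrapped as constants.
"""

from __future__ import annotations

import numpy as np
from scipy import sparse as sp
from scipy import special


class Tensor:
    """An ndarray with an optional gradient tape entry."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.requires_grad = bool(requires_grad)
        self.grad: np.ndarray | None = None
        self._parents: tuple[Tensor, ...] = ()
        self._backward = None

    # -- construction -----------------------------------------------------
    @staticmethod
    def _result(data, parents, backward):
        out = Tensor(data, requires_grad=any(p.requires_grad for p in parents))
        if out.requires_grad:
            out._parents = tuple(parents)
            out._backward = backward
        return out

    @property
    def shape(self):
        return self.data.shape

    @property
    def T(self):
        return transpose(self)

    def item(self) -> float:
        return float(self.data)

    # -- autograd ---------------------------------------------------------
    def backward(self, grad=None):
        if grad is None:
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen or not node.requires_grad:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                stack.append((p, False))
        self.grad = np.asarray(grad, dtype=np.float64)
        for node in reversed(topo):
            if node._backward is not None:
                node._backward(node.grad)

    def zero_grad(self):
        self.grad = None

    def _accum(self, g):
        if self.grad is None:
            self.grad = g.copy() if isinstance(g, np.ndarray) else np.asarray(g)
        else:
            self.grad = self.grad + g

    # -- operators --------------------------------------------------------
    def __add__(self, other):
        return add(self, other)

    __radd__ = __add__

    def __mul__(self, other):
        return mul(self, other)

    __rmul__ = __mul__

    def __neg__(self):
        return mul(self, -1.0)

    def __sub__(self, other):
        return add(self, mul(other, -1.0))

    def __rsub__(self, other):
        return add(mul(self, -1.0), other)

    def __truediv__(self, other):
        return div(self, other)

    def __rtruediv__(self, other):
        return div(other, self)

    def __matmul__(self, other):
        return matmul(self, other)

    def __pow__(self, p):
        return power(self, p)

    def __repr__(self):  # pragma: no cover - debugging aid
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum `grad` down to `shape` (reverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad


# ---------------------------------------------------------------------------
# arithmetic


def add(a, b):
    a, b = as_tensor(a), as_tensor(b)
    out_data = a.data + b.data

    def backward(g):
        if a.requires_grad:
            a._accum(_unbroadcast(g, a.data.shape))
        if b.requires_grad:
            b._accum(_unbroadcast(g, b.data.shape))

    return Tensor._result(out_data, (a, b), backward)


def mul(a, b):
    a, b = as_tensor(a), as_tensor(b)
    out_data = a.data * b.data

    def backward(g):
        if a.requires_grad:
            a._accum(_unbroadcast(g * b.data, a.data.shape))
        if b.requires_grad:
            b._accum(_unbroadcast(g * a.data, b.data.shape))

    return Tensor._result(out_data, (a, b), backward)


def div(a, b):
    a, b = as_tensor(a), as_tensor(b)
    out_data = a.data / b.data

    def backward(g):
        if a.requires_grad:
            a._accum(_unbroadcast(g / b.data, a.data.shape))
        if b.requires_grad:
            b._accum(_unbroadcast(-g * a.data / b.data**2, b.data.shape))

    return Tensor._result(out_data, (a, b), backward)


def power(a, p: float):
    a = as_tensor(a)
    out_data = a.data**p

    def backward(g):
        if a.requires_grad:
            a._accum(g * p * a.data ** (p - 1))

    return Tensor._result(out_data, (a,), backward)


def matmul(a, b):
    a, b = as_tensor(a), as_tensor(b)
    out_data = a.data @ b.data

    def backward(g):
        if a.requires_grad:
            a._accum(g @ b.data.T)
        if b.requires_grad:
            b._accum(a.data.T @ g)

    return Tensor._result(out_data, (a, b), backward)


def transpose(a):
    a = as_tensor(a)

    def backward(g):
        if a.requires_grad:
            a._accum(g.T)

    return Tensor._result(a.data.T, (a,), backward)


# ---------------------------------------------------------------------------
# elementwise nonlinearities


def exp(a):
    a = as_tensor(a)
    out_data = np.exp(a.data)

    def backward(g):
        if a.requires_grad:
            a._accum(g * out_data)

    return Tensor._result(out_data, (a,), backward)


def log(a):
    a = as_tensor(a)
    out_data = np.log(a.data)

    def backward(g):
        if a.requires_grad:
            a._accum(g / a.data)

    return Tensor._result(out_data, (a,), backward)


def tanh(a):
    a = as_tensor(a)
    out_data = np.tanh(a.data)

    def backward(g):
        if a.requires_grad:
            a._accum(g * (1.0 - out_data**2))

    return Tensor._result(out_data, (a,), backward)


def sigmoid(a):
    a = as_tensor(a)
    out_data = special.expit(a.data)

    def backward(g):
        if a.requires_grad:
            a._accum(g * out_data * (1.0 - out_data))

    return Tensor._result(out_data, (a,), backward)


def relu(a):
    a = as_tensor(a)
    mask = a.data > 0
    out_data = np.where(mask, a.data, 0.0)

    def backward(g):
        if a.requires_grad:
            a._accum(g * mask)

    return Tensor._result(out_data, (a,), backward)


def softplus(a):
    a = as_tensor(a)
    out_data = np.logaddexp(0.0, a.data)

    def backward(g):
        if a.requires_grad:
            a._accum(g * special.expit(a.data))

    return Tensor._result(out_data, (a,), backward)


def gammaln(a):
    a = as_tensor(a)
    out_data = special.gammaln(a.data)

    def backward(g):
        if a.requires_grad:
            a._accum(g * special.digamma(a.data))

    return Tensor._result(out_data, (a,), backward)


def sqrt(a):
    return power(a, 0.5)


def square(a):
    return power(a, 2.0)


def maximum(a, b):
    a, b = as_tensor(a), as_tensor(b)
    mask = a.data >= b.data
    out_data = np.where(mask, a.data, b.data)

    def backward(g):
        if a.requires_grad:
            a._accum(_unbroadcast(g * mask, a.data.shape))
        if b.requires_grad:
            b._accum(_unbroadcast(g * ~mask, b.data.shape))

    return Tensor._result(out_data, (a, b), backward)


def minimum(a, b):
    a, b = as_tensor(a), as_tensor(b)
    mask = a.data <= b.data
    out_data = np.where(mask, a.data, b.data)

    def backward(g):
        if a.requires_grad:
            a._accum(_unbroadcast(g * mask, a.data.shape))
        if b.requires_grad:
            b._accum(_unbroadcast(g * ~mask, b.data.shape))

    return Tensor._result(out_data, (a, b), backward)


def where(cond, a, b):
    """Select; `cond` is a constant boolean array (no gradient)."""
    cond = np.asarray(cond, dtype=bool)
    a, b = as_tensor(a), as_tensor(b)
    out_data = np.where(cond, a.data, b.data)

    def backward(g):
        if a.requires_grad:
            a._accum(_unbroadcast(g * cond, a.data.shape))
        if b.requires_grad:
            b._accum(_unbroadcast(g * ~cond, b.data.shape))

    return Tensor._result(out_data, (a, b), backward)


def logaddexp(a, b):
    """Stable log(exp(a) + exp(b)) with gradients."""
    a, b = as_tensor(a), as_tensor(b)
    out_data = np.logaddexp(a.data, b.data)

    def backward(g):
        if a.requires_grad:
            a._accum(_unbroadcast(g * np.exp(a.data - out_data), a.data.shape))
        if b.requires_grad:
            b._accum(_unbroadcast(g * np.exp(b.data - out_data), b.data.shape))

    return Tensor._result(out_data, (a, b), backward)


def logsigmoid(a):
    """log(sigmoid(a)) = -softplus(-a), numerically stable."""
    return mul(softplus(mul(a, -1.0)), -1.0)


# ---------------------------------------------------------------------------
# reductions / indexing


def tsum(a, axis=None, keepdims: bool = False):
    a = as_tensor(a)
    out_data = a.data.sum(axis=axis, keepdims=keepdims)

    def backward(g):
        if not a.requires_grad:
            return
        g = np.asarray(g)
        if axis is None:
            a._accum(np.broadcast_to(g, a.data.shape).copy())
        else:
            if not keepdims:
                g = np.expand_dims(g, axis)
            a._accum(np.broadcast_to(g, a.data.shape).copy())

    return Tensor._result(out_data, (a,), backward)


def tmean(a, axis=None, keepdims: bool = False):
    a = as_tensor(a)
    n = a.data.size if axis is None else a.data.shape[axis]
    return div(tsum(a, axis=axis, keepdims=keepdims), float(n))


def take_rows(a, idx):
    """Gather rows a[idx]; scatter-add on the way back."""
    a = as_tensor(a)
    idx = np.asarray(idx, dtype=np.intp)
    out_data = a.data[idx]

    def backward(g):
        if a.requires_grad:
            acc = np.zeros_like(a.data)
            np.add.at(acc, idx, g)
            a._accum(acc)

    return Tensor._result(out_data, (a,), backward)


def spmm(values, rows, cols, shape, dense):
    """Sparse @ dense where the sparse matrix has fixed pattern (rows, cols).

    `values` may be a trainable Tensor: gradients flow both into the per-entry
    values and into the dense right-hand side.
    """
    values, dense = as_tensor(values), as_tensor(dense)
    rows = np.asarray(rows, dtype=np.intp)
    cols = np.asarray(cols, dtype=np.intp)
    S = sp.csr_matrix((values.data, (rows, cols)), shape=shape)
    out_data = S @ dense.data

    def backward(g):
        if values.requires_grad:
            values._accum((g[rows] * dense.data[cols]).sum(axis=1))
        if dense.requires_grad:
            dense._accum(S.T @ g)

    return Tensor._result(out_data, (values, dense), backward)


def row_normalize(a, eps: float = 1e-12):
    """L2-normalize rows; zero rows map to zero vectors."""
    norm = sqrt(add(tsum(square(a), axis=1, keepdims=True), eps))
    return div(a, norm)


# ---------------------------------------------------------------------------
# parameters and optimization


def glorot(rng: np.random.Generator, fan_in: int, fan_out: int) -> Tensor:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return Tensor(rng.uniform(-limit, limit, size=(fan_in, fan_out)), requires_grad=True)


class Adam:
    """Adam with optional L2 weight decay (added to the gradient)."""

    def __init__(self, params, lr=1e-3, betas=(0.9, 0.999), eps=1e-8, weight_decay=0.0):
        self.params = [p for p in params if p.requires_grad]
        self.lr = float(lr)
        self.b1, self.b2 = betas
        self.eps = float(eps)
        self.weight_decay = float(weight_decay)
        self.t = 0
        self._m = [np.zeros_like(p.data) for p in self.params]
        self._v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self):
        for p in self.params:
            p.grad = None

    def step(self):
        self.t += 1
        for p, m, v in zip(self.params, self._m, self._v):
            if p.grad is None:
                continue
            g = p.grad
            if self.weight_decay:
                g = g + self.weight_decay * p.data
            m *= self.b1
            m += (1.0 - self.b1) * g
            v *= self.b2
            v += (1.0 - self.b2) * g * g
            mhat = m / (1.0 - self.b1**self.t)
            vhat = v / (1.0 - self.b2**self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
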