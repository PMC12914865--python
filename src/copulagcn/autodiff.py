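"""Minimal reverse-mode automatic differentiation on NumPy arrays.

Supports exactly the operations the training objective needs: dense and
sparse matrix products, elementwise nonlinearities, gathers/scatters and
reductions, plus custom ops with hand-derived gradients (the Poisson
distributional transform and the copula loss register themselves through
:class:`Op`). Shapes follow NumPy broadcasting for + and *; gradients of
broadcast operands are summed back to the operand shape.
"""

from __future__ import annotations

import numpy as np
import scipy.sparse
import scipy.special


class Tensor:
    """Array node in the computation graph."""

    __slots__ = ("value", "grad", "requires_grad", "_parents", "_backward")
    __array_priority__ = 100  # so ndarray + Tensor dispatches here

    def __init__(self, value, requires_grad: bool = False):
        self.value = np.asarray(value, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad
        self._parents: tuple[Tensor, ...] = ()
        self._backward = None

    @property
    def shape(self):
        return self.value.shape

    def _accumulate(self, g: np.ndarray) -> None:
        g = _unbroadcast(np.asarray(g, dtype=np.float64), self.value.shape)
        if self.grad is None:
            self.grad = g.copy()
        else:
            self.grad += g

    def backward(self, grad=None) -> None:
        """Reverse-mode sweep from this node (default seed: ones)."""
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
                if id(p) not in seen:
                    stack.append((p, False))
        self._accumulate(np.ones_like(self.value) if grad is None else grad)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    # -- operator sugar -------------------------------------------------
    def __add__(self, other):
        return add(self, other)

    __radd__ = __add__

    def __mul__(self, other):
        return mul(self, other)

    __rmul__ = __mul__

    def __sub__(self, other):
        return add(self, mul(other, -1.0))

    def __rsub__(self, other):
        return add(mul(self, -1.0), other)

    def __neg__(self):
        return mul(self, -1.0)

    def __matmul__(self, other):
        return matmul(self, other)

    def __truediv__(self, other):
        if isinstance(other, Tensor):
            return mul(self, power(other, -1.0))
        return mul(self, 1.0 / other)


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def _unbroadcast(g: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum gradient over axes introduced or expanded by broadcasting."""
    if g.shape == shape:
        return g
    extra = g.ndim - len(shape)
    if extra > 0:
        g = g.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and g.shape[i] != 1)
    if axes:
        g = g.sum(axis=axes, keepdims=True)
    return g.reshape(shape)


def _make(value, parents, backward) -> Tensor:
    out = Tensor(value)
    if any(p.requires_grad or p._parents for p in parents):
        out.requires_grad = True
        out._parents = tuple(parents)
        out._backward = backward
    return out


# -- primitive ops -------------------------------------------------------

def add(a, b) -> Tensor:
    a, b = as_tensor(a), as_tensor(b)
    def bwd(g):
        a._accumulate(g)
        b._accumulate(g)
    return _make(a.value + b.value, (a, b), bwd)


def mul(a, b) -> Tensor:
    a, b = as_tensor(a), as_tensor(b)
    def bwd(g):
        a._accumulate(g * b.value)
        b._accumulate(g * a.value)
    return _make(a.value * b.value, (a, b), bwd)


def power(a, p: float) -> Tensor:
    a = as_tensor(a)
    def bwd(g):
        a._accumulate(g * p * a.value ** (p - 1))
    return _make(a.value ** p, (a,), bwd)


def matmul(a, b) -> Tensor:
    a, b = as_tensor(a), as_tensor(b)
    def bwd(g):
        a._accumulate(g @ b.value.T)
        b._accumulate(a.value.T @ g)
    return _make(a.value @ b.value, (a, b), bwd)


def sparse_matmul(s: scipy.sparse.spmatrix, b) -> Tensor:
    """Product of a constant sparse matrix with a dense tensor."""
    b = as_tensor(b)
    st = s.T.tocsr()
    def bwd(g):
        b._accumulate(st @ g)
    return _make(s @ b.value, (b,), bwd)


def relu(a) -> Tensor:
    a = as_tensor(a)
    mask = a.value > 0
    def bwd(g):
        a._accumulate(g * mask)
    return _make(a.value * mask, (a,), bwd)


def tanh(a) -> Tensor:
    a = as_tensor(a)
    t = np.tanh(a.value)
    def bwd(g):
        a._accumulate(g * (1 - t * t))
    return _make(t, (a,), bwd)


def sigmoid(a) -> Tensor:
    a = as_tensor(a)
    s = scipy.special.expit(a.value)
    def bwd(g):
        a._accumulate(g * s * (1 - s))
    return _make(s, (a,), bwd)


def softplus(a) -> Tensor:
    """log(1 + e^x), computed overflow-safe; derivative is the sigmoid."""
    a = as_tensor(a)
    s = scipy.special.expit(a.value)
    def bwd(g):
        a._accumulate(g * s)
    return _make(np.logaddexp(0.0, a.value), (a,), bwd)


def log(a) -> Tensor:
    a = as_tensor(a)
    def bwd(g):
        a._accumulate(g / a.value)
    return _make(np.log(a.value), (a,), bwd)


def exp(a) -> Tensor:
    a = as_tensor(a)
    e = np.exp(a.value)
    def bwd(g):
        a._accumulate(g * e)
    return _make(e, (a,), bwd)


def clip(a, lo: float, hi: float) -> Tensor:
    """Clamp values; gradient passes only through the interior."""
    a = as_tensor(a)
    mask = (a.value > lo) & (a.value < hi)
    def bwd(g):
        a._accumulate(g * mask)
    return _make(np.clip(a.value, lo, hi), (a,), bwd)


def total(a) -> Tensor:
    a = as_tensor(a)
    def bwd(g):
        a._accumulate(np.broadcast_to(g, a.value.shape))
    return _make(a.value.sum(), (a,), bwd)


def mean(a) -> Tensor:
    a = as_tensor(a)
    n = a.value.size
    def bwd(g):
        a._accumulate(np.broadcast_to(g / n, a.value.shape))
    return _make(a.value.mean(), (a,), bwd)


def take_rows(a, index: np.ndarray) -> Tensor:
    """Row gather; duplicate indices accumulate in the gradient.

    The scatter-add in the backward pass runs through a cached sparse
    selection matrix (much faster than np.add.at for repeated use).
    """
    a = as_tensor(a)
    index = np.asarray(index, dtype=np.int64)
    n_rows = a.value.shape[0]
    sel = scipy.sparse.csr_matrix(
        (np.ones(len(index)), (np.arange(len(index)), index)),
        shape=(len(index), n_rows)).T.tocsr()
    def bwd(g):
        a._accumulate(sel @ g)
    return _make(a.value[index], (a,), bwd)


def reshape(a, shape) -> Tensor:
    a = as_tensor(a)
    old = a.value.shape
    def bwd(g):
        a._accumulate(g.reshape(old))
    return _make(a.value.reshape(shape), (a,), bwd)


def concat_cols(a, b) -> Tensor:
    a, b = as_tensor(a), as_tensor(b)
    na = a.value.shape[1]
    def bwd(g):
        a._accumulate(g[:, :na])
        b._accumulate(g[:, na:])
    return _make(np.concatenate([a.value, b.value], axis=1), (a, b), bwd)


class Op:
    """Base for custom differentiable operations.

    Subclasses implement ``forward(*values) -> value`` (may stash
    intermediates on self) and ``backward(grad) -> tuple-of-grads`` (one
    per input, None for non-differentiable inputs).
    """

    def __call__(self, *inputs) -> Tensor:
        tensors = [as_tensor(x) for x in inputs]
        value = self.forward(*[t.value for t in tensors])
        def bwd(g):
            grads = self.backward(g)
            for t, gr in zip(tensors, grads):
                if gr is not None:
                    t._accumulate(gr)
        return _make(value, tuple(tensors), bwd)

    def forward(self, *values):  # pragma: no cover - interface
        raise NotImplementedError

    def backward(self, grad):  # pragma: no cover - interface
        raise NotImplementedError


class Adam:
    """Adam optimizer over a list of Tensors (full-batch use)."""

    def __init__(self, params: list[Tensor], lr: float = 0.01,
                 betas=(0.9, 0.999), eps: float = 1e-8,
                 weight_decay: float = 0.0):
        self.params = params
        self.lr, self.betas, self.eps = lr, betas, eps
        self.weight_decay = weight_decay
        self.m = [np.zeros_like(p.value) for p in params]
        self.v = [np.zeros_like(p.value) for p in params]
        self.t = 0

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.betas
        for i, p in enumerate(self.params):
            g = p.grad if p.grad is not None else np.zeros_like(p.value)
            if self.weight_decay:
                g = g + self.weight_decay * p.value
            self.m[i] = b1 * self.m[i] + (1 - b1) * g
            self.v[i] = b2 * self.v[i] + (1 - b2) * g * g
            mhat = self.m[i] / (1 - b1 ** self.t)
            vhat = self.v[i] / (1 - b2 ** self.t)
            p.value -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
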