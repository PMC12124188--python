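"""Minimal reverse-mode automatic differentiation on NumPy arrays.

Only the operations needed by the transformer encoder and the contrastive
loss are implemented: elementwise arithmetic with broadcasting, matmul
(including batched), exp/log/sqrt/tanh, reductions, reshape/transpose,
concatenation and row gather (embedding lookup). All data is float64.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "concat", "take_rows", "softmax"]


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum `grad` down to `shape` (inverse of NumPy broadcasting)."""
    if grad.shape == shape:
        return grad
    # sum leading extra axes
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


class Tensor:
    """An array node in the computation graph."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False, parents=(), backward=None):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad = None
        self.requires_grad = bool(requires_grad)
        self._parents = parents
        self._backward = backward

    # -- helpers ------------------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    @staticmethod
    def _lift(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(x)

    def _make(self, data, parents, backward) -> "Tensor":
        req = any(p.requires_grad for p in parents)
        return Tensor(data, requires_grad=req,
                      parents=tuple(p for p in parents if p.requires_grad),
                      backward=backward if req else None)

    # -- arithmetic ---------------------------------------------------------
    def __add__(self, other):
        other = self._lift(other)
        out_data = self.data + other.data

        def backward(g):
            return (_unbroadcast(g, self.shape), _unbroadcast(g, other.shape))

        return self._binary(other, out_data, backward)

    def _binary(self, other, out_data, backward):
        parents = (self, other)
        req = self.requires_grad or other.requires_grad
        if not req:
            return Tensor(out_data)

        def bw(g, _parents=parents, _f=backward):
            grads = _f(g)
            out: dict = {}
            for p, gr in zip(_parents, grads):
                if not p.requires_grad:
                    continue
                if p in out:  # same tensor used for both operands
                    out[p] = out[p] + gr
                else:
                    out[p] = gr
            return out

        return Tensor(out_data, requires_grad=True,
                      parents=tuple(p for p in parents if p.requires_grad),
                      backward=bw)

    def _unary(self, out_data, grad_fn):
        if not self.requires_grad:
            return Tensor(out_data)

        def bw(g):
            return {self: grad_fn(g)}

        return Tensor(out_data, requires_grad=True, parents=(self,), backward=bw)

    __radd__ = __add__

    def __neg__(self):
        return self._unary(-self.data, lambda g: -g)

    def __sub__(self, other):
        return self + (-self._lift(other))

    def __rsub__(self, other):
        return self._lift(other) + (-self)

    def __mul__(self, other):
        other = self._lift(other)
        out_data = self.data * other.data

        def backward(g):
            return (_unbroadcast(g * other.data, self.shape),
                    _unbroadcast(g * self.data, other.shape))

        return self._binary(other, out_data, backward)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = self._lift(other)
        out_data = self.data / other.data

        def backward(g):
            return (_unbroadcast(g / other.data, self.shape),
                    _unbroadcast(-g * out_data / other.data, other.shape))

        return self._binary(other, out_data, backward)

    def __rtruediv__(self, other):
        return self._lift(other) * self ** -1.0

    def __pow__(self, p: float):
        out_data = self.data ** p
        return self._unary(out_data, lambda g: g * p * self.data ** (p - 1.0))

    def __matmul__(self, other):
        other = self._lift(other)
        out_data = self.data @ other.data

        def backward(g):
            a, b = self.data, other.data
            if a.ndim == 1 or b.ndim == 1:  # not used in the model; keep simple
                raise NotImplementedError("matmul backward requires ndim >= 2")
            ga = _unbroadcast(g @ np.swapaxes(b, -1, -2), a.shape)
            gb = _unbroadcast(np.swapaxes(a, -1, -2) @ g, b.shape)
            return (ga, gb)

        return self._binary(other, out_data, backward)

    # -- elementwise functions ----------------------------------------------
    def exp(self):
        out = np.exp(self.data)
        return self._unary(out, lambda g: g * out)

    def log(self):
        return self._unary(np.log(self.data), lambda g: g / self.data)

    def sqrt(self):
        out = np.sqrt(self.data)
        return self._unary(out, lambda g: g * 0.5 / out)

    def tanh(self):
        out = np.tanh(self.data)
        return self._unary(out, lambda g: g * (1.0 - out * out))

    def gelu(self):
        """GELU, tanh approximation, with a fused closed-form derivative."""
        x = self.data
        c = np.sqrt(2.0 / np.pi)
        u = c * (x + 0.044715 * x ** 3)
        t = np.tanh(u)
        out = 0.5 * x * (1.0 + t)

        def grad_fn(g):
            du = c * (1.0 + 3 * 0.044715 * x ** 2)
            return g * (0.5 * (1.0 + t) + 0.5 * x * (1.0 - t * t) * du)

        return self._unary(out, grad_fn)

    def softmax(self, axis: int = -1):
        """Numerically stable softmax with fused backward."""
        shifted = self.data - self.data.max(axis=axis, keepdims=True)
        e = np.exp(shifted)
        out = e / e.sum(axis=axis, keepdims=True)

        def grad_fn(g):
            dot = (g * out).sum(axis=axis, keepdims=True)
            return (g - dot) * out

        return self._unary(out, grad_fn)

    def layernorm(self, eps: float = 1e-5):
        """Standardize the last axis: (x - mean) / sqrt(var + eps)."""
        mu = self.data.mean(axis=-1, keepdims=True)
        xc = self.data - mu
        inv = 1.0 / np.sqrt((xc * xc).mean(axis=-1, keepdims=True) + eps)
        xhat = xc * inv

        def grad_fn(g):
            m1 = g.mean(axis=-1, keepdims=True)
            m2 = (g * xhat).mean(axis=-1, keepdims=True)
            return inv * (g - m1 - xhat * m2)

        return self._unary(xhat, grad_fn)

    # -- reductions ----------------------------------------------------------
    def sum(self, axis=None, keepdims=False):
        out = self.data.sum(axis=axis, keepdims=keepdims)

        def grad_fn(g):
            g = np.asarray(g)
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            return np.broadcast_to(g, self.shape)

        return self._unary(out, grad_fn)

    def mean(self, axis=None, keepdims=False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    # -- shape ops -----------------------------------------------------------
    def reshape(self, *shape):
        old = self.shape
        return self._unary(self.data.reshape(*shape), lambda g: g.reshape(old))

    def transpose(self, *axes):
        inv = np.argsort(axes)
        return self._unary(self.data.transpose(axes),
                           lambda g: g.transpose(tuple(inv)))

    # -- autodiff ------------------------------------------------------------
    def backward(self, grad=None):
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without grad requires a scalar")
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
        grads = {id(self): np.asarray(grad, dtype=np.float64)}
        for t in reversed(topo):
            g = grads.pop(id(t), None)
            if g is None:
                continue
            # grads are never mutated in place, so sharing is safe
            t.grad = g if t.grad is None else t.grad + g
            if t._backward is None:
                continue
            for parent, pg in t._backward(g).items():
                key = id(parent)
                if key in grads:
                    grads[key] = grads[key] + pg
                else:
                    grads[key] = pg
        # leaves keep .grad; interior nodes' grads are also retained in .grad,
        # which is harmless (graphs are rebuilt every step).

    def item(self) -> float:
        return float(self.data)


def concat(tensors, axis: int = 0) -> Tensor:
    """Concatenate tensors along `axis`, differentiable."""
    tensors = [Tensor._lift(t) for t in tensors]
    out_data = np.concatenate([t.data for t in tensors], axis=axis)
    req = [t for t in tensors if t.requires_grad]
    if not req:
        return Tensor(out_data)
    sizes = [t.data.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def bw(g):
        pieces = np.split(g, splits, axis=axis)
        return {t: p for t, p in zip(tensors, pieces) if t.requires_grad}

    return Tensor(out_data, requires_grad=True, parents=tuple(req), backward=bw)


def take_rows(table: Tensor, ids: np.ndarray) -> Tensor:
    """Embedding lookup: gather rows of `table` by an integer index array."""
    ids = np.asarray(ids)
    out_data = table.data[ids]
    if not table.requires_grad:
        return Tensor(out_data)

    def bw(g):
        gt = np.zeros_like(table.data)
        np.add.at(gt, ids, g)
        return {table: gt}

    return Tensor(out_data, requires_grad=True, parents=(table,), backward=bw)


def softmax(x: Tensor, axis: int = -1) -> Tensor:
    return x.softmax(axis=axis)
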