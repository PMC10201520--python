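"""Minimal reverse-mode automatic differentiation on NumPy arrays.

Implements exactly the operator set the sequence model and the RBM latent
machinery need: broadcast-aware arithmetic, (batched) matmul, slicing,
concatenation, reductions, the usual pointwise nonlinearities, and an
embedding gather.  Gradients are accumulated in float64 throughout.
"""

from __future__ import annotations

import numpy as np
from scipy.special import erf

__all__ = ["Tensor", "concat", "where", "embedding", "as_tensor"]


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum `grad` down to `shape` (inverse of NumPy broadcasting)."""
    if grad.shape == shape:
        return grad
    # sum over prepended axes
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


class Tensor:
    """A NumPy array with an optional gradient and a backward closure."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad = None
        self.requires_grad = bool(requires_grad)
        self._backward = None
        self._parents: tuple = ()

    # ---- construction helpers -------------------------------------------
    @staticmethod
    def _make(data, parents, backward):
        out = Tensor(data)
        if any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._parents = tuple(parents)
            out._backward = backward
        return out

    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def detach(self) -> "Tensor":
        return Tensor(self.data.copy())

    def item(self) -> float:
        return float(self.data)

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    # ---- arithmetic ------------------------------------------------------
    def __add__(self, other):
        other = as_tensor(other)
        out_data = self.data + other.data

        def backward(g):
            return (_unbroadcast(g, self.data.shape),
                    _unbroadcast(g, other.data.shape))

        return Tensor._make(out_data, (self, other), backward)

    __radd__ = __add__

    def __neg__(self):
        return Tensor._make(-self.data, (self,), lambda g: (-g,))

    def __sub__(self, other):
        return self + (-as_tensor(other))

    def __rsub__(self, other):
        return as_tensor(other) + (-self)

    def __mul__(self, other):
        other = as_tensor(other)
        out_data = self.data * other.data

        def backward(g):
            return (_unbroadcast(g * other.data, self.data.shape),
                    _unbroadcast(g * self.data, other.data.shape))

        return Tensor._make(out_data, (self, other), backward)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = as_tensor(other)
        out_data = self.data / other.data

        def backward(g):
            return (_unbroadcast(g / other.data, self.data.shape),
                    _unbroadcast(-g * self.data / other.data ** 2,
                                 other.data.shape))

        return Tensor._make(out_data, (self, other), backward)

    def __rtruediv__(self, other):
        return as_tensor(other) / self

    def __pow__(self, p: float):
        out_data = self.data ** p

        def backward(g):
            return (g * p * self.data ** (p - 1),)

        return Tensor._make(out_data, (self,), backward)

    def __matmul__(self, other):
        other = as_tensor(other)
        out_data = self.data @ other.data
        a, b = self.data, other.data

        def backward(g):
            if a.ndim == 1 and b.ndim == 1:
                ga, gb = g * b, g * a
            elif a.ndim == 1:      # (k,) @ (..., k, n)
                ga = _unbroadcast(np.swapaxes(b, -1, -2) @ g, a.shape)
                gb = _unbroadcast(a[..., :, None] * g[..., None, :], b.shape)
            elif b.ndim == 1:      # (..., m, k) @ (k,)
                ga = _unbroadcast(g[..., :, None] * b[None, :], a.shape)
                gb = _unbroadcast(np.swapaxes(a, -1, -2) @ g, b.shape)
            else:
                ga = _unbroadcast(g @ np.swapaxes(b, -1, -2), a.shape)
                gb = _unbroadcast(np.swapaxes(a, -1, -2) @ g, b.shape)
            return ga, gb

        return Tensor._make(out_data, (self, other), backward)

    # ---- pointwise nonlinearities ---------------------------------------
    def exp(self):
        out_data = np.exp(self.data)
        return Tensor._make(out_data, (self,), lambda g: (g * out_data,))

    def log(self):
        return Tensor._make(np.log(self.data), (self,),
                            lambda g: (g / self.data,))

    def sqrt(self):
        out_data = np.sqrt(self.data)
        return Tensor._make(out_data, (self,),
                            lambda g: (g * 0.5 / out_data,))

    def tanh(self):
        out_data = np.tanh(self.data)
        return Tensor._make(out_data, (self,),
                            lambda g: (g * (1.0 - out_data ** 2),))

    def sigmoid(self):
        out_data = np.empty_like(self.data)
        pos = self.data >= 0
        out_data[pos] = 1.0 / (1.0 + np.exp(-self.data[pos]))
        e = np.exp(self.data[~pos])
        out_data[~pos] = e / (1.0 + e)
        return Tensor._make(out_data, (self,),
                            lambda g: (g * out_data * (1.0 - out_data),))

    def gelu(self):
        x = self.data
        phi = 0.5 * (1.0 + erf(x / np.sqrt(2.0)))
        out_data = x * phi

        def backward(g):
            pdf = np.exp(-0.5 * x ** 2) / np.sqrt(2.0 * np.pi)
            return (g * (phi + x * pdf),)

        return Tensor._make(out_data, (self,), backward)

    def relu(self):
        mask = self.data > 0
        return Tensor._make(self.data * mask, (self,), lambda g: (g * mask,))

    # ---- reductions ------------------------------------------------------
    def sum(self, axis=None, keepdims: bool = False):
        out_data = self.data.sum(axis=axis, keepdims=keepdims)
        shape = self.data.shape

        def backward(g):
            if axis is None:
                return (np.broadcast_to(g, shape).astype(np.float64),)
            g2 = g
            if not keepdims:
                g2 = np.expand_dims(g, axis)
            return (np.broadcast_to(g2, shape).astype(np.float64),)

        return Tensor._make(out_data, (self,), backward)

    def mean(self, axis=None, keepdims: bool = False):
        if axis is None:
            n = self.data.size
        else:
            n = self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    # ---- shape manipulation ---------------------------------------------
    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        old = self.data.shape
        return Tensor._make(self.data.reshape(shape), (self,),
                            lambda g: (g.reshape(old),))

    def transpose(self, *axes):
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        inv = np.argsort(axes)
        return Tensor._make(self.data.transpose(axes), (self,),
                            lambda g: (g.transpose(inv),))

    def swapaxes(self, a: int, b: int):
        return Tensor._make(np.swapaxes(self.data, a, b), (self,),
                            lambda g: (np.swapaxes(g, a, b),))

    def __getitem__(self, idx):
        out_data = self.data[idx]
        shape = self.data.shape

        def backward(g):
            gx = np.zeros(shape, dtype=np.float64)
            np.add.at(gx, idx, g)
            return (gx,)

        return Tensor._make(out_data, (self,), backward)

    def pad(self, pad_width):
        """Zero padding; `pad_width` as for np.pad."""
        out_data = np.pad(self.data, pad_width)
        slices = tuple(slice(b, b + n) for (b, _), n
                       in zip(pad_width, self.data.shape))
        return Tensor._make(out_data, (self,), lambda g: (g[slices],))

    # ---- composites ------------------------------------------------------
    def softmax(self, axis: int = -1):
        m = self.data.max(axis=axis, keepdims=True)
        e = (self - m).exp()
        return e / e.sum(axis=axis, keepdims=True)

    def log_softmax(self, axis: int = -1):
        m = self.data.max(axis=axis, keepdims=True)
        shifted = self - m
        lse = shifted.exp().sum(axis=axis, keepdims=True).log()
        return shifted - lse

    # ---- backward pass ---------------------------------------------------
    def backward(self, grad=None):
        if not self.requires_grad:
            raise ValueError("backward() on a tensor that requires no grad")
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without grad requires a scalar")
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        visited = set()
        stack = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in visited:
                continue
            visited.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                if id(p) not in visited and p.requires_grad:
                    stack.append((p, False))
        grads = {id(self): np.asarray(grad, dtype=np.float64)}
        for node in reversed(topo):
            g = grads.pop(id(node), None)
            if g is None:
                continue
            if node._backward is None:
                if node.grad is None:
                    node.grad = np.zeros_like(node.data)
                node.grad = node.grad + g
                continue
            for p, gp in zip(node._parents, node._backward(g)):
                if not p.requires_grad or gp is None:
                    continue
                if id(p) in grads:
                    grads[id(p)] = grads[id(p)] + gp
                else:
                    grads[id(p)] = gp


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def concat(tensors, axis: int = 0) -> Tensor:
    tensors = [as_tensor(t) for t in tensors]
    out_data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def backward(g):
        return tuple(
            np.take(g, range(offsets[i], offsets[i + 1]), axis=axis)
            for i in range(len(tensors)))

    return Tensor._make(out_data, tuple(tensors), backward)


def where(cond, a, b) -> Tensor:
    """Elementwise select; `cond` is a constant boolean array."""
    cond = np.asarray(cond, dtype=bool)
    a, b = as_tensor(a), as_tensor(b)
    out_data = np.where(cond, a.data, b.data)

    def backward(g):
        return (_unbroadcast(np.where(cond, g, 0.0), a.data.shape),
                _unbroadcast(np.where(cond, 0.0, g), b.data.shape))

    return Tensor._make(out_data, (a, b), backward)


def embedding(weight: Tensor, ids) -> Tensor:
    """Row gather: `weight[ids]` with scatter-add backward."""
    ids = np.asarray(ids, dtype=np.int64)
    out_data = weight.data[ids]
    shape = weight.data.shape

    def backward(g):
        gw = np.zeros(shape, dtype=np.float64)
        np.add.at(gw, ids.reshape(-1),
                  g.reshape(-1, shape[-1]))
        return (gw,)

    return Tensor._make(out_data, (weight,), backward)
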