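"""Reverse-mode automatic differentiation on numpy arrays.

A small define-by-run engine in the micrograd style, but operating on whole
ndarrays with broadcasting-aware backward rules.  It exists because every
learnable component of this package (hash-encoded implicit networks, the
convolutional proximal operator, learnable step sizes) needs gradients of a
scalar self-supervised loss, and the computations are modest enough that
vectorized numpy is adequate.

Only the operations the package actually uses are implemented.  Gradients are
accumulated into ``Tensor.grad`` by :func:`backward`; graphs are single-use.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "as_tensor", "custom_op", "concat", "stack", "where"]


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum `grad` over axes that were broadcast to reach `grad.shape`."""
    if grad.shape == shape:
        return grad
    # sum leading extra axes
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, s in enumerate(shape):
        if s == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    """An ndarray node in the computation graph."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents", "name")

    # make `ndarray <op> Tensor` delegate to Tensor.__r<op>__
    __array_ufunc__ = None

    def __init__(self, data, requires_grad: bool = False, name: str = ""):
        self.data = np.asarray(data)
        self.grad = None
        self.requires_grad = bool(requires_grad)
        self._backward = None
        self._parents: tuple = ()
        self.name = name

    # ---- basic introspection -------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    @property
    def size(self):
        return self.data.size

    @property
    def dtype(self):
        return self.data.dtype

    def item(self):
        return self.data.item()

    def numpy(self):
        return self.data

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def zero_grad(self):
        self.grad = None

    def __repr__(self):
        tag = f" name={self.name!r}" if self.name else ""
        return f"Tensor(shape={self.data.shape}, dtype={self.data.dtype}{tag})"

    # ---- graph plumbing -------------------------------------------------
    def _accumulate(self, g):
        if self.grad is None:
            self.grad = np.array(g, dtype=self.data.dtype, copy=True)
        else:
            self.grad += g

    def backward(self, grad=None):
        """Backpropagate from this (typically scalar) tensor."""
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without argument requires a scalar")
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
                if id(p) not in visited:
                    stack.append((p, False))
        self._accumulate(grad)
        for node in reversed(topo):
            if node._backward is None or node.grad is None:
                continue
            grads = node._backward(node.grad)
            for parent, g in zip(node._parents, grads):
                if g is None:
                    continue
                if isinstance(parent, Tensor) and (parent.requires_grad or parent._parents):
                    parent._accumulate(_unbroadcast(np.asarray(g), parent.data.shape))

    # ---- arithmetic ------------------------------------------------------
    # python scalars take a fast path (single parent, no dtype promotion)

    def __add__(self, other):
        if isinstance(other, (int, float)):
            out = _node(self.data + other, (self,))
            out._backward = lambda g: (g,)
            return out
        other = as_tensor(other)
        out = _node(self.data + other.data, (self, other))
        out._backward = lambda g: (g, g)
        return out

    __radd__ = __add__

    def __sub__(self, other):
        if isinstance(other, (int, float)):
            return self + (-other)
        other = as_tensor(other)
        out = _node(self.data - other.data, (self, other))
        out._backward = lambda g: (g, -g)
        return out

    def __rsub__(self, other):
        if isinstance(other, (int, float)):
            out = _node(other - self.data, (self,))
            out._backward = lambda g: (-g,)
            return out
        return as_tensor(other) - self

    def __neg__(self):
        out = _node(-self.data, (self,))
        out._backward = lambda g: (-g,)
        return out

    def __mul__(self, other):
        if isinstance(other, (int, float)):
            out = _node(self.data * other, (self,))
            out._backward = lambda g: (g * other,)
            return out
        other = as_tensor(other)
        out = _node(self.data * other.data, (self, other))
        a, b = self.data, other.data
        out._backward = lambda g: (g * b, g * a)
        return out

    __rmul__ = __mul__

    def __truediv__(self, other):
        if isinstance(other, (int, float)):
            return self * (1.0 / other)
        other = as_tensor(other)
        out = _node(self.data / other.data, (self, other))
        a, b = self.data, other.data
        out._backward = lambda g: (g / b, -g * a / (b * b))
        return out

    def __rtruediv__(self, other):
        if isinstance(other, (int, float)):
            out = _node(other / self.data, (self,))
            a = self.data
            out._backward = lambda g: (-g * other / (a * a),)
            return out
        return as_tensor(other) / self

    def __pow__(self, p):
        if not np.isscalar(p):
            raise TypeError("only scalar exponents are supported")
        out = _node(self.data**p, (self,))
        a = self.data
        out._backward = lambda g: (g * p * a ** (p - 1),)
        return out

    def __matmul__(self, other):
        other = as_tensor(other)
        out = _node(self.data @ other.data, (self, other))
        a, b = self.data, other.data

        def bw(g):
            if a.ndim == 2 and b.ndim == 2:
                return g @ b.T, a.T @ g
            raise NotImplementedError("matmul backward only for 2D operands")

        out._backward = bw
        return out

    # ---- elementwise functions ------------------------------------------
    def exp(self):
        out = _node(np.exp(self.data), (self,))
        e = out.data
        out._backward = lambda g: (g * e,)
        return out

    def log(self):
        out = _node(np.log(self.data), (self,))
        a = self.data
        out._backward = lambda g: (g / a,)
        return out

    def sqrt(self):
        out = _node(np.sqrt(self.data), (self,))
        s = out.data
        out._backward = lambda g: (g / (2.0 * s),)
        return out

    def tanh(self):
        out = _node(np.tanh(self.data), (self,))
        t = out.data
        out._backward = lambda g: (g * (1.0 - t * t),)
        return out

    def sigmoid(self):
        out = _node(1.0 / (1.0 + np.exp(-self.data)), (self,))
        s = out.data
        out._backward = lambda g: (g * s * (1.0 - s),)
        return out

    def relu(self):
        out = _node(np.maximum(self.data, 0.0), (self,))
        m = self.data > 0
        out._backward = lambda g: (g * m,)
        return out

    def softplus(self):
        # numerically stable log(1 + e^x)
        out = _node(np.logaddexp(0.0, self.data), (self,))
        s = 1.0 / (1.0 + np.exp(-self.data))
        out._backward = lambda g: (g * s,)
        return out

    def abs(self):
        out = _node(np.abs(self.data), (self,))
        s = np.sign(self.data)
        out._backward = lambda g: (g * s,)
        return out

    def sin(self):
        out = _node(np.sin(self.data), (self,))
        c = np.cos(self.data)
        out._backward = lambda g: (g * c,)
        return out

    def cos(self):
        out = _node(np.cos(self.data), (self,))
        s = -np.sin(self.data)
        out._backward = lambda g: (g * s,)
        return out

    def clip(self, lo, hi):
        out = _node(np.clip(self.data, lo, hi), (self,))
        m = (self.data >= lo) & (self.data <= hi)
        out._backward = lambda g: (g * m,)
        return out

    def astype(self, dtype):
        out = _node(self.data.astype(dtype), (self,))
        orig = self.data.dtype
        out._backward = lambda g: (g.astype(orig),)
        return out

    # ---- reductions / shaping -------------------------------------------
    def sum(self, axis=None, keepdims=False):
        out = _node(self.data.sum(axis=axis, keepdims=keepdims), (self,))
        shape, nd = self.data.shape, self.data.ndim

        def bw(g):
            g = np.asarray(g)
            if axis is None:
                return (np.broadcast_to(g, shape),)
            axes = axis if isinstance(axis, tuple) else (axis,)
            axes = tuple(a % nd for a in axes)
            if not keepdims:
                for a in sorted(axes):
                    g = np.expand_dims(g, a)
            return (np.broadcast_to(g, shape),)

        out._backward = bw
        return out

    def mean(self, axis=None, keepdims=False):
        n = self.data.size if axis is None else np.prod(
            [self.data.shape[a] for a in (axis if isinstance(axis, tuple) else (axis,))]
        )
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(n))

    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        out = _node(self.data.reshape(shape), (self,))
        orig = self.data.shape
        out._backward = lambda g: (g.reshape(orig),)
        return out

    def transpose(self, *axes):
        axes = axes or None
        out = _node(np.transpose(self.data, axes), (self,))
        inv = None if axes is None else tuple(np.argsort(axes))
        out._backward = lambda g: (np.transpose(g, inv),)
        return out

    @property
    def T(self):
        return self.transpose()

    def __getitem__(self, idx):
        out = _node(self.data[idx], (self,))
        shape, dt = self.data.shape, self.data.dtype
        basic = isinstance(idx, (int, slice, type(Ellipsis))) or (
            isinstance(idx, tuple)
            and all(isinstance(i, (int, slice, type(Ellipsis))) for i in idx)
        )

        def bw(g):
            full = np.zeros(shape, dtype=dt)
            if basic:
                full[idx] += g  # basic indexing never aliases
            else:
                np.add.at(full, idx, g)
            return (full,)

        out._backward = bw
        return out


def _node(data, parents) -> Tensor:
    out = Tensor(data)
    out._parents = tuple(p for p in parents)
    return out


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def custom_op(out_data, parents, backward_fn) -> Tensor:
    """Build a graph node with a hand-written backward rule.

    ``backward_fn(out_grad) -> tuple`` must return one (possibly None)
    gradient array per parent.
    """
    out = _node(np.asarray(out_data), tuple(as_tensor(p) for p in parents))
    out._backward = backward_fn
    return out


def concat(tensors, axis=0) -> Tensor:
    tensors = [as_tensor(t) for t in tensors]
    out = _node(np.concatenate([t.data for t in tensors], axis=axis), tuple(tensors))
    sizes = [t.data.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]
    out._backward = lambda g: tuple(np.split(g, splits, axis=axis))
    return out


def stack(tensors, axis=0) -> Tensor:
    tensors = [as_tensor(t) for t in tensors]
    out = _node(np.stack([t.data for t in tensors], axis=axis), tuple(tensors))
    out._backward = lambda g: tuple(
        np.take(g, i, axis=axis) for i in range(len(tensors))
    )
    return out


def where(cond, a, b) -> Tensor:
    """Elementwise select with a boolean (non-differentiable) condition."""
    a, b = as_tensor(a), as_tensor(b)
    c = np.asarray(cond)
    out = _node(np.where(c, a.data, b.data), (a, b))
    out._backward = lambda g: (g * c, g * (~c))
    return out
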