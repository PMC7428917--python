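"""Minimal reverse-mode automatic differentiation over NumPy arrays.

This is the numerical core behind the attention/LSTM models: a tape-based
``Tensor`` supporting the handful of operations the networks need
(broadcast arithmetic, matmul, the usual activations, masked softmax,
embedding lookup, concatenation, reductions and basic indexing).
Gradients are accumulated into ``Tensor.grad`` by :meth:`Tensor.backward`.

The engine is deliberately small — correctness is checked against
finite differences in the test suite rather than against a framework.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "concat", "stack", "embedding", "masked_softmax"]


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (reverses NumPy broadcasting)."""
    if grad.shape == shape:
        return grad
    # sum over leading axes added by broadcasting
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    # sum over axes that were size-1 in the original
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad


def _astensor(x) -> "Tensor":
    return x if isinstance(x, Tensor) else Tensor(np.asarray(x, dtype=float))


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False, parents=(), backward=None):
        self.data = np.asarray(data, dtype=float)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad or any(p.requires_grad for p in parents)
        self._parents = parents
        self._backward = backward

    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    # ------------------------------------------------------------------ #
    # arithmetic

    def __add__(self, other):
        other = _astensor(other)
        out = Tensor(self.data + other.data, parents=(self, other))

        def bw(g):
            return (_unbroadcast(g, self.shape), _unbroadcast(g, other.shape))

        out._backward = bw
        return out

    __radd__ = __add__

    def __neg__(self):
        out = Tensor(-self.data, parents=(self,))
        out._backward = lambda g: (-g,)
        return out

    def __sub__(self, other):
        return self + (-_astensor(other))

    def __rsub__(self, other):
        return _astensor(other) + (-self)

    def __mul__(self, other):
        other = _astensor(other)
        out = Tensor(self.data * other.data, parents=(self, other))

        def bw(g):
            return (
                _unbroadcast(g * other.data, self.shape),
                _unbroadcast(g * self.data, other.shape),
            )

        out._backward = bw
        return out

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = _astensor(other)
        out = Tensor(self.data / other.data, parents=(self, other))

        def bw(g):
            return (
                _unbroadcast(g / other.data, self.shape),
                _unbroadcast(-g * self.data / other.data**2, other.shape),
            )

        out._backward = bw
        return out

    def __pow__(self, p: float):
        out = Tensor(self.data**p, parents=(self,))
        out._backward = lambda g: (g * p * self.data ** (p - 1),)
        return out

    def __matmul__(self, other):
        other = _astensor(other)
        out = Tensor(self.data @ other.data, parents=(self, other))

        def bw(g):
            a, b = self.data, other.data
            if a.ndim == 1 and b.ndim == 1:
                ga, gb = g * b, g * a
            elif b.ndim == 1:
                ga = g[..., None] * b
                gb = _unbroadcast(
                    (a * g[..., None]).reshape(-1, a.shape[-1]).sum(axis=0), b.shape
                )
            elif a.ndim == 1:
                ga = (g[..., None, :] * b).sum(axis=-1)
                ga = _unbroadcast(ga, a.shape)
                gb = a[:, None] * g if g.ndim == 1 else np.einsum("i,...j->ij", a, g)
                gb = _unbroadcast(gb, b.shape)
            else:
                ga = _unbroadcast(g @ np.swapaxes(b, -1, -2), a.shape)
                gb = _unbroadcast(np.swapaxes(a, -1, -2) @ g, b.shape)
            return (ga, gb)

        out._backward = bw
        return out

    # ------------------------------------------------------------------ #
    # nonlinearities

    def tanh(self):
        t = np.tanh(self.data)
        out = Tensor(t, parents=(self,))
        out._backward = lambda g: (g * (1.0 - t * t),)
        return out

    def sigmoid(self):
        s = 1.0 / (1.0 + np.exp(-self.data))
        out = Tensor(s, parents=(self,))
        out._backward = lambda g: (g * s * (1.0 - s),)
        return out

    def relu(self):
        out = Tensor(np.maximum(self.data, 0.0), parents=(self,))
        out._backward = lambda g: (g * (self.data > 0),)
        return out

    def leaky_relu(self, alpha: float = 0.01):
        out = Tensor(np.where(self.data > 0, self.data, alpha * self.data), parents=(self,))
        out._backward = lambda g: (g * np.where(self.data > 0, 1.0, alpha),)
        return out

    def exp(self):
        e = np.exp(self.data)
        out = Tensor(e, parents=(self,))
        out._backward = lambda g: (g * e,)
        return out

    def log(self):
        out = Tensor(np.log(self.data), parents=(self,))
        out._backward = lambda g: (g / self.data,)
        return out

    def sqrt(self):
        r = np.sqrt(self.data)
        out = Tensor(r, parents=(self,))
        out._backward = lambda g: (g * 0.5 / r,)
        return out

    # ------------------------------------------------------------------ #
    # shape & reductions

    def sum(self, axis=None, keepdims: bool = False):
        out = Tensor(self.data.sum(axis=axis, keepdims=keepdims), parents=(self,))

        def bw(g):
            if axis is None:
                return (np.broadcast_to(g, self.shape).copy(),)
            gg = g
            if not keepdims:
                gg = np.expand_dims(g, axis)
            return (np.broadcast_to(gg, self.shape).copy(),)

        out._backward = bw
        return out

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else np.prod(
            [self.shape[a] for a in (axis if isinstance(axis, tuple) else (axis,))]
        )
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(n))

    def reshape(self, *shape):
        out = Tensor(self.data.reshape(*shape), parents=(self,))
        out._backward = lambda g: (g.reshape(self.shape),)
        return out

    def __getitem__(self, idx):
        out = Tensor(self.data[idx], parents=(self,))

        def bw(g):
            full = np.zeros_like(self.data)
            np.add.at(full, idx, g)
            return (full,)

        out._backward = bw
        return out

    # ------------------------------------------------------------------ #

    def backward(self, grad: np.ndarray | None = None):
        """Backpropagate; seeds with ones for a scalar output."""
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

        self.grad = np.ones_like(self.data) if grad is None else np.asarray(grad, dtype=float)
        for node in reversed(topo):
            if node._backward is None or node.grad is None:
                continue
            for parent, g in zip(node._parents, node._backward(node.grad)):
                if not parent.requires_grad:
                    continue
                if parent.grad is None:
                    parent.grad = np.zeros_like(parent.data)
                parent.grad += g


def concat(tensors: list, axis: int = -1) -> Tensor:
    tensors = [_astensor(t) for t in tensors]
    out = Tensor(np.concatenate([t.data for t in tensors], axis=axis), parents=tuple(tensors))
    sizes = [t.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    out._backward = lambda g: tuple(np.split(g, splits, axis=axis))
    return out


def stack(tensors: list, axis: int = 0) -> Tensor:
    tensors = [_astensor(t) for t in tensors]
    out = Tensor(np.stack([t.data for t in tensors], axis=axis), parents=tuple(tensors))

    def bw(g):
        return tuple(np.moveaxis(g, axis, 0)[i] for i in range(len(tensors)))

    out._backward = bw
    return out


def embedding(weight: Tensor, idx: np.ndarray) -> Tensor:
    """Row lookup ``weight[idx]`` with scatter-add backward."""
    idx = np.asarray(idx)
    out = Tensor(weight.data[idx], parents=(weight,))

    def bw(g):
        full = np.zeros_like(weight.data)
        np.add.at(full, idx, g)
        return (full,)

    out._backward = bw
    return out


def masked_softmax(scores: Tensor, mask: np.ndarray, axis: int = -1) -> Tensor:
    """Softmax over ``axis`` restricted to positions where ``mask`` is 1.

    Masked positions receive exactly 0 weight. Every softmax slice must
    contain at least one unmasked position.
    """
    mask = np.asarray(mask, dtype=bool)
    x = np.where(mask, scores.data, -np.inf)
    x = x - np.max(x, axis=axis, keepdims=True)
    e = np.exp(x)
    e = np.where(mask, e, 0.0)
    s = e / e.sum(axis=axis, keepdims=True)
    out = Tensor(s, parents=(scores,))

    def bw(g):
        dot = (g * s).sum(axis=axis, keepdims=True)
        return (s * (g - dot),)

    out._backward = bw
    return out
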