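"""Minimal reverse-mode automatic differentiation on numpy arrays.

A small tensor/op graph sufficient for transformer-style models: broadcasted
arithmetic, batched matmul, reductions, softmax, SiLU/ReLU/sigmoid, embedding
lookup, concatenation and a fused masked cross-entropy. Gradients are
accumulated by a topological backward sweep. All data is float64.

This is deliberately compact: no views, no in-place graph ops, no higher-order
gradients.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "concatenate", "embedding_lookup", "cross_entropy"]


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum `grad` down to `shape` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    """A numpy array plus an optional gradient and backward closure."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad = None
        self.requires_grad = bool(requires_grad)
        self._backward = None
        self._parents: tuple = ()

    # -- construction helpers -------------------------------------------------

    @staticmethod
    def _wrap(other) -> "Tensor":
        return other if isinstance(other, Tensor) else Tensor(other)

    @classmethod
    def _from_op(cls, data, parents, backward) -> "Tensor":
        out = cls(data)
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

    def item(self) -> float:
        return float(self.data)

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    # -- arithmetic -----------------------------------------------------------

    def __add__(self, other):
        a, b = self, self._wrap(other)
        out_data = a.data + b.data

        def backward(g):
            return (_unbroadcast(g, a.shape), _unbroadcast(g, b.shape))

        return Tensor._from_op(out_data, (a, b), backward)

    __radd__ = __add__

    def __neg__(self):
        return Tensor._from_op(-self.data, (self,), lambda g: (-g,))

    def __sub__(self, other):
        return self + (-self._wrap(other))

    def __rsub__(self, other):
        return self._wrap(other) + (-self)

    def __mul__(self, other):
        a, b = self, self._wrap(other)
        out_data = a.data * b.data

        def backward(g):
            return (_unbroadcast(g * b.data, a.shape), _unbroadcast(g * a.data, b.shape))

        return Tensor._from_op(out_data, (a, b), backward)

    __rmul__ = __mul__

    def __truediv__(self, other):
        a, b = self, self._wrap(other)
        out_data = a.data / b.data

        def backward(g):
            ga = _unbroadcast(g / b.data, a.shape)
            gb = _unbroadcast(-g * a.data / (b.data * b.data), b.shape)
            return (ga, gb)

        return Tensor._from_op(out_data, (a, b), backward)

    def __matmul__(self, other):
        a, b = self, self._wrap(other)
        out_data = a.data @ b.data

        def backward(g):
            ga = _unbroadcast(g @ np.swapaxes(b.data, -1, -2), a.shape)
            gb = _unbroadcast(np.swapaxes(a.data, -1, -2) @ g, b.shape)
            return (ga, gb)

        return Tensor._from_op(out_data, (a, b), backward)

    def __pow__(self, exponent: float):
        e = float(exponent)
        out_data = self.data**e

        def backward(g):
            return (g * e * self.data ** (e - 1.0),)

        return Tensor._from_op(out_data, (self,), backward)

    # -- shape ops ------------------------------------------------------------

    def reshape(self, *shape):
        orig = self.shape
        out_data = self.data.reshape(*shape)
        return Tensor._from_op(out_data, (self,), lambda g: (g.reshape(orig),))

    def swapaxes(self, ax1: int, ax2: int):
        out_data = np.swapaxes(self.data, ax1, ax2)
        return Tensor._from_op(out_data, (self,), lambda g: (np.swapaxes(g, ax1, ax2),))

    def transpose(self, axes):
        axes = tuple(axes)
        inv = tuple(np.argsort(axes))
        out_data = self.data.transpose(axes)
        return Tensor._from_op(out_data, (self,), lambda g: (g.transpose(inv),))

    # -- reductions -----------------------------------------------------------

    def sum(self, axis=None, keepdims: bool = False):
        out_data = self.data.sum(axis=axis, keepdims=keepdims)
        shape = self.shape

        def backward(g):
            if axis is None:
                return (np.broadcast_to(g, shape).copy(),)
            gg = g
            if not keepdims:
                gg = np.expand_dims(gg, axis)
            return (np.broadcast_to(gg, shape).copy(),)

        return Tensor._from_op(out_data, (self,), backward)

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    # -- elementwise nonlinearities -------------------------------------------

    def exp(self):
        out_data = np.exp(self.data)
        return Tensor._from_op(out_data, (self,), lambda g: (g * out_data,))

    def log(self):
        return Tensor._from_op(np.log(self.data), (self,), lambda g: (g / self.data,))

    def sqrt(self):
        out_data = np.sqrt(self.data)
        return Tensor._from_op(out_data, (self,), lambda g: (g / (2.0 * out_data),))

    def relu(self):
        out_data = np.maximum(self.data, 0.0)
        mask = self.data > 0.0
        return Tensor._from_op(out_data, (self,), lambda g: (g * mask,))

    def sigmoid(self):
        s = 1.0 / (1.0 + np.exp(-self.data))

        def backward(g):
            return (g * s * (1.0 - s),)

        return Tensor._from_op(s, (self,), backward)

    def silu(self):
        """x * sigmoid(x) (the SiLU / swish activation)."""
        s = 1.0 / (1.0 + np.exp(-self.data))

        def backward(g):
            return (g * (s + self.data * s * (1.0 - s)),)

        return Tensor._from_op(self.data * s, (self,), backward)

    def softmax(self, axis: int = -1):
        """Numerically stable softmax along `axis`.

        Rows whose entries are all highly negative (fully masked) come out
        uniform rather than NaN; exp of (masked - max) underflows to exactly
        zero for masked entries in partially masked rows.
        """
        shifted = self.data - self.data.max(axis=axis, keepdims=True)
        e = np.exp(shifted)
        y = e / e.sum(axis=axis, keepdims=True)

        def backward(g):
            dot = (g * y).sum(axis=axis, keepdims=True)
            return (y * (g - dot),)

        return Tensor._from_op(y, (self,), backward)

    # -- backward -------------------------------------------------------------

    def backward(self, grad=None):
        if grad is None:
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen = set()
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
                if p.requires_grad and id(p) not in seen:
                    stack.append((p, False))

        grads = {id(self): np.asarray(grad, dtype=np.float64)}
        for node in reversed(topo):
            g = grads.pop(id(node), None)
            if g is None:
                continue
            if node._backward is None:
                node.grad = g if node.grad is None else node.grad + g
                continue
            parent_grads = node._backward(g)
            for p, pg in zip(node._parents, parent_grads):
                if not p.requires_grad or pg is None:
                    continue
                if id(p) in grads:
                    grads[id(p)] = grads[id(p)] + pg
                else:
                    grads[id(p)] = pg


def concatenate(tensors, axis: int = -1) -> Tensor:
    tensors = [Tensor._wrap(t) for t in tensors]
    out_data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.data.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def backward(g):
        return tuple(np.split(g, splits, axis=axis))

    return Tensor._from_op(out_data, tensors, backward)


def embedding_lookup(weight: Tensor, indices) -> Tensor:
    """Row gather `weight[indices]` with scatter-add backward."""
    idx = np.asarray(indices)
    out_data = weight.data[idx]

    def backward(g):
        gw = np.zeros_like(weight.data)
        np.add.at(gw, idx, g)
        return (gw,)

    return Tensor._from_op(out_data, (weight,), backward)


def cross_entropy(logits: Tensor, targets, mask=None) -> Tensor:
    """Mean token-level cross entropy.

    logits: (..., V); targets: integer array matching the leading shape;
    mask: optional boolean array over the leading shape selecting the
    positions that contribute. Fused for numerical stability.
    """
    tgt = np.asarray(targets)
    if mask is None:
        mask = np.ones(tgt.shape, dtype=bool)
    else:
        mask = np.asarray(mask, dtype=bool)
    n = int(mask.sum())
    if n == 0:
        raise ValueError("cross_entropy: no unmasked positions")

    x = logits.data
    xmax = x.max(axis=-1, keepdims=True)
    lse = xmax[..., 0] + np.log(np.exp(x - xmax).sum(axis=-1))
    picked = np.take_along_axis(x, tgt[..., None], axis=-1)[..., 0]
    loss = ((lse - picked) * mask).sum() / n

    def backward(g):
        soft = np.exp(x - xmax)
        soft /= soft.sum(axis=-1, keepdims=True)
        onehot = np.zeros_like(x)
        np.put_along_axis(onehot, tgt[..., None], 1.0, axis=-1)
        return (g * (soft - onehot) * mask[..., None] / n,)

    return Tensor._from_op(loss, (logits,), backward)
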