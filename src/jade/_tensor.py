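"""Minimal reverse-mode automatic differentiation over numpy arrays.

The JADE objective couples one-layer graph-convolutional encoders/decoders, a
bilinear contrastive discriminator, an attention-parameterised transport cost
and a truncated Sinkhorn loop. All of these are small dense compositions of
matrix products and elementwise maps, so a compact tape-based Tensor with the
dozen primitives below is sufficient to differentiate every loss exactly.
Gradients of every primitive and of the composed losses are checked against
central finite differences in the test suite.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "astensor", "Adam"]


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum `grad` down to `shape`, undoing numpy broadcasting."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, size in enumerate(shape):
        if size == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


class Tensor:
    """A numpy array with an optional gradient tape."""

    __slots__ = ("value", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, value, requires_grad: bool = False, _parents=(), _backward=None):
        self.value = np.asarray(value, dtype=np.float64)
        self.requires_grad = bool(requires_grad)
        self.grad = None
        self._parents = _parents
        self._backward = _backward

    @property
    def shape(self):
        return self.value.shape

    # -- graph construction -------------------------------------------------

    @staticmethod
    def _make(value, parents, backward):
        needs = any(p.requires_grad or p._parents for p in parents)
        if not needs:
            return Tensor(value)
        return Tensor(value, _parents=parents, _backward=backward)

    def backward(self):
        if self.value.size != 1:
            raise ValueError("backward() requires a scalar loss")
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
        for node in topo:
            node.grad = None
        self.grad = np.ones_like(self.value)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    def _accum(self, g: np.ndarray):
        if self.grad is None:
            self.grad = g.copy()
        else:
            self.grad += g

    # -- operators ----------------------------------------------------------

    def __add__(self, other):
        other = astensor(other)

        def back(g):
            self._accum(_unbroadcast(g, self.shape))
            other._accum(_unbroadcast(g, other.shape))

        return Tensor._make(self.value + other.value, (self, other), back)

    __radd__ = __add__

    def __neg__(self):
        def back(g):
            self._accum(-g)

        return Tensor._make(-self.value, (self,), back)

    def __sub__(self, other):
        return self + (-astensor(other))

    def __rsub__(self, other):
        return astensor(other) + (-self)

    def __mul__(self, other):
        other = astensor(other)

        def back(g):
            self._accum(_unbroadcast(g * other.value, self.shape))
            other._accum(_unbroadcast(g * self.value, other.shape))

        return Tensor._make(self.value * other.value, (self, other), back)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = astensor(other)

        def back(g):
            self._accum(_unbroadcast(g / other.value, self.shape))
            other._accum(_unbroadcast(-g * self.value / other.value**2, other.shape))

        return Tensor._make(self.value / other.value, (self, other), back)

    def __rtruediv__(self, other):
        return astensor(other) / self

    def __matmul__(self, other):
        other = astensor(other)

        def back(g):
            self._accum(g @ other.value.T)
            other._accum(self.value.T @ g)

        return Tensor._make(self.value @ other.value, (self, other), back)

    @property
    def T(self):
        def back(g):
            self._accum(g.T)

        return Tensor._make(self.value.T, (self,), back)

    # -- elementwise maps ---------------------------------------------------

    def relu(self):
        mask = self.value > 0

        def back(g):
            self._accum(g * mask)

        return Tensor._make(np.where(mask, self.value, 0.0), (self,), back)

    def exp(self):
        out_val = np.exp(self.value)

        def back(g):
            self._accum(g * out_val)

        return Tensor._make(out_val, (self,), back)

    def log(self):
        def back(g):
            self._accum(g / self.value)

        return Tensor._make(np.log(self.value), (self,), back)

    def sqrt(self):
        out_val = np.sqrt(self.value)

        def back(g):
            # guard the (sub)gradient at exactly zero
            self._accum(g * 0.5 / np.maximum(out_val, 1e-150))

        return Tensor._make(out_val, (self,), back)

    def sigmoid(self):
        out_val = np.where(
            self.value >= 0,
            1.0 / (1.0 + np.exp(-np.clip(self.value, -500, None))),
            np.exp(np.clip(self.value, None, 500))
            / (1.0 + np.exp(np.clip(self.value, None, 500))),
        )

        def back(g):
            self._accum(g * out_val * (1.0 - out_val))

        return Tensor._make(out_val, (self,), back)

    def clip(self, lo: float, hi: float):
        """Clamp values; gradient passes only where unclamped."""
        mask = (self.value > lo) & (self.value < hi)

        def back(g):
            self._accum(g * mask)

        return Tensor._make(np.clip(self.value, lo, hi), (self,), back)

    # -- reductions / structure --------------------------------------------

    def sum(self, axis=None, keepdims: bool = False):
        def back(g):
            if axis is None:
                self._accum(np.full_like(self.value, float(g)))
            else:
                g_arr = np.asarray(g)
                if not keepdims:
                    g_arr = np.expand_dims(g_arr, axis)
                self._accum(np.broadcast_to(g_arr, self.value.shape).copy())

        return Tensor._make(self.value.sum(axis=axis, keepdims=keepdims), (self,), back)

    def mean(self, axis=None, keepdims: bool = False):
        denom = self.value.size if axis is None else self.value.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) / float(denom)

    def gather_rows(self, idx: np.ndarray):
        idx = np.asarray(idx, dtype=np.intp)

        def back(g):
            out = np.zeros_like(self.value)
            np.add.at(out, idx, g)
            self._accum(out)

        return Tensor._make(self.value[idx], (self,), back)

    def softmax_rows(self):
        shifted = self.value - self.value.max(axis=1, keepdims=True)
        e = np.exp(shifted)
        out_val = e / e.sum(axis=1, keepdims=True)

        def back(g):
            dot = (g * out_val).sum(axis=1, keepdims=True)
            self._accum(out_val * (g - dot))

        return Tensor._make(out_val, (self,), back)

    def frobenius(self):
        """Unsquared Frobenius norm, smooth away from zero."""
        return (self * self).sum().sqrt()

    def item(self) -> float:
        return float(self.value)


def astensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


class Adam:
    """Adam optimiser over a list of parameter Tensors."""

    def __init__(self, params: list[Tensor], lr: float = 1e-3,
                 betas=(0.9, 0.999), eps: float = 1e-8):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.value) for p in self.params]
        self.v = [np.zeros_like(p.value) for p in self.params]

    def step(self):
        self.t += 1
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1**self.t)
            vhat = self.v[i] / (1 - self.b2**self.t)
            p.value -= self.lr * mhat / (np.sqrt(vhat) + self.eps)

    def zero_grad(self):
        for p in self.params:
            p.grad = None
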