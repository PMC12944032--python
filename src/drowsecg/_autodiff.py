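"""Minimal reverse-mode automatic differentiation on NumPy arrays.

Just enough machinery for the gated-transformer classifier: broadcasting
elementwise arithmetic, batched matmul, reductions, shape ops, and the
nonlinearities the architecture uses.  Gradients are accumulated by a
topological-order backward sweep.  The engine is gradient-checked against
central finite differences in the test suite.
"""

from __future__ import annotations

import numpy as np


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum `grad` down to `shape` (reverse of NumPy broadcasting)."""
    if grad.shape == shape:
        return grad
    ndiff = grad.ndim - len(shape)
    if ndiff > 0:
        grad = grad.sum(axis=tuple(range(ndiff)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=float)
        self.grad = None
        self.requires_grad = requires_grad
        self._backward = None
        self._parents: tuple[Tensor, ...] = ()

    @property
    def shape(self):
        return self.data.shape

    # -- graph plumbing ----------------------------------------------------

    @staticmethod
    def _lift(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(x)

    def _make(self, data, parents, backward) -> "Tensor":
        out = Tensor(data, requires_grad=any(p.requires_grad for p in parents))
        if out.requires_grad:
            out._parents = parents
            out._backward = backward
        return out

    def detach(self) -> "Tensor":
        return Tensor(self.data.copy())

    def backward(self):
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
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is not None:
                node._backward()

    def _accum(self, g: np.ndarray):
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad += g

    # -- arithmetic --------------------------------------------------------

    def __add__(self, other):
        o = self._lift(other)
        out = self._make(self.data + o.data, (self, o), None)
        def back():
            if self.requires_grad:
                self._accum(_unbroadcast(out.grad, self.data.shape))
            if o.requires_grad:
                o._accum(_unbroadcast(out.grad, o.data.shape))
        out._backward = back
        return out

    __radd__ = __add__

    def __mul__(self, other):
        o = self._lift(other)
        out = self._make(self.data * o.data, (self, o), None)
        def back():
            if self.requires_grad:
                self._accum(_unbroadcast(out.grad * o.data, self.data.shape))
            if o.requires_grad:
                o._accum(_unbroadcast(out.grad * self.data, o.data.shape))
        out._backward = back
        return out

    __rmul__ = __mul__

    def __neg__(self):
        return self * -1.0

    def __sub__(self, other):
        return self + (-self._lift(other))

    def __rsub__(self, other):
        return self._lift(other) + (-self)

    def __truediv__(self, other):
        return self * self._lift(other) ** -1.0

    def __rtruediv__(self, other):
        return self._lift(other) * self ** -1.0

    def __pow__(self, exponent: float):
        out = self._make(self.data**exponent, (self,), None)
        def back():
            if self.requires_grad:
                self._accum(out.grad * exponent * self.data ** (exponent - 1.0))
        out._backward = back
        return out

    def __matmul__(self, other):
        o = self._lift(other)
        out = self._make(self.data @ o.data, (self, o), None)
        def back():
            if self.requires_grad:
                g = out.grad @ np.swapaxes(o.data, -1, -2)
                self._accum(_unbroadcast(g, self.data.shape))
            if o.requires_grad:
                g = np.swapaxes(self.data, -1, -2) @ out.grad
                o._accum(_unbroadcast(g, o.data.shape))
        out._backward = back
        return out

    # -- nonlinearities ----------------------------------------------------

    def exp(self):
        out = self._make(np.exp(self.data), (self,), None)
        def back():
            if self.requires_grad:
                self._accum(out.grad * out.data)
        out._backward = back
        return out

    def log(self):
        out = self._make(np.log(self.data), (self,), None)
        def back():
            if self.requires_grad:
                self._accum(out.grad / self.data)
        out._backward = back
        return out

    def tanh(self):
        out = self._make(np.tanh(self.data), (self,), None)
        def back():
            if self.requires_grad:
                self._accum(out.grad * (1.0 - out.data**2))
        out._backward = back
        return out

    def relu(self):
        out = self._make(np.maximum(self.data, 0.0), (self,), None)
        def back():
            if self.requires_grad:
                self._accum(out.grad * (self.data > 0))
        out._backward = back
        return out

    def sigmoid(self):
        out = self._make(1.0 / (1.0 + np.exp(-self.data)), (self,), None)
        def back():
            if self.requires_grad:
                self._accum(out.grad * out.data * (1.0 - out.data))
        out._backward = back
        return out

    # -- reductions and shape ops ------------------------------------------

    def sum(self, axis=None, keepdims=False):
        out = self._make(self.data.sum(axis=axis, keepdims=keepdims), (self,), None)
        def back():
            if self.requires_grad:
                g = out.grad
                if axis is not None and not keepdims:
                    g = np.expand_dims(g, axis)
                self._accum(np.broadcast_to(g, self.data.shape).copy())
        out._backward = back
        return out

    def mean(self, axis=None, keepdims=False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def reshape(self, *shape):
        out = self._make(self.data.reshape(*shape), (self,), None)
        def back():
            if self.requires_grad:
                self._accum(out.grad.reshape(self.data.shape))
        out._backward = back
        return out

    def transpose(self, axes):
        out = self._make(self.data.transpose(axes), (self,), None)
        inv = np.argsort(axes)
        def back():
            if self.requires_grad:
                self._accum(out.grad.transpose(inv))
        out._backward = back
        return out


# -- composed operations -----------------------------------------------------

_GELU_C = np.sqrt(2.0 / np.pi)


def gelu(x: Tensor) -> Tensor:
    """Smooth-gated (tanh-form) GELU nonlinearity."""
    inner = (x + x * x * x * 0.044715) * _GELU_C
    return x * 0.5 * (inner.tanh() + 1.0)


def softmax(x: Tensor, axis: int = -1) -> Tensor:
    shifted = x + Tensor(-np.max(x.data, axis=axis, keepdims=True))
    e = shifted.exp()
    return e / e.sum(axis=axis, keepdims=True)


def log_softmax(x: Tensor, axis: int = -1) -> Tensor:
    shifted = x + Tensor(-np.max(x.data, axis=axis, keepdims=True))
    return shifted - shifted.exp().sum(axis=axis, keepdims=True).log()


def layer_norm(x: Tensor, gamma: Tensor, beta: Tensor, eps: float = 1e-5) -> Tensor:
    mu = x.mean(axis=-1, keepdims=True)
    xc = x - mu
    var = (xc * xc).mean(axis=-1, keepdims=True)
    return xc * ((var + eps) ** -0.5) * gamma + beta
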