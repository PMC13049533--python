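"""Minimal reverse-mode automatic differentiation on numpy arrays.

Only the trainable mask decoder and the training objective need gradients;
the frozen encoders run as plain numpy. The op set is therefore small and
chosen for that workload: broadcasting arithmetic, batched matmul, shape
ops, softmax, sigmoid-family primitives and GELU. Everything is float64.
"""

from __future__ import annotations

import numpy as np
from scipy import special as _sp


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum `grad` down to `shape` (reverse of numpy broadcasting)."""
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
    """An n-d array with an optional gradient tape behind it."""

    __slots__ = ("data", "grad", "requires_grad", "_children", "_backward")

    def __init__(self, data, requires_grad: bool = False, _children=(), _backward=None):
        self.data = np.asarray(data, dtype=np.float64)
        self.requires_grad = bool(requires_grad)
        self.grad = None
        self._children = _children if self.requires_grad else ()
        self._backward = _backward

    # -- construction helpers -------------------------------------------------
    @staticmethod
    def as_tensor(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(x)

    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    @property
    def size(self):
        return self.data.size

    def item(self) -> float:
        return float(np.squeeze(self.data))

    def __float__(self) -> float:
        return float(np.squeeze(self.data))

    def numpy(self) -> np.ndarray:
        return self.data

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    def _accumulate(self, g: np.ndarray) -> None:
        if self.grad is None:
            # copy: g may alias another node's gradient buffer
            self.grad = np.array(g, dtype=self.data.dtype)
        else:
            self.grad += g

    # -- arithmetic -----------------------------------------------------------
    def __add__(self, other):
        other = Tensor.as_tensor(other)
        out_req = self.requires_grad or other.requires_grad
        out = Tensor(self.data + other.data, out_req, (self, other))

        def bw():
            g = out.grad
            if self.requires_grad:
                self._accumulate(_unbroadcast(g, self.data.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(g, other.data.shape))

        out._backward = bw
        return out

    __radd__ = __add__

    def __neg__(self):
        out = Tensor(-self.data, self.requires_grad, (self,))

        def bw():
            if self.requires_grad:
                self._accumulate(-out.grad)

        out._backward = bw
        return out

    def __sub__(self, other):
        return self + (-Tensor.as_tensor(other))

    def __rsub__(self, other):
        return Tensor.as_tensor(other) + (-self)

    def __mul__(self, other):
        other = Tensor.as_tensor(other)
        out_req = self.requires_grad or other.requires_grad
        out = Tensor(self.data * other.data, out_req, (self, other))

        def bw():
            g = out.grad
            if self.requires_grad:
                self._accumulate(_unbroadcast(g * other.data, self.data.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(g * self.data, other.data.shape))

        out._backward = bw
        return out

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = Tensor.as_tensor(other)
        out_req = self.requires_grad or other.requires_grad
        out = Tensor(self.data / other.data, out_req, (self, other))

        def bw():
            g = out.grad
            if self.requires_grad:
                self._accumulate(_unbroadcast(g / other.data, self.data.shape))
            if other.requires_grad:
                other._accumulate(
                    _unbroadcast(-g * self.data / (other.data ** 2), other.data.shape)
                )

        out._backward = bw
        return out

    def __rtruediv__(self, other):
        return Tensor.as_tensor(other) / self

    def __pow__(self, p: float):
        out = Tensor(self.data ** p, self.requires_grad, (self,))

        def bw():
            if self.requires_grad:
                self._accumulate(out.grad * p * self.data ** (p - 1))

        out._backward = bw
        return out

    def __matmul__(self, other):
        other = Tensor.as_tensor(other)
        out_req = self.requires_grad or other.requires_grad
        out = Tensor(self.data @ other.data, out_req, (self, other))

        def bw():
            g = out.grad
            if self.requires_grad:
                ga = g @ np.swapaxes(other.data, -1, -2)
                self._accumulate(_unbroadcast(ga, self.data.shape))
            if other.requires_grad:
                gb = np.swapaxes(self.data, -1, -2) @ g
                other._accumulate(_unbroadcast(gb, other.data.shape))

        out._backward = bw
        return out

    # -- reductions -----------------------------------------------------------
    def sum(self, axis=None, keepdims: bool = False):
        out = Tensor(self.data.sum(axis=axis, keepdims=keepdims), self.requires_grad, (self,))

        def bw():
            if not self.requires_grad:
                return
            g = out.grad
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            self._accumulate(np.broadcast_to(g, self.data.shape).copy())

        out._backward = bw
        return out

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else np.prod(
            [self.data.shape[a] for a in (axis if isinstance(axis, tuple) else (axis,))]
        )
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(n))

    # -- shape ops ------------------------------------------------------------
    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        out = Tensor(self.data.reshape(shape), self.requires_grad, (self,))

        def bw():
            if self.requires_grad:
                self._accumulate(out.grad.reshape(self.data.shape))

        out._backward = bw
        return out

    def transpose(self, *axes):
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        out = Tensor(self.data.transpose(axes), self.requires_grad, (self,))
        inv = np.argsort(axes)

        def bw():
            if self.requires_grad:
                self._accumulate(out.grad.transpose(inv))

        out._backward = bw
        return out

    @property
    def T(self):
        return self.transpose(tuple(range(self.ndim))[::-1])

    def __getitem__(self, idx):
        out = Tensor(self.data[idx], self.requires_grad, (self,))

        def bw():
            if self.requires_grad:
                g = np.zeros_like(self.data)
                np.add.at(g, idx, out.grad)
                self._accumulate(g)

        out._backward = bw
        return out

    # -- autodiff driver ------------------------------------------------------
    def backward(self):
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar output")
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:  # iterative DFS; graphs can be deep
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen or not node.requires_grad:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for ch in node._children:
                stack.append((ch, False))
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is not None:
                node._backward()


# -- elementwise / structural functions ---------------------------------------

def exp(x: Tensor) -> Tensor:
    x = Tensor.as_tensor(x)
    out = Tensor(np.exp(x.data), x.requires_grad, (x,))

    def bw():
        if x.requires_grad:
            x._accumulate(out.grad * out.data)

    out._backward = bw
    return out


def log(x: Tensor) -> Tensor:
    x = Tensor.as_tensor(x)
    out = Tensor(np.log(x.data), x.requires_grad, (x,))

    def bw():
        if x.requires_grad:
            x._accumulate(out.grad / x.data)

    out._backward = bw
    return out


def relu(x: Tensor) -> Tensor:
    x = Tensor.as_tensor(x)
    out = Tensor(np.maximum(x.data, 0.0), x.requires_grad, (x,))

    def bw():
        if x.requires_grad:
            x._accumulate(out.grad * (x.data > 0))

    out._backward = bw
    return out


_SQRT2 = np.sqrt(2.0)
_INV_SQRT_2PI = 1.0 / np.sqrt(2.0 * np.pi)


def gelu(x: Tensor) -> Tensor:
    """Exact (erf-based) Gaussian error linear unit."""
    x = Tensor.as_tensor(x)
    cdf = 0.5 * (1.0 + _sp.erf(x.data / _SQRT2))
    out = Tensor(x.data * cdf, x.requires_grad, (x,))

    def bw():
        if x.requires_grad:
            pdf = _INV_SQRT_2PI * np.exp(-0.5 * x.data ** 2)
            x._accumulate(out.grad * (cdf + x.data * pdf))

    out._backward = bw
    return out


def sigmoid(x: Tensor) -> Tensor:
    x = Tensor.as_tensor(x)
    y = _sp.expit(x.data)
    out = Tensor(y, x.requires_grad, (x,))

    def bw():
        if x.requires_grad:
            x._accumulate(out.grad * y * (1.0 - y))

    out._backward = bw
    return out


def logsigmoid(x: Tensor) -> Tensor:
    """log(sigmoid(x)) computed stably (never -inf for finite logits)."""
    x = Tensor.as_tensor(x)
    out = Tensor(_sp.log_expit(x.data), x.requires_grad, (x,))

    def bw():
        if x.requires_grad:
            x._accumulate(out.grad * _sp.expit(-x.data))

    out._backward = bw
    return out


def softmax(x: Tensor, axis: int = -1) -> Tensor:
    x = Tensor.as_tensor(x)
    z = x.data - x.data.max(axis=axis, keepdims=True)
    e = np.exp(z)
    y = e / e.sum(axis=axis, keepdims=True)
    out = Tensor(y, x.requires_grad, (x,))

    def bw():
        if x.requires_grad:
            g = out.grad
            x._accumulate(y * (g - (g * y).sum(axis=axis, keepdims=True)))

    out._backward = bw
    return out


def concat(tensors, axis: int = 0) -> Tensor:
    tensors = [Tensor.as_tensor(t) for t in tensors]
    req = any(t.requires_grad for t in tensors)
    out = Tensor(np.concatenate([t.data for t in tensors], axis=axis), req, tuple(tensors))
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def bw():
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                sl = [slice(None)] * out.data.ndim
                sl[axis] = slice(lo, hi)
                t._accumulate(out.grad[tuple(sl)])

    out._backward = bw
    return out
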