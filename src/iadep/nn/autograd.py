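"""Minimal reverse-mode automatic differentiation on numpy arrays.

Just enough machinery for the prediction network: broadcast-aware
elementwise arithmetic, batched matmul, reductions, 1-D convolution,
and the activations the architecture uses.  Gradient correctness is
exercised against finite differences in the test suite.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "conv1d", "pad_last", "softmax", "sigmoid", "leaky_relu", "maximum"]


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of numpy broadcasting)."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, s in enumerate(shape):
        if s == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_prev")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=float)
        self.grad = None
        self.requires_grad = bool(requires_grad)
        self._backward = None
        self._prev = ()

    # -- helpers ----------------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    @staticmethod
    def _wrap(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(x)

    def _make(self, data, parents, backward) -> "Tensor":
        out = Tensor(data)
        out.requires_grad = any(p.requires_grad for p in parents)
        if out.requires_grad:
            out._prev = tuple(parents)
            out._backward = backward
        return out

    def _accum(self, g: np.ndarray) -> None:
        if not self.requires_grad:
            return
        if self.grad is None:
            self.grad = np.array(np.broadcast_to(g, self.data.shape))
        else:
            self.grad += g

    def detach(self) -> "Tensor":
        return Tensor(self.data.copy())

    # -- arithmetic --------------------------------------------------------
    def __add__(self, other):
        other = self._wrap(other)
        out_data = self.data + other.data

        def backward(g):
            self._accum(_unbroadcast(g, self.shape))
            other._accum(_unbroadcast(g, other.shape))

        return self._make(out_data, (self, other), backward)

    __radd__ = __add__

    def __neg__(self):
        def backward(g):
            self._accum(-g)

        return self._make(-self.data, (self,), backward)

    def __sub__(self, other):
        return self + (-self._wrap(other))

    def __rsub__(self, other):
        return self._wrap(other) + (-self)

    def __mul__(self, other):
        other = self._wrap(other)
        out_data = self.data * other.data

        def backward(g):
            self._accum(_unbroadcast(g * other.data, self.shape))
            other._accum(_unbroadcast(g * self.data, other.shape))

        return self._make(out_data, (self, other), backward)

    __rmul__ = __mul__

    def __truediv__(self, other):
        return self * self._wrap(other) ** -1.0

    def __rtruediv__(self, other):
        return self._wrap(other) * self**-1.0

    def __pow__(self, exponent: float):
        out_data = self.data**exponent

        def backward(g):
            self._accum(g * exponent * self.data ** (exponent - 1.0))

        return self._make(out_data, (self,), backward)

    def __matmul__(self, other):
        other = self._wrap(other)
        out_data = self.data @ other.data

        def backward(g):
            self._accum(_unbroadcast(g @ np.swapaxes(other.data, -1, -2), self.shape))
            other._accum(_unbroadcast(np.swapaxes(self.data, -1, -2) @ g, other.shape))

        return self._make(out_data, (self, other), backward)

    # -- shape ops ---------------------------------------------------------
    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        orig = self.shape
        out_data = self.data.reshape(shape)

        def backward(g):
            self._accum(g.reshape(orig))

        return self._make(out_data, (self,), backward)

    def swapaxes(self, a: int, b: int):
        out_data = np.swapaxes(self.data, a, b)

        def backward(g):
            self._accum(np.swapaxes(g, a, b))

        return self._make(out_data, (self,), backward)

    # -- reductions --------------------------------------------------------
    def sum(self, axis=None, keepdims=False):
        out_data = self.data.sum(axis=axis, keepdims=keepdims)

        def backward(g):
            g = np.asarray(g)
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            self._accum(np.broadcast_to(g, self.shape).copy())

        return self._make(out_data, (self,), backward)

    def mean(self, axis=None, keepdims=False):
        count = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / count)

    # -- nonlinearities ----------------------------------------------------
    def exp(self):
        out_data = np.exp(self.data)

        def backward(g):
            self._accum(g * out_data)

        return self._make(out_data, (self,), backward)

    # -- engine ------------------------------------------------------------
    def backward(self):
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar loss")
        topo, seen = [], set()

        def visit(t):
            if id(t) in seen:
                return
            seen.add(id(t))
            for p in t._prev:
                visit(p)
            topo.append(t)

        visit(self)
        self.grad = np.ones_like(self.data)
        for t in reversed(topo):
            if t._backward is not None and t.requires_grad:
                t._backward(t.grad)


# -- free functions ---------------------------------------------------------


def maximum(a: Tensor, b: Tensor) -> Tensor:
    a, b = Tensor._wrap(a), Tensor._wrap(b)
    take_a = a.data >= b.data   # ties route the gradient to the first arg
    out_data = np.where(take_a, a.data, b.data)

    def backward(g):
        a._accum(_unbroadcast(g * take_a, a.shape))
        b._accum(_unbroadcast(g * ~take_a, b.shape))

    return a._make(out_data, (a, b), backward)


def sigmoid(x: Tensor) -> Tensor:
    x = Tensor._wrap(x)
    out_data = 1.0 / (1.0 + np.exp(-x.data))

    def backward(g):
        x._accum(g * out_data * (1.0 - out_data))

    return x._make(out_data, (x,), backward)


def leaky_relu(x: Tensor, a: float = 100.0) -> Tensor:
    """x for x >= 0, x / a otherwise (``a`` is a divisor, default 100)."""
    x = Tensor._wrap(x)
    if a <= 0:
        raise ValueError("leaky_relu divisor must be positive")
    pos = x.data >= 0
    slope = np.where(pos, 1.0, 1.0 / a)
    out_data = x.data * slope

    def backward(g):
        x._accum(g * slope)

    return x._make(out_data, (x,), backward)


def softmax(x: Tensor, axis: int = -1) -> Tensor:
    """Numerically stable softmax (shift by a detached per-row max)."""
    x = Tensor._wrap(x)
    shift = Tensor(x.data.max(axis=axis, keepdims=True))  # constant: softmax is shift-invariant
    e = (x - shift).exp()
    return e / e.sum(axis=axis, keepdims=True)


def pad_last(x: Tensor, left: int, right: int) -> Tensor:
    """Zero-pad the last axis."""
    x = Tensor._wrap(x)
    widths = [(0, 0)] * (x.ndim - 1) + [(left, right)]
    out_data = np.pad(x.data, widths)
    L = x.shape[-1]

    def backward(g):
        x._accum(g[..., left:left + L])

    return x._make(out_data, (x,), backward)


def conv1d(x: Tensor, weight: Tensor, bias: Tensor = None, stride: int = 1, pad: int = 0) -> Tensor:
    """1-D convolution: x (B, C_in, L), weight (C_out, C_in, K).

    Output length is floor((L + 2*pad - K)/stride) + 1.
    """
    x = Tensor._wrap(x)
    if pad:
        x = pad_last(x, pad, pad)
    B, C_in, L = x.shape
    C_out, C_in_w, K = weight.shape
    if C_in_w != C_in:
        raise ValueError(f"channel mismatch: input {C_in}, kernel {C_in_w}")
    if L < K:
        raise ValueError(
            f"input length {L} shorter than kernel {K}; reduce kernel size or padding"
        )
    cols = np.lib.stride_tricks.sliding_window_view(x.data, K, axis=2)[:, :, ::stride, :]
    T = cols.shape[2]
    # im2col: (B, T, C_in*K) once, then one big matmul
    colsmat = np.ascontiguousarray(cols.transpose(0, 2, 1, 3)).reshape(B * T, C_in * K)
    wmat = weight.data.reshape(C_out, C_in * K)
    out_data = (colsmat @ wmat.T).reshape(B, T, C_out).transpose(0, 2, 1)
    if bias is not None:
        out_data = out_data + bias.data[None, :, None]
    parents = (x, weight) if bias is None else (x, weight, bias)

    def backward(g):
        gmat = np.ascontiguousarray(g.transpose(0, 2, 1)).reshape(B * T, C_out)
        weight._accum((gmat.T @ colsmat).reshape(C_out, C_in, K))
        if bias is not None:
            bias._accum(g.sum(axis=(0, 2)))
        if x.requires_grad:
            gcols = (gmat @ wmat).reshape(B, T, C_in, K).transpose(0, 2, 1, 3)
            gx = np.zeros((B, C_in, L))
            for k in range(K):
                # positions t*stride + k collect the k-th kernel tap's grads
                gx[:, :, k:k + stride * T:stride] += gcols[:, :, :, k]
            x._accum(gx)

    return x._make(out_data, parents, backward)
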