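"""Network building blocks on top of the autograd engine."""

from __future__ import annotations

import numpy as np

from .autograd import Tensor, conv1d, leaky_relu, softmax

__all__ = [
    "Linear",
    "Conv1d",
    "ResidualBlock1d",
    "LayerNorm",
    "MultiHeadAttention",
    "dropout",
    "Adam",
]


class Module:
    def parameters(self):
        params = []
        for v in self.__dict__.values():
            if isinstance(v, Tensor) and v.requires_grad:
                params.append(v)
            elif isinstance(v, Module):
                params.extend(v.parameters())
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        params.extend(item.parameters())
        return params


def _kaiming(rng, fan_in, *shape):
    return Tensor(rng.standard_normal(shape) * np.sqrt(2.0 / fan_in), requires_grad=True)


class Linear(Module):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        self.weight = _kaiming(rng, n_in, n_in, n_out)
        self.bias = Tensor(np.zeros(n_out), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return x @ self.weight + self.bias


class Conv1d(Module):
    def __init__(self, c_in: int, c_out: int, kernel: int, stride: int, rng, pad: int = None):
        self.weight = _kaiming(rng, c_in * kernel, c_out, c_in, kernel)
        self.bias = Tensor(np.zeros(c_out), requires_grad=True)
        self.stride = stride
        self.pad = kernel // 2 if pad is None else pad

    def __call__(self, x: Tensor) -> Tensor:
        return conv1d(x, self.weight, self.bias, stride=self.stride, pad=self.pad)


class ResidualBlock1d(Module):
    """conv-act-conv with an identity (or strided 1x1-conv) skip path."""

    def __init__(self, width: int, kernel: int, stride: int, leaky_a: float, rng):
        self.conv1 = Conv1d(width, width, kernel, stride, rng)
        self.conv2 = Conv1d(width, width, kernel, 1, rng)
        self.leaky_a = leaky_a
        self.skip = Conv1d(width, width, 1, stride, rng, pad=0) if stride > 1 else None

    def __call__(self, x: Tensor) -> Tensor:
        h = leaky_relu(self.conv1(x), self.leaky_a)
        h = self.conv2(h)
        s = self.skip(x) if self.skip is not None else x
        return leaky_relu(h + s, self.leaky_a)


class LayerNorm(Module):
    def __init__(self, width: int, eps: float = 1e-5):
        self.gamma = Tensor(np.ones(width), requires_grad=True)
        self.beta = Tensor(np.zeros(width), requires_grad=True)
        self.eps = eps

    def __call__(self, x: Tensor) -> Tensor:
        mu = x.mean(axis=-1, keepdims=True)
        xc = x - mu
        var = (xc * xc).mean(axis=-1, keepdims=True)
        return xc * (var + self.eps) ** -0.5 * self.gamma + self.beta


class MultiHeadAttention(Module):
    """Scaled dot-product attention, h heads over width d_model."""

    def __init__(self, d_model: int, n_heads: int, rng):
        if d_model % n_heads != 0:
            raise ValueError(f"width {d_model} not divisible by {n_heads} heads")
        self.n_heads = n_heads
        self.d_k = d_model // n_heads
        self.wq = Linear(d_model, d_model, rng)
        self.wk = Linear(d_model, d_model, rng)
        self.wv = Linear(d_model, d_model, rng)
        self.wo = Linear(d_model, d_model, rng)

    def _split(self, x: Tensor) -> Tensor:
        B, T, D = x.shape
        return x.reshape(B, T, self.n_heads, self.d_k).swapaxes(1, 2)  # (B, h, T, dk)

    def __call__(self, q_in: Tensor, k_in: Tensor = None, v_in: Tensor = None) -> Tensor:
        k_in = q_in if k_in is None else k_in
        v_in = k_in if v_in is None else v_in
        q, k, v = self._split(self.wq(q_in)), self._split(self.wk(k_in)), self._split(self.wv(v_in))
        scores = (q @ k.swapaxes(-1, -2)) * (1.0 / np.sqrt(self.d_k))
        out = softmax(scores, axis=-1) @ v                  # (B, h, Tq, dk)
        B, h, Tq, dk = out.shape
        out = out.swapaxes(1, 2).reshape(B, Tq, h * dk)
        return self.wo(out)


def dropout(x: Tensor, p: float, rng: np.random.Generator, training: bool) -> Tensor:
    if not training or p <= 0.0:
        return x
    mask = (rng.random(x.shape) >= p) / (1.0 - p)
    return x * Tensor(mask)


class Adam:
    """Adam optimizer; the L2 penalty enters through the loss, not here."""

    def __init__(self, params, lr: float = 1e-3, betas=(0.9, 0.999), eps: float = 1e-8):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self):
        for p in self.params:
            p.grad = None

    def step(self):
        self.t += 1
        for i, p in enumerate(self.params):
            g = p.grad if p.grad is not None else np.zeros_like(p.data)
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1**self.t)
            vhat = self.v[i] / (1 - self.b2**self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
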