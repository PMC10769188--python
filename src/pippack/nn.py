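"""Minimal neural-network building blocks on top of :mod:`pippack.ops`."""

from __future__ import annotations

import numpy as np

from . import ops as A
from .ops import Tensor


class Module:
    """Base class with recursive parameter discovery by attribute walk."""

    def named_parameters(self, prefix: str = ""):
        for name, value in vars(self).items():
            full = f"{prefix}{name}"
            if isinstance(value, Tensor) and value.requires_grad:
                yield full, value
            elif isinstance(value, Module):
                yield from value.named_parameters(f"{full}.")
            elif isinstance(value, (list, tuple)):
                for i, item in enumerate(value):
                    if isinstance(item, Module):
                        yield from item.named_parameters(f"{full}.{i}.")
                    elif isinstance(item, Tensor) and item.requires_grad:
                        yield f"{full}.{i}", item

    def parameters(self):
        return [p for _, p in self.named_parameters()]

    def n_parameters(self) -> int:
        return int(sum(p.data.size for p in self.parameters()))

    def zero_grad(self):
        for p in self.parameters():
            p.zero_grad()

    def state_dict(self) -> dict:
        return {name: p.data.copy() for name, p in self.named_parameters()}

    def load_state_dict(self, state: dict):
        own = dict(self.named_parameters())
        if set(own) != set(state):
            missing = set(own) ^ set(state)
            raise ValueError(f"parameter name mismatch: {sorted(missing)[:5]}")
        for name, p in own.items():
            arr = np.asarray(state[name], dtype=np.float64)
            if arr.shape != p.data.shape:
                raise ValueError(
                    f"shape mismatch for {name}: checkpoint {arr.shape} "
                    f"vs model {p.data.shape}")
            p.data = arr.copy()


class Linear(Module):
    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator,
                 bias: bool = True, init_scale: float = 1.0):
        # LeCun-style fan-in initialization
        std = init_scale / np.sqrt(d_in)
        self.weight = Tensor(rng.normal(0.0, std, size=(d_in, d_out)),
                             requires_grad=True)
        self.bias = Tensor(np.zeros(d_out), requires_grad=True) if bias else None

    def __call__(self, x):
        out = A.matmul(x, self.weight)
        if self.bias is not None:
            out = A.add(out, self.bias)
        return out


class MLP(Module):
    """ReLU MLP with ``depth`` hidden layers."""

    def __init__(self, d_in: int, d_hidden: int, d_out: int, depth: int,
                 rng: np.random.Generator, final_bias: bool = True):
        dims = [d_in] + [d_hidden] * depth + [d_out]
        self.layers = [Linear(dims[i], dims[i + 1], rng,
                              bias=(final_bias or i < len(dims) - 2))
                       for i in range(len(dims) - 1)]

    def __call__(self, x):
        for i, layer in enumerate(self.layers):
            x = layer(x)
            if i < len(self.layers) - 1:
                x = A.relu(x)
        return x


class LayerNorm(Module):
    def __init__(self, dim: int, eps: float = 1e-5):
        self.gain = Tensor(np.ones(dim), requires_grad=True)
        self.offset = Tensor(np.zeros(dim), requires_grad=True)
        self.eps = eps

    def __call__(self, x):
        mu = A.mean_(x, axis=-1, keepdims=True)
        centered = A.sub(x, mu)
        var = A.mean_(A.mul(centered, centered), axis=-1, keepdims=True)
        normed = A.div(centered, A.sqrt(A.add(var, self.eps)))
        return A.add(A.mul(normed, self.gain), self.offset)


class Adam:
    """Adam over a list of parameters; the learning rate is set per step."""

    def __init__(self, params, lr: float = 1e-3, betas=(0.9, 0.999),
                 eps: float = 1e-8):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def step(self, lr: float = None):
        if lr is not None:
            self.lr = lr
        self.t += 1
        for p, m, v in zip(self.params, self.m, self.v):
            if p.grad is None:
                continue
            g = p.grad
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * g * g
            mhat = m / (1 - self.b1 ** self.t)
            vhat = v / (1 - self.b2 ** self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)

    def zero_grad(self):
        for p in self.params:
            p.zero_grad()
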