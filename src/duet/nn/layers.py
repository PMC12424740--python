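"""Neural-network building blocks on top of the autodiff engine."""

from __future__ import annotations

from typing import List

import numpy as np

from .autodiff import Parameter, Tensor, embedding


class Module:
    """Lightweight parameter container with recursive traversal."""

    def parameters(self) -> List[Parameter]:
        out: List[Parameter] = []
        seen = set()
        for value in self.__dict__.values():
            for p in _collect(value):
                if id(p) not in seen:
                    seen.add(id(p))
                    out.append(p)
        return out

    def n_parameters(self) -> int:
        return int(sum(p.data.size for p in self.parameters()))

    def state_arrays(self) -> List[np.ndarray]:
        return [p.data for p in self.parameters()]

    def load_arrays(self, arrays: List[np.ndarray]) -> None:
        params = self.parameters()
        if len(arrays) != len(params):
            raise ValueError("parameter count mismatch on load")
        for p, a in zip(params, arrays):
            if p.data.shape != a.shape:
                raise ValueError("parameter shape mismatch on load")
            p.data = np.asarray(a, dtype=np.float64).copy()


def _collect(value):
    if isinstance(value, Parameter):
        yield value
    elif isinstance(value, Module):
        yield from value.parameters()
    elif isinstance(value, (list, tuple)):
        for v in value:
            yield from _collect(v)


class Linear(Module):
    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator, zero_init: bool = False):
        if zero_init:
            w = np.zeros((d_in, d_out))
        else:
            w = rng.standard_normal((d_in, d_out)) / np.sqrt(d_in)
        self.weight = Parameter(w)
        self.bias = Parameter(np.zeros(d_out))

    def __call__(self, x: Tensor) -> Tensor:
        return x @ self.weight + self.bias


class Embedding(Module):
    def __init__(self, n: int, d: int, rng: np.random.Generator, scale: float = 0.02):
        self.weight = Parameter(scale * rng.standard_normal((n, d)))

    def __call__(self, idx: np.ndarray) -> Tensor:
        return embedding(self.weight, idx)


class RMSNorm(Module):
    """RMS normalization over the last axis with a learned scale (QK-norm)."""

    def __init__(self, dim: int, eps: float = 1e-6):
        self.scale = Parameter(np.ones(dim))
        self.eps = eps

    def __call__(self, x: Tensor) -> Tensor:
        ms = (x**2.0).mean(axis=-1, keepdims=True)
        return x * (ms + self.eps) ** -0.5 * self.scale


def layer_norm(x: Tensor, eps: float = 1e-6) -> Tensor:
    """Affine-free layer normalization over the last axis (pre-norm blocks)."""
    mu = x.mean(axis=-1, keepdims=True)
    xc = x - mu
    var = (xc**2.0).mean(axis=-1, keepdims=True)
    return xc * (var + eps) ** -0.5


def sinusoidal_embedding(t: np.ndarray, dim: int = 256, max_period: float = 10000.0) -> np.ndarray:
    """Sinusoidal features of a (batch of) scalar time(s), shape (..., dim)."""
    t = np.atleast_1d(np.asarray(t, dtype=np.float64))
    half = dim // 2
    freqs = np.exp(-np.log(max_period) * np.arange(half) / half)
    args = t[..., None] * freqs * 1000.0
    return np.concatenate([np.cos(args), np.sin(args)], axis=-1)


def dropout(x: Tensor, p: float, rng: np.random.Generator, training: bool) -> Tensor:
    if not training or p <= 0.0:
        return x
    keep = (rng.random(x.shape) >= p).astype(np.float64) / (1.0 - p)
    return x * keep
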