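"""Minimal reverse-mode automatic differentiation over numpy arrays.

A deliberately small tensor library: just the operations the transformer
denoiser needs (broadcasted arithmetic, batched matmul, reductions, reshape /
transpose / basic indexing, GeLU / SiLU, softmax, embedding lookup).  Arrays
are float64 throughout; gradients are accumulated by a topological backward
sweep.  Gradient recording can be disabled globally with :func:`no_grad` for
inference.
"""

from __future__ import annotations

import contextlib
from typing import Iterable, Optional

import numpy as np
from scipy.special import erf

_GRAD_ENABLED = True


@contextlib.contextmanager
def no_grad():
    global _GRAD_ENABLED
    prev = _GRAD_ENABLED
    _GRAD_ENABLED = False
    try:
        yield
    finally:
        _GRAD_ENABLED = prev


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of numpy broadcasting)."""
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
    __slots__ = ("data", "grad", "requires_grad", "_children", "_backward")

    def __init__(self, data, requires_grad: bool = False, _children=(), _backward=None):
        self.data = np.asarray(data, dtype=np.float64)
        self.requires_grad = bool(requires_grad) and _GRAD_ENABLED
        self.grad: Optional[np.ndarray] = None
        self._children = _children if self.requires_grad else ()
        self._backward = _backward

    # -- construction helpers -------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def _accumulate(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.array(g, dtype=np.float64)
        else:
            self.grad += g

    # -- autograd driver ------------------------------------------------------
    def backward(self, grad: Optional[np.ndarray] = None) -> None:
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without grad requires a scalar")
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen = set()

        def visit(node: "Tensor"):
            stack = [(node, iter(node._children))]
            seen.add(id(node))
            while stack:
                cur, it = stack[-1]
                advanced = False
                for child in it:
                    if id(child) not in seen and child.requires_grad:
                        seen.add(id(child))
                        stack.append((child, iter(child._children)))
                        advanced = True
                        break
                if not advanced:
                    topo.append(cur)
                    stack.pop()

        visit(self)
        self._accumulate(np.asarray(grad, dtype=np.float64))
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    # -- arithmetic -----------------------------------------------------------
    def __add__(self, other):
        other = as_tensor(other)
        out = Tensor(
            self.data + other.data,
            self.requires_grad or other.requires_grad,
            (self, other),
        )

        def bwd(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g, self.data.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(g, other.data.shape))

        out._backward = bwd
        return out

    __radd__ = __add__

    def __neg__(self):
        return self * -1.0

    def __sub__(self, other):
        return self + (-as_tensor(other))

    def __rsub__(self, other):
        return as_tensor(other) + (-self)

    def __mul__(self, other):
        other = as_tensor(other)
        out = Tensor(
            self.data * other.data,
            self.requires_grad or other.requires_grad,
            (self, other),
        )

        def bwd(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g * other.data, self.data.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(g * self.data, other.data.shape))

        out._backward = bwd
        return out

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = as_tensor(other)
        return self * other ** -1.0

    def __rtruediv__(self, other):
        return as_tensor(other) * self ** -1.0

    def __pow__(self, n: float):
        out = Tensor(self.data**n, self.requires_grad, (self,))

        def bwd(g):
            self._accumulate(g * n * self.data ** (n - 1.0))

        out._backward = bwd
        return out

    def __matmul__(self, other):
        other = as_tensor(other)
        out = Tensor(
            np.matmul(self.data, other.data),
            self.requires_grad or other.requires_grad,
            (self, other),
        )

        def bwd(g):
            if self.requires_grad:
                ga = np.matmul(g, np.swapaxes(other.data, -1, -2))
                self._accumulate(_unbroadcast(ga, self.data.shape))
            if other.requires_grad:
                if other.data.ndim == 2 and self.data.ndim > 2:
                    # x @ W with batched x: one flattened GEMM
                    d_in, d_out = other.data.shape
                    gb = self.data.reshape(-1, d_in).T @ g.reshape(-1, d_out)
                    other._accumulate(gb)
                else:
                    gb = np.matmul(np.swapaxes(self.data, -1, -2), g)
                    other._accumulate(_unbroadcast(gb, other.data.shape))

        out._backward = bwd
        return out

    # -- reductions / shape ---------------------------------------------------
    def sum(self, axis=None, keepdims: bool = False):
        out = Tensor(self.data.sum(axis=axis, keepdims=keepdims), self.requires_grad, (self,))

        def bwd(g):
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            self._accumulate(np.broadcast_to(g, self.data.shape).copy())

        out._backward = bwd
        return out

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else np.prod(
            [self.data.shape[a] for a in (axis if isinstance(axis, tuple) else (axis,))]
        )
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(n))

    def reshape(self, *shape):
        out = Tensor(self.data.reshape(*shape), self.requires_grad, (self,))
        out._backward = lambda g: self._accumulate(g.reshape(self.data.shape))
        return out

    def transpose(self, *axes):
        out = Tensor(self.data.transpose(*axes), self.requires_grad, (self,))
        inv = np.argsort(axes)
        out._backward = lambda g: self._accumulate(g.transpose(*inv))
        return out

    def __getitem__(self, key):
        out = Tensor(self.data[key], self.requires_grad, (self,))

        def bwd(g):
            full = np.zeros_like(self.data)
            full[key] += g
            self._accumulate(full)

        out._backward = bwd
        return out

    # -- nonlinearities -------------------------------------------------------
    def gelu(self):
        x = self.data
        cdf = 0.5 * (1.0 + erf(x / np.sqrt(2.0)))
        out = Tensor(x * cdf, self.requires_grad, (self,))

        def bwd(g):
            pdf = np.exp(-0.5 * x * x) / np.sqrt(2.0 * np.pi)
            self._accumulate(g * (cdf + x * pdf))

        out._backward = bwd
        return out

    def silu(self):
        sig = 1.0 / (1.0 + np.exp(-self.data))
        out = Tensor(self.data * sig, self.requires_grad, (self,))

        def bwd(g):
            self._accumulate(g * sig * (1.0 + self.data * (1.0 - sig)))

        out._backward = bwd
        return out

    def softmax(self, axis: int = -1):
        m = self.data.max(axis=axis, keepdims=True)
        e = np.exp(self.data - m)
        s = e / e.sum(axis=axis, keepdims=True)
        out = Tensor(s, self.requires_grad, (self,))

        def bwd(g):
            dot = (g * s).sum(axis=axis, keepdims=True)
            self._accumulate(s * (g - dot))

        out._backward = bwd
        return out

    def log_softmax(self, axis: int = -1):
        m = self.data.max(axis=axis, keepdims=True)
        z = self.data - m
        lse = np.log(np.exp(z).sum(axis=axis, keepdims=True))
        ls = z - lse
        out = Tensor(ls, self.requires_grad, (self,))

        def bwd(g):
            self._accumulate(g - np.exp(ls) * g.sum(axis=axis, keepdims=True))

        out._backward = bwd
        return out


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def embedding(weight: Tensor, idx: np.ndarray) -> Tensor:
    """Row lookup ``weight[idx]`` with scatter-add backward."""
    idx = np.asarray(idx, dtype=np.int64)
    out = Tensor(weight.data[idx], weight.requires_grad, (weight,))

    def bwd(g):
        full = np.zeros_like(weight.data)
        np.add.at(full, idx, g)
        weight._accumulate(full)

    out._backward = bwd
    return out


class Parameter(Tensor):
    def __init__(self, data):
        super().__init__(data, requires_grad=True)


class Adam:
    """Standard Adam with optional linear warmup."""

    def __init__(
        self,
        params: Iterable[Parameter],
        lr: float = 1e-3,
        betas: tuple = (0.9, 0.999),
        eps: float = 1e-8,
        warmup: int = 0,
        total_steps: int = 0,
        final_lr_frac: float = 0.1,
    ):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.warmup = warmup
        self.total_steps = total_steps  # enables cosine decay when > 0
        self.final_lr_frac = final_lr_frac
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self) -> None:
        self.t += 1
        lr = self.lr
        if self.warmup and self.t <= self.warmup:
            lr = self.lr * self.t / self.warmup
        elif self.total_steps > 0:
            frac = min(1.0, (self.t - self.warmup) / max(1, self.total_steps - self.warmup))
            floor = self.final_lr_frac
            lr = self.lr * (floor + (1 - floor) * 0.5 * (1 + np.cos(np.pi * frac)))
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mh = self.m[i] / (1 - self.b1**self.t)
            vh = self.v[i] / (1 - self.b2**self.t)
            p.data -= lr * mh / (np.sqrt(vh) + self.eps)
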