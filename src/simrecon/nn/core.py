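"""Minimal CPU convolutional-network engine.

Layers store their parameters and implement an explicit forward/backward pair;
gradients accumulate into ``Parameter.grad``.  Convolution is im2col + GEMM,
which keeps the whole training loop inside BLAS.  Everything runs in a single
dtype chosen at construction time (float32 for speed; float64 for the
finite-difference gradient checks in the test suite).

This is deliberately a small engine, not a general autograd: the architectures
in this package are static graphs, and explicit backward passes keep the code
auditable and dependency-free.
"""

from __future__ import annotations

from typing import Iterator, List, Optional, Sequence

import numpy as np

__all__ = [
    "Parameter",
    "Module",
    "Sequential",
    "Conv2d",
    "ReLU",
    "AvgPool2",
    "UpsampleNearest2",
    "im2col",
    "col2im",
]


class Parameter:
    """A trainable array with an accumulated gradient."""

    __slots__ = ("value", "grad")

    def __init__(self, value: np.ndarray):
        self.value = value
        self.grad = np.zeros_like(value)


class Module:
    """Base class: parameter discovery by attribute walk."""

    def parameters(self) -> Iterator[Parameter]:
        for obj in self.__dict__.values():
            yield from _params_of(obj)

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad[...] = 0.0

    def n_parameters(self) -> int:
        return sum(p.value.size for p in self.parameters())

    def state_arrays(self) -> List[np.ndarray]:
        return [p.value for p in self.parameters()]

    def load_state_arrays(self, arrays: Sequence[np.ndarray]) -> None:
        params = list(self.parameters())
        if len(arrays) != len(params):
            raise ValueError(f"expected {len(params)} arrays, got {len(arrays)}")
        for p, a in zip(params, arrays):
            if p.value.shape != a.shape:
                raise ValueError(f"shape mismatch {p.value.shape} vs {a.shape}")
            p.value = a.astype(p.value.dtype)
            p.grad = np.zeros_like(p.value)

    def forward(self, x: np.ndarray) -> np.ndarray:  # pragma: no cover - interface
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:  # pragma: no cover - interface
        raise NotImplementedError

    def __call__(self, x: np.ndarray) -> np.ndarray:
        return self.forward(x)


def _params_of(obj) -> Iterator[Parameter]:
    if isinstance(obj, Parameter):
        yield obj
    elif isinstance(obj, Module):
        yield from obj.parameters()
    elif isinstance(obj, (list, tuple)):
        for item in obj:
            yield from _params_of(item)


def im2col(x: np.ndarray, k: int, pad: int) -> np.ndarray:
    """Unfold ``(N, C, H, W)`` into ``(N, C*k*k, H*W)`` patch columns."""
    n, c, h, w = x.shape
    xp = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad))) if pad else x
    cols = np.empty((n, c, k * k, h, w), dtype=x.dtype)
    t = 0
    for di in range(k):
        for dj in range(k):
            cols[:, :, t] = xp[:, :, di : di + h, dj : dj + w]
            t += 1
    return cols.reshape(n, c * k * k, h * w)


def col2im(dcols: np.ndarray, xshape, k: int, pad: int) -> np.ndarray:
    """Adjoint of :func:`im2col`: scatter-add columns back to an image."""
    n, c, h, w = xshape
    d = dcols.reshape(n, c, k * k, h, w)
    dxp = np.zeros((n, c, h + 2 * pad, w + 2 * pad), dtype=dcols.dtype)
    t = 0
    for di in range(k):
        for dj in range(k):
            dxp[:, :, di : di + h, dj : dj + w] += d[:, :, t]
            t += 1
    return dxp[:, :, pad : pad + h, pad : pad + w] if pad else dxp


class Conv2d(Module):
    """Same-padding 2-D convolution, 3x3 by default, He-initialised."""

    def __init__(self, c_in: int, c_out: int, ksize: int = 3,
                 rng: Optional[np.random.Generator] = None, dtype=np.float32):
        self.c_in, self.c_out, self.ksize = c_in, c_out, ksize
        self.pad = ksize // 2
        rng = rng or np.random.default_rng()
        scale = np.sqrt(2.0 / (c_in * ksize * ksize))
        self.weight = Parameter(
            (rng.standard_normal((c_out, c_in, ksize, ksize)) * scale).astype(dtype)
        )
        self.bias = Parameter(np.zeros(c_out, dtype=dtype))
        self._cols = None
        self._xshape = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        n, c, h, w = x.shape
        if c != self.c_in:
            raise ValueError(f"expected {self.c_in} input channels, got {c}")
        self._xshape = x.shape
        self._cols = im2col(x, self.ksize, self.pad)
        wm = self.weight.value.reshape(self.c_out, -1)
        y = np.matmul(wm, self._cols)  # (N, c_out, H*W)
        y += self.bias.value[:, None]
        return y.reshape(n, self.c_out, h, w)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        n, _, h, w = self._xshape
        dym = dy.reshape(n, self.c_out, h * w)
        self.weight.grad += np.einsum(
            "nof,ngf->og", dym, self._cols, optimize=True
        ).reshape(self.weight.value.shape)
        self.bias.grad += dym.sum(axis=(0, 2))
        wm = self.weight.value.reshape(self.c_out, -1)
        dcols = np.matmul(wm.T, dym)
        self._cols = None
        return col2im(dcols, self._xshape, self.ksize, self.pad)


class ReLU(Module):
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return np.where(self._mask, x, 0)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return np.where(self._mask, dy, 0)


class AvgPool2(Module):
    """2x2 average pooling (spatial sides must be even)."""

    def forward(self, x: np.ndarray) -> np.ndarray:
        n, c, h, w = x.shape
        self._xshape = x.shape
        return x.reshape(n, c, h // 2, 2, w // 2, 2).mean(axis=(3, 5))

    def backward(self, dy: np.ndarray) -> np.ndarray:
        n, c, h, w = self._xshape
        d = np.repeat(np.repeat(dy, 2, axis=2), 2, axis=3) * 0.25
        return d.astype(dy.dtype)


class UpsampleNearest2(Module):
    """2x nearest-neighbour upsampling."""

    def forward(self, x: np.ndarray) -> np.ndarray:
        return np.repeat(np.repeat(x, 2, axis=2), 2, axis=3)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        n, c, h, w = dy.shape
        return dy.reshape(n, c, h // 2, 2, w // 2, 2).sum(axis=(3, 5))


class Sequential(Module):
    def __init__(self, *modules: Module):
        self.modules = list(modules)

    def forward(self, x: np.ndarray) -> np.ndarray:
        for m in self.modules:
            x = m(x)
        return x

    def backward(self, dy: np.ndarray) -> np.ndarray:
        for m in reversed(self.modules):
            dy = m.backward(dy)
        return dy
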