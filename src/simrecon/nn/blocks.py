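"""Network building blocks and the three reconstruction architectures.

All three networks map an ``(N, in_frames, H, W)`` raw-stack tensor to a
single ``(N, 1, H, W)`` reconstruction at the same spatial size — there is no
spatial upsampling anywhere, since SIM raw frames and the reconstruction share
a pixel grid.

* ``RCAN``-style (default): a head convolution into ``n_features`` channels,
  ``n_residual_groups`` residual groups of ``n_residual_blocks`` residual
  channel-attention blocks each (with a group-level skip), a long skip over
  the whole body, and a 1-channel tail convolution.  Channel attention is a
  global average pool, a two-layer bottleneck (reduction ``r``), a sigmoid
  gate and a channel rescale.
* ``EDSR``-style: the same backbone without attention — a flat sequence of
  residual blocks with 0.1 residual scaling, the cited architecture's
  convention.
* ``UNet``-style baseline: a standard 4-level encoder-decoder with skip
  concatenations.
"""

from __future__ import annotations

from typing import List, Optional

import numpy as np

from .core import AvgPool2, Conv2d, Module, ReLU, Sequential, UpsampleNearest2

__all__ = ["ChannelAttention", "RCAB", "EDSRBlock", "ResidualGroup", "RCAN", "EDSR", "UNet"]


class ChannelAttention(Module):
    """Squeeze-and-excitation channel gate: GAP -> bottleneck -> sigmoid -> rescale."""

    def __init__(self, channels: int, reduction: int,
                 rng: Optional[np.random.Generator] = None, dtype=np.float32):
        from .core import Parameter

        rng = rng or np.random.default_rng()
        hidden = max(channels // reduction, 1)
        s1 = np.sqrt(2.0 / channels)
        s2 = np.sqrt(2.0 / hidden)
        self.w1 = Parameter((rng.standard_normal((hidden, channels)) * s1).astype(dtype))
        self.b1 = Parameter(np.zeros(hidden, dtype=dtype))
        self.w2 = Parameter((rng.standard_normal((channels, hidden)) * s2).astype(dtype))
        self.b2 = Parameter(np.zeros(channels, dtype=dtype))

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        self._pool = x.mean(axis=(2, 3))  # (N, C)
        z1 = self._pool @ self.w1.value.T + self.b1.value
        self._h = np.where(z1 > 0, z1, 0)
        z2 = self._h @ self.w2.value.T + self.b2.value
        self._s = 1.0 / (1.0 + np.exp(-z2))
        return x * self._s[:, :, None, None]

    def backward(self, dy: np.ndarray) -> np.ndarray:
        x, s, h, pool = self._x, self._s, self._h, self._pool
        dx = dy * s[:, :, None, None]
        ds = (dy * x).sum(axis=(2, 3))
        dz2 = ds * s * (1.0 - s)
        self.w2.grad += dz2.T @ h
        self.b2.grad += dz2.sum(axis=0)
        dh = dz2 @ self.w2.value
        dz1 = np.where(h > 0, dh, 0)
        self.w1.grad += dz1.T @ pool
        self.b1.grad += dz1.sum(axis=0)
        dpool = dz1 @ self.w1.value
        hw = x.shape[2] * x.shape[3]
        dx += dpool[:, :, None, None] / hw
        self._x = None
        return dx


class RCAB(Module):
    """Residual channel-attention block: x + CA(conv(relu(conv(x))))."""

    def __init__(self, channels: int, reduction: int, rng=None, dtype=np.float32):
        self.conv1 = Conv2d(channels, channels, rng=rng, dtype=dtype)
        self.relu = ReLU()
        self.conv2 = Conv2d(channels, channels, rng=rng, dtype=dtype)
        self.attention = ChannelAttention(channels, reduction, rng=rng, dtype=dtype)

    def forward(self, x: np.ndarray) -> np.ndarray:
        return x + self.attention(self.conv2(self.relu(self.conv1(x))))

    def backward(self, dy: np.ndarray) -> np.ndarray:
        d = self.conv1.backward(self.relu.backward(self.conv2.backward(self.attention.backward(dy))))
        return dy + d


class EDSRBlock(Module):
    """Plain residual block with 0.1 residual scaling: x + 0.1*conv(relu(conv(x)))."""

    scale = 0.1

    def __init__(self, channels: int, rng=None, dtype=np.float32):
        self.conv1 = Conv2d(channels, channels, rng=rng, dtype=dtype)
        self.relu = ReLU()
        self.conv2 = Conv2d(channels, channels, rng=rng, dtype=dtype)

    def forward(self, x: np.ndarray) -> np.ndarray:
        return x + self.scale * self.conv2(self.relu(self.conv1(x)))

    def backward(self, dy: np.ndarray) -> np.ndarray:
        d = self.conv1.backward(self.relu.backward(self.conv2.backward(dy * self.scale)))
        return dy + d


class ResidualGroup(Module):
    """A run of residual blocks plus a convolution, wrapped in a group skip."""

    def __init__(self, channels: int, n_blocks: int, reduction: int, rng=None, dtype=np.float32):
        self.blocks = [RCAB(channels, reduction, rng=rng, dtype=dtype) for _ in range(n_blocks)]
        self.conv = Conv2d(channels, channels, rng=rng, dtype=dtype)

    def forward(self, x: np.ndarray) -> np.ndarray:
        h = x
        for b in self.blocks:
            h = b(h)
        return x + self.conv(h)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        d = self.conv.backward(dy)
        for b in reversed(self.blocks):
            d = b.backward(d)
        return dy + d


def _identity_initialise(net, in_frames: int, n_features: int) -> None:
    """Start the network at a mean-frame pass-through.

    The closing convolution of every residual branch is zeroed (the standard
    zero-residual initialisation, which makes each block and the long skip an
    identity at step 0) and the head/tail convolutions get a mean-of-frames
    centre tap on top of scaled-down random weights.  The untrained network
    then already emits (approximately) the widefield projection, and training
    only has to learn the improvement — which converges orders of magnitude
    faster at small step budgets without changing the architecture.
    """
    for block_owner in (getattr(net, "groups", None) or [net]):
        for b in getattr(block_owner, "blocks", []):
            b.conv2.weight.value[...] = 0
            b.conv2.bias.value[...] = 0
        if hasattr(block_owner, "conv"):
            block_owner.conv.weight.value[...] = 0
    net.body_conv.weight.value[...] = 0
    h = net.head.weight.value
    h *= 0.3
    h[:, :, h.shape[2] // 2, h.shape[3] // 2] += 1.0 / in_frames
    t = net.tail.weight.value
    t *= 0.3
    t[0, :, t.shape[2] // 2, t.shape[3] // 2] += 1.0 / n_features


class RCAN(Module):
    """Residual channel-attention network for stack-to-image regression."""

    def __init__(self, in_frames: int, n_groups: int = 10, n_blocks: int = 3,
                 n_features: int = 64, reduction: int = 16, rng=None, dtype=np.float32,
                 identity_init: bool = True):
        self.head = Conv2d(in_frames, n_features, rng=rng, dtype=dtype)
        self.groups = [
            ResidualGroup(n_features, n_blocks, reduction, rng=rng, dtype=dtype)
            for _ in range(n_groups)
        ]
        self.body_conv = Conv2d(n_features, n_features, rng=rng, dtype=dtype)
        self.tail = Conv2d(n_features, 1, rng=rng, dtype=dtype)
        if identity_init:
            _identity_initialise(self, in_frames, n_features)

    def forward(self, x: np.ndarray) -> np.ndarray:
        f0 = self.head(x)
        h = f0
        for g in self.groups:
            h = g(h)
        f = f0 + self.body_conv(h)  # long skip
        return self.tail(f)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        df = self.tail.backward(dy)
        d = self.body_conv.backward(df)
        for g in reversed(self.groups):
            d = g.backward(d)
        return self.head.backward(df + d)


class EDSR(Module):
    """Attention-free deep residual network (flat block sequence, long skip)."""

    def __init__(self, in_frames: int, n_blocks: int = 30, n_features: int = 64,
                 rng=None, dtype=np.float32, identity_init: bool = True):
        self.head = Conv2d(in_frames, n_features, rng=rng, dtype=dtype)
        self.blocks = [EDSRBlock(n_features, rng=rng, dtype=dtype) for _ in range(n_blocks)]
        self.body_conv = Conv2d(n_features, n_features, rng=rng, dtype=dtype)
        self.tail = Conv2d(n_features, 1, rng=rng, dtype=dtype)
        if identity_init:
            _identity_initialise(self, in_frames, n_features)

    def forward(self, x: np.ndarray) -> np.ndarray:
        f0 = self.head(x)
        h = f0
        for b in self.blocks:
            h = b(h)
        f = f0 + self.body_conv(h)
        return self.tail(f)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        df = self.tail.backward(dy)
        d = self.body_conv.backward(df)
        for b in reversed(self.blocks):
            d = b.backward(d)
        return self.head.backward(df + d)


class _ConvBlock(Module):
    def __init__(self, c_in, c_out, rng=None, dtype=np.float32):
        self.seq = Sequential(
            Conv2d(c_in, c_out, rng=rng, dtype=dtype), ReLU(),
            Conv2d(c_out, c_out, rng=rng, dtype=dtype), ReLU(),
        )

    def forward(self, x):
        return self.seq(x)

    def backward(self, dy):
        return self.seq.backward(dy)


class UNet(Module):
    """4-level encoder-decoder with skip concatenations.

    Input spatial sides must be divisible by 16 (four 2x poolings).
    """

    LEVELS = 4

    def __init__(self, in_frames: int, n_features: int = 32, rng=None, dtype=np.float32):
        f = n_features
        widths = [f, 2 * f, 4 * f, 8 * f]
        self.enc = []
        c = in_frames
        for w in widths:
            self.enc.append(_ConvBlock(c, w, rng=rng, dtype=dtype))
            c = w
        self.pool = [AvgPool2() for _ in widths]
        self.bottleneck = _ConvBlock(widths[-1], 16 * f, rng=rng, dtype=dtype)
        self.up = [UpsampleNearest2() for _ in widths]
        self.dec = []
        c = 16 * f
        for w in reversed(widths):
            self.dec.append(_ConvBlock(c + w, w, rng=rng, dtype=dtype))
            c = w
        self.tail = Conv2d(widths[0], 1, rng=rng, dtype=dtype)

    def forward(self, x: np.ndarray) -> np.ndarray:
        if x.shape[2] % 16 or x.shape[3] % 16:
            raise ValueError("unet input sides must be divisible by 16")
        skips = []
        h = x
        for enc, pool in zip(self.enc, self.pool):
            h = enc(h)
            skips.append(h)
            h = pool(h)
        h = self.bottleneck(h)
        self._skip_channels = []
        for dec, up, skip in zip(self.dec, self.up, reversed(skips)):
            h = up(h)
            self._skip_channels.append((h.shape[1], skip.shape[1]))
            h = dec(np.concatenate([h, skip], axis=1))
        return self.tail(h)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        d = self.tail.backward(dy)
        dskips = []
        for dec, up, (c_up, c_skip) in zip(
            reversed(self.dec), reversed(self.up), reversed(self._skip_channels)
        ):
            dcat = dec.backward(d)
            d_up, d_skip = dcat[:, :c_up], dcat[:, c_up:]
            dskips.append(d_skip)
            d = up.backward(d_up)
        d = self.bottleneck.backward(d)
        # dskips were collected shallow-to-deep; encoders unwind deep-to-shallow
        for enc, pool, dskip in zip(reversed(self.enc), reversed(self.pool), reversed(dskips)):
            d = pool.backward(d)
            d = enc.backward(d + dskip)
        return d
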