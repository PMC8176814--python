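"""Network configuration and construction.

The default reconstruction network is the residual channel-attention
architecture: 10 residual groups of 3 residual blocks (~100 convolutional
layers at full width), taking the raw stack as input channels and emitting a
single same-size frame — no spatial upsampling anywhere.  ``edsr`` (plain
deep-residual) and ``unet`` (encoder-decoder) variants are provided for
architecture comparisons.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from typing import Optional

import numpy as np

from .nn import EDSR, RCAN, Module, UNet

__all__ = ["NetworkConfig", "build_network", "normalise_stack", "select_input_frames"]

_ARCH_ALIASES = {
    "rcan": "rcan", "rcan_style": "rcan",
    "edsr": "edsr", "edsr_style": "edsr",
    "unet": "unet", "unet_style": "unet",
}


@dataclass(frozen=True)
class NetworkConfig:
    """Architecture hyperparameters.

    ``in_frames`` is the number of raw frames consumed (1 selects the
    widefield-input ablation: the network sees only the mean frame).
    ``n_residual_blocks_per_group`` is ignored by ``unet``; for ``edsr`` the
    blocks form one flat sequence of length ``groups * blocks``.
    """

    architecture: str = "rcan"
    in_frames: int = 9
    n_residual_groups: int = 10
    n_residual_blocks_per_group: int = 3
    n_features: int = 64
    attention_reduction: int = 16

    def __post_init__(self) -> None:
        if self.canonical_architecture not in ("rcan", "edsr", "unet"):
            raise ValueError(
                f"unknown architecture {self.architecture!r}; "
                "expected one of rcan/edsr/unet"
            )
        if self.in_frames < 1:
            raise ValueError("in_frames must be >= 1")
        for name in ("n_residual_groups", "n_residual_blocks_per_group",
                     "n_features", "attention_reduction"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")

    @property
    def canonical_architecture(self) -> str:
        return _ARCH_ALIASES.get(self.architecture, self.architecture)

    def to_dict(self) -> dict:
        return asdict(self)


def build_network(cfg: NetworkConfig, seed: Optional[int] = None,
                  dtype=np.float32) -> Module:
    """Instantiate the configured architecture with seeded initialisation."""
    rng = np.random.default_rng(seed)
    arch = cfg.canonical_architecture
    if arch == "rcan":
        return RCAN(cfg.in_frames, cfg.n_residual_groups,
                    cfg.n_residual_blocks_per_group, cfg.n_features,
                    cfg.attention_reduction, rng=rng, dtype=dtype)
    if arch == "edsr":
        return EDSR(cfg.in_frames,
                    cfg.n_residual_groups * cfg.n_residual_blocks_per_group,
                    cfg.n_features, rng=rng, dtype=dtype)
    return UNet(cfg.in_frames, max(cfg.n_features // 2, 4), rng=rng, dtype=dtype)


def normalise_stack(frames: np.ndarray) -> np.ndarray:
    """Per-stack min-max normalisation to [0, 1].

    Experimental stacks carry arbitrary camera offsets and gains; min-max per
    stack makes reconstruction exactly invariant to global affine intensity
    rescaling of the input.
    """
    frames = np.asarray(frames, dtype=np.float64)
    lo, hi = frames.min(), frames.max()
    if hi <= lo:
        return np.zeros_like(frames)
    return (frames - lo) / (hi - lo)


def select_input_frames(frames: np.ndarray, in_frames: int) -> np.ndarray:
    """Reduce a stack to the network's input channels.

    ``in_frames == 1`` is the widefield-input ablation (mean of all frames);
    otherwise the first ``in_frames`` frames in acquisition order are used, so
    frame-subset ablations are well defined.
    """
    n = frames.shape[0]
    if in_frames == 1:
        return frames.mean(axis=0, keepdims=True)
    if in_frames > n:
        raise ValueError(f"network expects {in_frames} frames but stack has {n}")
    return frames[:in_frames]
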