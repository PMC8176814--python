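"""Training protocol, presets and multi-configuration comparisons.

Thin functional layer over :class:`simrecon.estimator.SIMReconstructor`: the
optimisation protocol (Adam, initial learning rate 1e-4 halved every 20
epochs, MSE loss against clean targets) lives in the estimator; this module
adds the config dataclass, named presets and the frames/architecture
comparison used to verify that the network exploits the whole raw stack.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import List, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd

from .estimator import SIMReconstructor, learning_rate_schedule
from .network import NetworkConfig

__all__ = [
    "TrainConfig",
    "DESK_TRAIN",
    "PAPER_TRAIN",
    "DESK_NETWORK",
    "train_model",
    "compare_configs",
    "frames_ablation",
]


@dataclass(frozen=True)
class TrainConfig:
    """Optimisation hyperparameters.

    The learning rate at epoch ``e`` is
    ``initial_lr * 0.5 ** floor(e / lr_halving_period)``.
    """

    epochs: int = 200
    initial_lr: float = 1e-4
    lr_halving_period: int = 20
    batch_size: int = 4
    loss: str = "mse"
    seed: int = 0
    checkpoint_period: int = 0
    validation_fraction: float = 0.1
    patch_size: Optional[int] = None

    def __post_init__(self) -> None:
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.initial_lr <= 0:
            raise ValueError("initial_lr must be > 0")
        if self.lr_halving_period < 1:
            raise ValueError("lr_halving_period must be >= 1")

    def learning_rate(self, epoch: int) -> float:
        return learning_rate_schedule(self.initial_lr, self.lr_halving_period, epoch)


#: Full-scale protocol: 200 epochs at 512-pixel frames, 256-pixel crops.
PAPER_TRAIN = TrainConfig(epochs=200, patch_size=256)

#: Desk-scale protocol: trains a tiny model on a CPU in minutes.  The step
#: budget is ~300x smaller than the full protocol, so the initial learning
#: rate is raised to 1e-3 (the halving schedule is unchanged).
DESK_TRAIN = TrainConfig(epochs=10, initial_lr=1e-3, batch_size=1,
                         validation_fraction=0.125)

#: Desk-scale architecture: 2 groups x 2 blocks, 16 features.
DESK_NETWORK = NetworkConfig(n_residual_groups=2, n_residual_blocks_per_group=2,
                             n_features=16, attention_reduction=4)


def _as_arrays(dataset):
    """Accept (stacks, targets) arrays or a dataset directory."""
    if isinstance(dataset, (str, Path)):
        from .simulate import load_dataset

        stacks, targets, _ = load_dataset(dataset)
        return stacks, targets
    stacks, targets = dataset[0], dataset[1]
    return np.asarray(stacks), np.asarray(targets)


def _make_estimator(net_cfg: NetworkConfig, train_cfg: TrainConfig) -> SIMReconstructor:
    return SIMReconstructor(
        architecture=net_cfg.architecture, in_frames=net_cfg.in_frames,
        n_residual_groups=net_cfg.n_residual_groups,
        n_residual_blocks_per_group=net_cfg.n_residual_blocks_per_group,
        n_features=net_cfg.n_features,
        attention_reduction=net_cfg.attention_reduction,
        epochs=train_cfg.epochs, initial_lr=train_cfg.initial_lr,
        lr_halving_period=train_cfg.lr_halving_period,
        batch_size=train_cfg.batch_size, loss=train_cfg.loss,
        patch_size=train_cfg.patch_size,
        validation_fraction=train_cfg.validation_fraction,
        random_state=train_cfg.seed,
    )


def train_model(dataset, net_cfg: NetworkConfig = NetworkConfig(),
                train_cfg: TrainConfig = TrainConfig(),
                checkpoint_path: Optional[Union[str, Path]] = None
                ) -> Tuple[SIMReconstructor, pd.DataFrame]:
    """Train one model; returns the fitted estimator and its training log."""
    stacks, targets = _as_arrays(dataset)
    est = _make_estimator(net_cfg, train_cfg).fit(stacks, targets)
    if checkpoint_path is not None:
        est.save(checkpoint_path)
    return est, est.history_


def compare_configs(dataset,
                    configs: Sequence[Tuple[str, NetworkConfig]],
                    train_cfg: TrainConfig = TrainConfig(),
                    seeds: Sequence[int] = (0,)) -> pd.DataFrame:
    """Train each configuration identically and align the validation curves.

    ``configs`` is a list of ``(label, NetworkConfig)``; every configuration is
    trained with the same protocol on the same dataset for each seed.  Returns
    a tidy frame ``label, seed, epoch, lr, train_loss, val_psnr, val_ssim``
    (one row per label per epoch per seed) for plotting and for the
    frames-ablation ordering check.
    """
    if len(configs) < 1:
        raise ValueError("need at least one configuration")
    stacks, targets = _as_arrays(dataset)
    frames = []
    for label, net_cfg in configs:
        for seed in seeds:
            est = _make_estimator(net_cfg, replace(train_cfg, seed=seed))
            est.fit(stacks, targets)
            log = est.history_.copy()
            log.insert(0, "label", label)
            log.insert(1, "seed", seed)
            frames.append(log)
    return pd.concat(frames, ignore_index=True)


def frames_ablation(n_pairs: int = 24, image_size: int = 48, epochs: int = 10,
                    frame_counts: Sequence[int] = (9, 6, 3, 1),
                    seeds: Sequence[int] = (0, 1, 2),
                    data_seed: int = 11) -> pd.DataFrame:
    """Vary the number of raw frames the network consumes (Fig.-7-style).

    Trains one tiny model per frame count (``1`` is the widefield-input
    ablation: the network sees only the mean frame) on a shared simulated
    dataset, identically for each replicate seed, and returns the aligned
    validation curves.  Defaults are desk-scale: 24 procedural pairs at
    ``image_size`` 48 px, 10 epochs, 3 seeds — minutes on one CPU.
    """
    from .optics import OpticalConfig
    from .simulate import simulate_pairs

    cfg = OpticalConfig(image_size=image_size)
    stacks, targets, _ = simulate_pairs(n_pairs, cfg=cfg, seed=data_seed)
    configs = [(f"frames{k}", replace(DESK_NETWORK, in_frames=k))
               for k in frame_counts]
    train_cfg = replace(DESK_TRAIN, epochs=epochs, validation_fraction=0.17)
    return compare_configs((stacks, targets), configs, train_cfg, seeds=seeds)
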