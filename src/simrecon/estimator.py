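"""Scikit-learn-style estimator wrapping network construction and training.

``SIMReconstructor`` is a supervised regressor from raw SIM stacks
``(n_stacks, n_frames, H, W)`` to reconstructed images ``(n_stacks, H, W)``.
It follows the sklearn estimator contract (``get_params``/``set_params``,
``fit``/``predict``/``score``, fitted attributes with a trailing underscore)
so it composes with sklearn model-selection utilities, while the optimisation
protocol is the one used for learned SIM reconstruction: Adam at an initial
learning rate of 1e-4, halved every 20 epochs, minimising mean-squared error
against the clean ground truths, with a held-out validation split scored by
PSNR/SSIM every epoch and the best-validation weights retained.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import List, Optional, Sequence, Union

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, RegressorMixin

from .metrics import psnr as _psnr, ssim as _ssim
from .network import NetworkConfig, build_network, normalise_stack, select_input_frames
from .nn import Adam

__all__ = ["SIMReconstructor", "learning_rate_schedule"]


def learning_rate_schedule(initial_lr: float, halving_period: int, epoch: int) -> float:
    """Stepped halving: ``initial_lr * 0.5 ** floor(epoch / halving_period)``."""
    return initial_lr * 0.5 ** (epoch // halving_period)


class SIMReconstructor(RegressorMixin, BaseEstimator):
    """Learned stack-to-image SIM reconstruction.

    Parameters
    ----------
    architecture : {'rcan', 'edsr', 'unet'}
        Network family; the residual channel-attention network is the default.
    in_frames : int
        Raw frames consumed per stack.  Stacks with more frames are truncated
        to the first ``in_frames`` in acquisition order; ``in_frames=1`` is the
        widefield-input ablation (the network sees the mean frame only).
    n_residual_groups, n_residual_blocks_per_group, n_features, attention_reduction :
        Architecture width/depth; defaults are the full-scale configuration
        (10 groups of 3 blocks, 64 features).
    epochs, initial_lr, lr_halving_period, batch_size, loss :
        Optimisation protocol.  ``loss`` is ``'mse'`` (default) or ``'l1'``.
    patch_size : int or None
        When set, train on random square crops of this side (augmentation
        variety at load time instead of dataset bloat); validation always
        scores full frames.
    validation_fraction : float
        Fraction of pairs held out for validation (at least one pair).
    random_state : int
        Seeds initialisation, the split, shuffling and cropping.

    Attributes
    ----------
    network_ : Module
        Trained network (best-validation weights).
    history_ : pandas.DataFrame
        Per-epoch ``epoch, lr, train_loss, val_psnr, val_ssim``.
    best_epoch_ : int
        Epoch whose weights are retained.
    train_indices_, val_indices_ : ndarray
        The disjoint split actually used.
    """

    def __init__(self, architecture: str = "rcan", in_frames: int = 9,
                 n_residual_groups: int = 10, n_residual_blocks_per_group: int = 3,
                 n_features: int = 64, attention_reduction: int = 16,
                 epochs: int = 200, initial_lr: float = 1e-4,
                 lr_halving_period: int = 20, batch_size: int = 4,
                 loss: str = "mse", patch_size: Optional[int] = None,
                 validation_fraction: float = 0.1, random_state: int = 0):
        self.architecture = architecture
        self.in_frames = in_frames
        self.n_residual_groups = n_residual_groups
        self.n_residual_blocks_per_group = n_residual_blocks_per_group
        self.n_features = n_features
        self.attention_reduction = attention_reduction
        self.epochs = epochs
        self.initial_lr = initial_lr
        self.lr_halving_period = lr_halving_period
        self.batch_size = batch_size
        self.loss = loss
        self.patch_size = patch_size
        self.validation_fraction = validation_fraction
        self.random_state = random_state

    # ------------------------------------------------------------------

    def network_config(self) -> NetworkConfig:
        return NetworkConfig(
            architecture=self.architecture, in_frames=self.in_frames,
            n_residual_groups=self.n_residual_groups,
            n_residual_blocks_per_group=self.n_residual_blocks_per_group,
            n_features=self.n_features,
            attention_reduction=self.attention_reduction,
        )

    def _validate_xy(self, X, y=None):
        # keep the input precision here: per-stack normalisation must happen
        # before any float32 downcast or affine-rescaling invariance is lost
        X = np.asarray(X, dtype=float)
        if X.ndim != 4:
            raise ValueError(f"X must be (n_stacks, n_frames, H, W); got shape {X.shape}")
        if X.shape[1] < self.in_frames:
            raise ValueError(
                f"network expects {self.in_frames} frames per stack but stacks "
                f"have {X.shape[1]}"
            )
        if y is not None:
            y = np.asarray(y, dtype=np.float32)
            if y.shape != (X.shape[0],) + X.shape[2:]:
                raise ValueError(
                    f"y must be (n_stacks, H, W) matching X; got {y.shape}"
                )
        return X, y

    def _prepare_inputs(self, X: np.ndarray) -> np.ndarray:
        """Per-stack min-max normalisation, then frame selection."""
        return np.stack([
            select_input_frames(normalise_stack(s), self.in_frames).astype(np.float32)
            for s in X
        ])

    def _loss_and_grad(self, pred: np.ndarray, target: np.ndarray):
        diff = pred - target
        if self.loss == "mse":
            return float(np.mean(diff**2)), (2.0 / diff.size) * diff
        if self.loss == "l1":
            return float(np.mean(np.abs(diff))), np.sign(diff) / diff.size
        raise ValueError(f"unknown loss {self.loss!r}; expected 'mse' or 'l1'")

    # ------------------------------------------------------------------

    def fit(self, X, y):
        """Train on paired (stacks, ground truths); see class docstring."""
        X, y = self._validate_xy(X, y)
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.initial_lr <= 0:
            raise ValueError("initial_lr must be > 0")
        n = X.shape[0]
        rng = np.random.default_rng(self.random_state)
        n_val = max(int(round(self.validation_fraction * n)), 1)
        if n_val >= n:
            raise ValueError("validation split leaves no training pairs")
        perm = rng.permutation(n)
        self.val_indices_ = np.sort(perm[:n_val])
        self.train_indices_ = np.sort(perm[n_val:])

        Xn = self._prepare_inputs(X)
        net = build_network(self.network_config(), seed=int(rng.integers(2**31)))
        opt = Adam(list(net.parameters()))

        Xtr, ytr = Xn[self.train_indices_], y[self.train_indices_]
        Xval, yval = Xn[self.val_indices_], y[self.val_indices_]

        rows = []
        best_psnr, best_state, best_epoch = -np.inf, None, -1
        for epoch in range(self.epochs):
            lr = learning_rate_schedule(self.initial_lr, self.lr_halving_period, epoch)
            order = rng.permutation(len(Xtr))
            losses = []
            for start in range(0, len(order), self.batch_size):
                idx = order[start : start + self.batch_size]
                xb, yb = Xtr[idx], ytr[idx]
                if self.patch_size is not None and self.patch_size < xb.shape[-1]:
                    p = self.patch_size
                    xs, ys_ = [], []
                    for s, t in zip(xb, yb):
                        top = rng.integers(0, s.shape[-2] - p + 1)
                        left = rng.integers(0, s.shape[-1] - p + 1)
                        xs.append(s[:, top : top + p, left : left + p])
                        ys_.append(t[top : top + p, left : left + p])
                    xb, yb = np.stack(xs), np.stack(ys_)
                pred = net(xb)[:, 0]
                loss, dpred = self._loss_and_grad(pred, yb)
                if not np.isfinite(loss):
                    raise RuntimeError(
                        f"training diverged (loss {loss}) at epoch {epoch}"
                    )
                losses.append(loss)
                net.zero_grad()
                net.backward(dpred[:, None].astype(xb.dtype))
                opt.step(lr)
            val_psnr, val_ssim = self._score_validation(net, Xval, yval)
            rows.append({"epoch": epoch, "lr": lr,
                         "train_loss": float(np.mean(losses)),
                         "val_psnr": val_psnr, "val_ssim": val_ssim})
            if val_psnr > best_psnr:
                best_psnr, best_epoch = val_psnr, epoch
                best_state = [p.copy() for p in net.state_arrays()]

        net.load_state_arrays(best_state)
        self.network_ = net
        self.history_ = pd.DataFrame(rows)
        self.best_epoch_ = best_epoch
        self.best_val_psnr_ = best_psnr
        return self

    @staticmethod
    def _metric_normalise(img: np.ndarray) -> np.ndarray:
        # metrics compare both images after normalisation to [0, 1]; min-max
        # puts the network output and the widefield baseline on equal footing
        lo, hi = img.min(), img.max()
        return (img - lo) / (hi - lo) if hi > lo else np.zeros_like(img)

    def _score_validation(self, net, Xval, yval):
        psnrs, ssims = [], []
        for s, t in zip(Xval, yval):
            pred = self._metric_normalise(net(s[None])[0, 0].astype(float))
            psnrs.append(_psnr(pred, t.astype(float)))
            ssims.append(_ssim(pred, t.astype(float)))
        return float(np.mean(psnrs)), float(np.mean(ssims))

    def predict(self, X) -> np.ndarray:
        """Reconstruct each stack; output is float64 in the target scale (unclipped)."""
        self._check_fitted()
        X, _ = self._validate_xy(X)
        Xn = self._prepare_inputs(X)
        return np.stack([self.network_(s[None])[0, 0].astype(float) for s in Xn])

    def score(self, X, y) -> float:
        """Mean PSNR (dB) over stacks, both images normalised to [0, 1]."""
        X, y = self._validate_xy(X, y)
        preds = self.predict(X)
        return float(np.mean([
            _psnr(self._metric_normalise(p), t.astype(float))
            for p, t in zip(preds, y)
        ]))

    def _check_fitted(self):
        if not hasattr(self, "network_"):
            raise RuntimeError("this SIMReconstructor instance is not fitted yet")

    # ------------------------------------------------------------------
    # self-describing checkpoints

    def save(self, path: Union[str, Path],
             simulation_fingerprint: Optional[dict] = None) -> None:
        """Write weights plus the full configuration as one ``.npz`` checkpoint."""
        self._check_fitted()
        meta = {
            "params": self.get_params(),
            "network_config": self.network_config().to_dict(),
            "best_epoch": int(self.best_epoch_),
            "simulation_fingerprint": simulation_fingerprint or {},
        }
        arrays = {f"w{i}": a for i, a in enumerate(self.network_.state_arrays())}
        np.savez(path, meta=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8),
                 **arrays)

    @classmethod
    def load(cls, path: Union[str, Path]) -> "SIMReconstructor":
        with np.load(path) as data:
            meta = json.loads(bytes(data["meta"]).decode())
            arrays = [data[f"w{i}"] for i in range(len(data.files) - 1)]
        est = cls(**meta["params"])
        net = build_network(est.network_config(), seed=0)
        net.load_state_arrays(arrays)
        est.network_ = net
        est.best_epoch_ = meta["best_epoch"]
        est.history_ = pd.DataFrame()
        est.simulation_fingerprint_ = meta.get("simulation_fingerprint", {})
        return est
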