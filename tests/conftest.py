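"""Shared fixtures: a small optical configuration and a desk-trained model.

The desk-scale model (tiny residual channel-attention network trained on 32
simulated procedural pairs at 64 px) is expensive enough (~20 s) that it is
trained once per session and shared by the training, inference, evaluation
and acceptance tests.
"""

from dataclasses import replace

import numpy as np
import pytest

import simrecon as sr

DESK_SEED = 7
DESK_TRAIN_SEED = 3


@pytest.fixture(scope="session")
def small_cfg():
    return sr.OpticalConfig(image_size=64)


@pytest.fixture(scope="session")
def desk_dataset(small_cfg):
    """32 simulated procedural training pairs at 64 px (the desk scale)."""
    stacks, targets, records = sr.simulate_pairs(32, cfg=small_cfg, seed=DESK_SEED)
    return stacks, targets, records


@pytest.fixture(scope="session")
def desk_model(desk_dataset):
    """Tiny reconstruction model trained with the desk protocol."""
    stacks, targets, _ = desk_dataset
    est, _ = sr.train_model((stacks, targets), sr.DESK_NETWORK,
                            replace(sr.DESK_TRAIN, seed=DESK_TRAIN_SEED))
    return est


@pytest.fixture(scope="session")
def desk_widefield_psnr(desk_dataset, desk_model):
    """Widefield-baseline PSNR on the desk model's held-out validation pairs."""
    stacks, targets, _ = desk_dataset
    scores = []
    for i in desk_model.val_indices_:
        wf = sr.widefield_projection(stacks[i])
        wf = (wf - wf.min()) / (wf.max() - wf.min())
        scores.append(sr.psnr(wf, targets[i]))
    return float(np.mean(scores))
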