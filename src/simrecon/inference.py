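"""End-user reconstruction: TIFF in, reconstructed TIFF out.

The widefield projection (pixelwise mean of the raw frames, the
diffraction-limited baseline) is also defined here.  Multi-page TIFFs whose
page count is a multiple of the model's frame count are treated as timelapses
and reconstructed stack by stack; large frames are reconstructed in
overlapping tiles blended with a linear ramp, which a fully convolutional
network permits.
"""

from __future__ import annotations

import time
from dataclasses import dataclass
from pathlib import Path
from typing import List, Optional, Union

import numpy as np

from .estimator import SIMReconstructor
from .simulate import RawStack

__all__ = ["ReconstructionResult", "widefield_projection", "reconstruct_array",
           "reconstruct_file"]


@dataclass
class ReconstructionResult:
    image: np.ndarray
    widefield: np.ndarray
    model_fingerprint: str = ""
    timing: float = 0.0  # wall-clock seconds, informational only

    def __post_init__(self) -> None:
        if self.image.shape != self.widefield.shape:
            raise ValueError("image and widefield must share the stack's spatial shape")


def widefield_projection(stack: Union[RawStack, np.ndarray]) -> np.ndarray:
    """Pixelwise arithmetic mean over the raw frames.

    With ideal three-phase patterns the stripes cancel in the mean, so this is
    the image a widefield microscope with homogeneous illumination would have
    recorded — the standard diffraction-limited reference.
    """
    frames = stack.frames if isinstance(stack, RawStack) else np.asarray(stack, dtype=float)
    if frames.ndim != 3 or len(frames) == 0:
        raise ValueError("expected a non-empty (n_frames, H, W) stack")
    return frames.mean(axis=0)


def _blend_window(h: int, w: int, overlap: int, dtype=float) -> np.ndarray:
    ramp_h = np.minimum(np.arange(1, h + 1), np.arange(h, 0, -1))
    ramp_w = np.minimum(np.arange(1, w + 1), np.arange(w, 0, -1))
    wh = np.clip(ramp_h / max(overlap, 1), None, 1.0)
    ww = np.clip(ramp_w / max(overlap, 1), None, 1.0)
    return np.outer(wh, ww).astype(dtype)


def reconstruct_array(model: SIMReconstructor, frames: np.ndarray,
                      tile: int = 512, overlap: int = 32) -> np.ndarray:
    """Reconstruct one stack, tiling spatially when frames exceed ``tile``."""
    _, h, w = frames.shape
    if h <= tile and w <= tile:
        return model.predict(frames[None])[0]
    out = np.zeros((h, w))
    weight = np.zeros((h, w))
    step = tile - overlap
    for top in range(0, h, step):
        for left in range(0, w, step):
            t0, l0 = min(top, max(h - tile, 0)), min(left, max(w - tile, 0))
            t1, l1 = min(t0 + tile, h), min(l0 + tile, w)
            patch = model.predict(frames[:, t0:t1, l0:l1][None])[0]
            win = _blend_window(t1 - t0, l1 - l0, overlap)
            out[t0:t1, l0:l1] += patch * win
            weight[t0:t1, l0:l1] += win
            if l1 >= w:
                break
        if t1 >= h:
            break
    return out / np.maximum(weight, 1e-12)


def reconstruct_file(
    tiff_path: Union[str, Path],
    checkpoint: Union[str, Path, SIMReconstructor],
    out_dir: Optional[Union[str, Path]] = None,
    clip: bool = True,
    float_output: bool = False,
    tile: int = 512,
    overlap: int = 32,
) -> List[ReconstructionResult]:
    """Reconstruct a raw SIM TIFF (or a timelapse of stacks).

    The page count must be the model's ``in_frames`` or an integer multiple of
    it (consecutive blocks are treated as a timelapse).  Outputs are written
    next to the input (or into ``out_dir``) as ``<stem>_sr.tif``, 16-bit by
    default or float32 when ``float_output``; a ``<stem>_wf.tif`` widefield
    projection is written alongside.
    """
    import tifffile

    tiff_path = Path(tiff_path)
    model = (checkpoint if isinstance(checkpoint, SIMReconstructor)
             else SIMReconstructor.load(checkpoint))
    try:
        pages = tifffile.imread(tiff_path)
    except Exception as exc:
        raise ValueError(f"could not read TIFF {tiff_path}: {exc}") from exc
    pages = np.asarray(pages)
    if pages.ndim == 2:
        pages = pages[None]
    n_frames = model.in_frames
    if pages.shape[0] % n_frames:
        raise ValueError(
            f"{tiff_path.name} has {pages.shape[0]} pages, not a multiple of the "
            f"model's {n_frames}-frame stack layout"
        )
    out_dir = Path(out_dir) if out_dir is not None else tiff_path.parent
    out_dir.mkdir(parents=True, exist_ok=True)
    results: List[ReconstructionResult] = []
    images, widefields = [], []
    for i in range(pages.shape[0] // n_frames):
        stack = pages[i * n_frames : (i + 1) * n_frames].astype(float)
        t0 = time.perf_counter()
        image = reconstruct_array(model, stack, tile=tile, overlap=overlap)
        elapsed = time.perf_counter() - t0
        if clip:
            image = np.clip(image, 0.0, 1.0)
        wf = widefield_projection(stack)
        results.append(ReconstructionResult(image=image, widefield=wf,
                                            model_fingerprint=str(checkpoint),
                                            timing=elapsed))
        images.append(image)
        widefields.append(wf)
    def _export(arrs):
        data = np.stack(arrs)
        if float_output:
            return data.astype(np.float32)
        return (np.clip(data, 0.0, 1.0) * np.iinfo(np.uint16).max + 0.5).astype(np.uint16)

    tifffile.imwrite(out_dir / f"{tiff_path.stem}_sr.tif", _export(images))
    tifffile.imwrite(out_dir / f"{tiff_path.stem}_wf.tif", _export(widefields))
    return results
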