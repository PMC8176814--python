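"""Randomised training-data generation for learned SIM reconstruction.

The training set is built entirely in silico: a source image (any photo-like
raster, or the bundled procedural generator) becomes the ground truth, and a
raw SIM stack is simulated from it with randomised illumination parameters —
a single stripe frequency ``k0`` and modulation depth ``m`` per stack, plus
Gaussian jitter on the per-orientation angle and per-frame phase to emulate
the imperfect pattern control of real instruments.  Pairs are written as
multi-page TIFF stacks with single-page TIFF targets and a JSON manifest that
records every sampled parameter, so any pair can be re-simulated exactly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import List, Optional, Sequence, Tuple, Union

import numpy as np
from skimage.color import rgb2gray
from skimage.transform import resize

from .optics import (
    IlluminationParams,
    NoiseSpec,
    OpticalConfig,
    TransferFunctions,
    apply_forward,
    illumination_pattern,
    make_otf,
)

__all__ = [
    "simulate_pairs",
    "StackLayout",
    "SimulationRanges",
    "RawStack",
    "TrainingPair",
    "prepare_ground_truth",
    "sample_stack_params",
    "simulate_stack",
    "generate_procedural_image",
    "build_dataset",
    "load_dataset",
]

IMAGE_EXTENSIONS = (".png", ".jpg", ".jpeg", ".tif", ".tiff", ".bmp")


@dataclass(frozen=True)
class StackLayout:
    """Acquisition geometry of one raw stack.

    The conventional SIM acquisition is 3 orientations x 3 phases = 9 frames;
    5x5 layouts and frame-reduced variants are also supported.  Base
    orientations are evenly spaced over pi (optionally with a global offset
    randomised per stack); base phases step by ``2 pi / n_phases``.  Layouts
    with fewer than 3 phases are permitted but flagged: the analytical
    unmixing problem they correspond to is underdetermined.
    """

    n_orientations: int = 3
    n_phases: int = 3

    def __post_init__(self) -> None:
        if self.n_orientations < 1 or self.n_phases < 1:
            raise ValueError("n_orientations and n_phases must be >= 1")

    @property
    def n_frames(self) -> int:
        return self.n_orientations * self.n_phases

    @property
    def underdetermined(self) -> bool:
        """True when one orientation yields fewer frames than the analytical
        unmixing needs (fewer than 3 phases)."""
        return self.n_phases < 3

    def base_orientations(self, offset: float = 0.0) -> np.ndarray:
        return offset + np.arange(self.n_orientations) * np.pi / self.n_orientations

    def base_phases(self) -> np.ndarray:
        return np.arange(self.n_phases) * 2.0 * np.pi / self.n_phases


@dataclass(frozen=True)
class SimulationRanges:
    """Randomisation ranges for stack simulation.

    ``k0_range`` and ``m_range`` are sampled uniformly once per stack,
    ``noise_level_range`` gives the Gaussian noise multiplier eta per stack,
    and the jitter standard deviations perturb per-orientation angle,
    per-frame phase and (optionally) per-frame stripe frequency.  Defaults
    put ``k0`` near the OTF cutoff (0.7-0.95 kc), where the resolution gain
    of SIM is largest, with eta spanning 0-4.
    """

    k0_range: Tuple[float, float] = (0.19, 0.26)
    m_range: Tuple[float, float] = (0.5, 1.0)
    noise_level_range: Tuple[float, float] = (0.0, 4.0)
    phase_jitter_sd: float = 0.05
    angle_jitter_sd: float = 0.05
    k0_jitter_sd: float = 0.0

    def __post_init__(self) -> None:
        for name in ("k0_range", "m_range", "noise_level_range"):
            lo, hi = getattr(self, name)
            if lo > hi:
                raise ValueError(f"{name} must satisfy min <= max")
        for name in ("phase_jitter_sd", "angle_jitter_sd", "k0_jitter_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    @classmethod
    def for_config(cls, cfg: OpticalConfig, k0_fraction=(0.7, 0.95), **kwargs) -> "SimulationRanges":
        """Ranges with ``k0`` expressed as a fraction of the OTF cutoff."""
        kc = cfg.cutoff_frequency
        return cls(k0_range=(k0_fraction[0] * kc, k0_fraction[1] * kc), **kwargs)


@dataclass
class RawStack:
    """An ordered set of raw SIM frames plus provenance.

    ``true_params`` is present only for simulated stacks; measured stacks
    loaded from TIFF carry frames and layout only.
    """

    frames: np.ndarray
    layout: Optional[StackLayout] = None
    true_params: Optional[List[IlluminationParams]] = None
    source_id: str = ""

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        if self.frames.ndim != 3:
            raise ValueError("frames must be a (n_frames, H, W) array")
        if self.layout is not None and len(self.frames) != self.layout.n_frames:
            raise ValueError(
                f"stack has {len(self.frames)} frames but layout expects "
                f"{self.layout.n_frames}"
            )

    def __len__(self) -> int:
        return len(self.frames)


@dataclass
class TrainingPair:
    """A simulated raw stack and its clean ground-truth target.

    The target is the unmodified grayscale source image: the network learns to
    undo blur, noise and patterning in one step, rather than to imitate any
    particular analytical reconstruction.
    """

    input: RawStack
    target: np.ndarray

    def __post_init__(self) -> None:
        if self.target.shape != self.input.frames.shape[1:]:
            raise ValueError("target shape must match frame shape")


def prepare_ground_truth(image: Union[np.ndarray, str, Path], size: int = 512) -> np.ndarray:
    """Convert an arbitrary raster image to a ``size x size`` grayscale ground truth.

    Colour is collapsed by luminance weighting, the aspect ratio is handled by
    centre-crop to square followed by resampling, and intensities are mapped
    to [0, 1] (integer images by their dtype range; out-of-range float images
    by min-max).  An image already of the requested size in [0, 1] passes
    through unchanged up to dtype.
    """
    if isinstance(image, (str, Path)):
        import imageio.v3 as iio

        image = iio.imread(image)
    img = np.asarray(image)
    if img.size == 0:
        raise ValueError("empty image")
    if np.issubdtype(img.dtype, np.integer):
        img = img.astype(float) / np.iinfo(img.dtype).max
    else:
        img = img.astype(float)
    if img.ndim == 3:
        if img.shape[2] == 4:  # drop alpha
            img = img[:, :, :3]
        img = rgb2gray(img)
    elif img.ndim != 2:
        raise ValueError(f"expected a 2-D or 3-D image, got shape {img.shape}")
    if img.min() < 0 or img.max() > 1:
        lo, hi = img.min(), img.max()
        img = (img - lo) / (hi - lo) if hi > lo else np.zeros_like(img)
    h, w = img.shape
    if (h, w) != (size, size):
        side = min(h, w)
        top, left = (h - side) // 2, (w - side) // 2
        img = img[top : top + side, left : left + side]
        img = resize(img, (size, size), anti_aliasing=True, preserve_range=True)
        img = np.clip(img, 0.0, 1.0)
    return img


def sample_stack_params(
    layout: StackLayout,
    ranges: SimulationRanges,
    rng: Union[int, np.random.Generator, None] = None,
    orientation_offset: Optional[float] = None,
) -> List[IlluminationParams]:
    """Draw the illumination parameters for one stack.

    A single ``k0`` and ``m`` are drawn per stack; each orientation gets a
    Gaussian-jittered angle, each frame a Gaussian-jittered phase and an
    optional per-frame ``k0`` jitter.  Frames are ordered orientation-major
    (all phases of orientation 0, then orientation 1, ...), matching the
    conventional 9-frame acquisition order.  When ``orientation_offset`` is
    None a global offset is drawn uniformly from [0, pi): the network must not
    memorise absolute stripe directions.
    """
    gen = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    k0 = gen.uniform(*ranges.k0_range)
    m = gen.uniform(*ranges.m_range)
    if orientation_offset is None:
        orientation_offset = gen.uniform(0.0, np.pi)
    thetas = layout.base_orientations(orientation_offset)
    if ranges.angle_jitter_sd > 0:
        thetas = thetas + gen.normal(0.0, ranges.angle_jitter_sd, size=thetas.shape)
    phases = layout.base_phases()
    params: List[IlluminationParams] = []
    for theta in thetas:
        for phi in phases:
            if ranges.phase_jitter_sd > 0:
                phi = phi + gen.normal(0.0, ranges.phase_jitter_sd)
            frame_k0 = k0
            if ranges.k0_jitter_sd > 0:
                frame_k0 = max(k0 + gen.normal(0.0, ranges.k0_jitter_sd), 1e-6)
            params.append(IlluminationParams(k0=frame_k0, theta=float(theta), phi=float(phi), m=m))
    return params


def simulate_stack(
    gt: np.ndarray,
    params: Sequence[IlluminationParams],
    cfg: OpticalConfig,
    noise: NoiseSpec = NoiseSpec(model="none"),
    layout: Optional[StackLayout] = None,
    tf: Optional[TransferFunctions] = None,
    rng: Optional[np.random.Generator] = None,
    source_id: str = "",
) -> RawStack:
    """Simulate one raw SIM stack: one frame per illumination parameter set."""
    gt = np.asarray(gt, dtype=float)
    if gt.shape != (cfg.image_size, cfg.image_size):
        raise ValueError(
            f"ground truth shape {gt.shape} does not match image_size {cfg.image_size}"
        )
    if layout is not None and len(params) != layout.n_frames:
        raise ValueError("number of parameter sets does not match layout")
    if tf is None:
        tf = make_otf(cfg)
    if rng is None:
        rng = np.random.default_rng(noise.seed)
    frames = np.stack(
        [
            apply_forward(gt, illumination_pattern(p, cfg.image_size), tf, noise, rng=rng)
            for p in params
        ]
    )
    return RawStack(frames=frames, layout=layout, true_params=list(params), source_id=source_id)


# ---------------------------------------------------------------------------
# procedural ground-truth generator


def _draw_line(canvas: np.ndarray, r0, c0, r1, c1, value: float) -> None:
    from skimage.draw import line

    n = canvas.shape[0]
    rr, cc = line(int(r0) % n, int(c0) % n, int(r1) % n, int(c1) % n)
    keep = (rr >= 0) & (rr < n) & (cc >= 0) & (cc < n)
    canvas[rr[keep], cc[keep]] = np.maximum(canvas[rr[keep], cc[keep]], value)


def generate_procedural_image(size: int = 512, seed: Optional[int] = None) -> np.ndarray:
    """Composite a randomised synthetic ground truth in [0, 1].

    Stands in for a photographic image corpus so that no download is required.
    Each image mixes primitives chosen to span the spatial-frequency content a
    reconstruction network must learn from: smooth gradients, filled discs and
    polygons (low frequency), curved filaments (edges), line gratings of
    varying spacing and single-pixel points (energy at and beyond half the
    OTF cutoff).
    """
    if size < 16:
        raise ValueError("size must be >= 16")
    from skimage.draw import disk, polygon
    from scipy.ndimage import gaussian_filter

    rng = np.random.default_rng(seed)
    img = np.zeros((size, size))

    # smooth background: photographic images are dense, not sparse objects on
    # an empty field, so the canvas starts at a substantial fill level
    gy, gx = np.mgrid[0:size, 0:size] / size
    a, b = rng.uniform(-0.3, 0.3, 2)
    img += rng.uniform(0.15, 0.45) + a * (gx - 0.5) + b * (gy - 0.5)
    img = np.clip(img, 0.0, None)

    # filled polygons
    for _ in range(rng.integers(1, 4)):
        k = rng.integers(3, 7)
        cy, cx = rng.uniform(0, size, 2)
        ang = np.sort(rng.uniform(0, 2 * np.pi, k))
        rad = rng.uniform(size * 0.05, size * 0.25, k)
        rr, cc = polygon(cy + rad * np.sin(ang), cx + rad * np.cos(ang), shape=img.shape)
        img[rr, cc] += rng.uniform(0.1, 0.4)

    # discs
    for _ in range(rng.integers(3, 9)):
        cy, cx = rng.uniform(0, size, 2)
        rr, cc = disk((cy, cx), rng.uniform(1.5, size * 0.06), shape=img.shape)
        img[rr, cc] += rng.uniform(0.2, 0.7)

    # curved filaments: smoothed random walks
    for _ in range(rng.integers(2, 6)):
        npts = rng.integers(4, 9)
        pts = np.cumsum(rng.uniform(-size * 0.2, size * 0.2, (npts, 2)), axis=0)
        pts += rng.uniform(0, size, 2)
        val = rng.uniform(0.4, 1.0)
        for (r0, c0), (r1, c1) in zip(pts[:-1], pts[1:]):
            _draw_line(img, r0, c0, r1, c1, val)

    img = gaussian_filter(img, rng.uniform(0.4, 1.0))

    # line gratings of varying spacing in a random sub-window
    for _ in range(rng.integers(1, 3)):
        spacing = int(rng.integers(2, 9))
        w = int(rng.uniform(size * 0.15, size * 0.4))
        top, left = rng.integers(0, size - w, 2)
        val = rng.uniform(0.5, 1.0)
        sub = img[top : top + w, left : left + w]
        if rng.random() < 0.5:
            sub[:, ::spacing] = np.maximum(sub[:, ::spacing], val)
        else:
            sub[::spacing, :] = np.maximum(sub[::spacing, :], val)

    # single-pixel point emitters
    npts = rng.integers(10, 60)
    rr = rng.integers(0, size, npts)
    cc = rng.integers(0, size, npts)
    img[rr, cc] = rng.uniform(0.6, 1.0, npts)

    # robust contrast normalisation: photographic corpora fill the intensity
    # range; scaling by the max would let a single bright primitive leave the
    # rest of the image unrealistically dark
    hi = np.percentile(img, 99.0)
    if hi > 0:
        img = img / hi
    return np.clip(img, 0.0, 1.0)


def simulate_pairs(
    n: int,
    cfg: OpticalConfig = OpticalConfig(),
    layout: StackLayout = StackLayout(),
    ranges: Optional[SimulationRanges] = None,
    seed: int = 0,
    noise_model: str = "gaussian",
):
    """Simulate ``n`` training pairs in memory (procedural ground truths).

    Returns ``(stacks, targets, records)`` where ``stacks`` is
    ``(n, n_frames, H, W)``, ``targets`` is ``(n, H, W)`` and ``records``
    holds the sampled parameters per pair.  Deterministic given ``seed``;
    the same sampling scheme as :func:`build_dataset` without the file layer.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if ranges is None:
        ranges = SimulationRanges.for_config(cfg)
    tf = make_otf(cfg)
    children = np.random.SeedSequence(seed).spawn(n)
    stacks, targets, records = [], [], []
    for i in range(n):
        rng = np.random.default_rng(children[i])
        gt = generate_procedural_image(cfg.image_size, seed=int(rng.integers(2**31)))
        params = sample_stack_params(layout, ranges, rng)
        eta = float(rng.uniform(*ranges.noise_level_range))
        noise = NoiseSpec(model=noise_model if eta > 0 else "none", level=eta)
        stack = simulate_stack(gt, params, cfg, noise, layout=layout, tf=tf,
                               rng=rng, source_id=f"procedural:{i}")
        stacks.append(stack.frames)
        targets.append(gt)
        records.append({"noise_level": eta, "params": params})
    return np.stack(stacks), np.stack(targets), records


# ---------------------------------------------------------------------------
# dataset builder


def _params_record(p: IlluminationParams) -> dict:
    return {"k0": p.k0, "theta": p.theta, "phi": p.phi, "m": p.m, "i0": p.i0}


def _list_source_images(source: Union[str, Path]) -> List[Path]:
    src = Path(source)
    files = sorted(p for p in src.iterdir() if p.suffix.lower() in IMAGE_EXTENSIONS)
    if not files:
        raise ValueError(f"no images found in {src}")
    return files


def build_dataset(
    source: Union[str, Path],
    n: int,
    out_dir: Union[str, Path],
    cfg: OpticalConfig = OpticalConfig(),
    layout: StackLayout = StackLayout(),
    ranges: Optional[SimulationRanges] = None,
    seed: int = 0,
    validation_fraction: float = 0.1,
    noise_model: str = "gaussian",
) -> dict:
    """Simulate ``n`` training pairs and write them with a manifest.

    ``source`` is either a directory of images (cycled if shorter than ``n``)
    or the string ``"procedural"`` for the bundled generator.  Each pair gets
    a multi-page float32 TIFF stack, a single-page target TIFF and a manifest
    record with every sampled parameter; the run is fully determined by
    ``seed``.  A seeded random subset of pairs (``validation_fraction``) is
    tagged for validation.
    """
    import tifffile

    if n < 1:
        raise ValueError("n must be >= 1")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if ranges is None:
        ranges = SimulationRanges.for_config(cfg)
    procedural = str(source) == "procedural"
    files = None if procedural else _list_source_images(source)

    ss = np.random.SeedSequence(seed)
    children = ss.spawn(n + 1)
    n_val = int(round(validation_fraction * n))
    val_idx = set(
        np.random.default_rng(children[-1]).permutation(n)[:n_val].tolist()
    )

    records = []
    for i in range(n):
        rng = np.random.default_rng(children[i])
        if procedural:
            gt = generate_procedural_image(cfg.image_size, seed=rng.integers(2**31))
            src_id = f"procedural:{i}"
        else:
            path = files[i % len(files)]
            gt = prepare_ground_truth(path, cfg.image_size)
            src_id = str(path)
        params = sample_stack_params(layout, ranges, rng)
        eta = float(rng.uniform(*ranges.noise_level_range))
        noise = NoiseSpec(model=noise_model if eta > 0 else "none", level=eta)
        stack = simulate_stack(gt, params, cfg, noise, layout=layout, rng=rng, source_id=src_id)
        stack_path = out / f"pair_{i:04d}_stack.tif"
        target_path = out / f"pair_{i:04d}_gt.tif"
        tifffile.imwrite(stack_path, stack.frames.astype(np.float32))
        tifffile.imwrite(target_path, gt.astype(np.float32))
        records.append(
            {
                "index": i,
                "source_id": src_id,
                "stack_file": stack_path.name,
                "target_file": target_path.name,
                "validation": i in val_idx,
                "noise": {"model": noise.model, "level": eta},
                "frame_params": [_params_record(p) for p in params],
            }
        )

    manifest = {
        "seed": seed,
        "n_pairs": n,
        "optical_config": asdict(cfg),
        "layout": {
            "n_orientations": layout.n_orientations,
            "n_phases": layout.n_phases,
            "underdetermined": layout.underdetermined,
        },
        "ranges": asdict(ranges),
        "validation_fraction": validation_fraction,
        "pairs": records,
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return manifest


def load_dataset(data_dir: Union[str, Path]):
    """Read a written dataset back as ``(stacks, targets, manifest)`` arrays."""
    import tifffile

    data_dir = Path(data_dir)
    with open(data_dir / "manifest.json") as fh:
        manifest = json.load(fh)
    stacks, targets = [], []
    for rec in manifest["pairs"]:
        stacks.append(tifffile.imread(data_dir / rec["stack_file"]))
        targets.append(tifffile.imread(data_dir / rec["target_file"]))
    return np.stack(stacks), np.stack(targets), manifest
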