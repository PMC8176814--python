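"""Physical image-formation model for structured-illumination microscopy (SIM).

A fluorescent sample :math:`S(x,y)` is excited by a sinusoidal stripe pattern

.. math::

    I_{\\theta,\\phi}(x,y) = I_0\\left[1 - \\frac{m}{2}
        \\cos\\big(2\\pi(k_x x + k_y y) + \\phi\\big)\\right],

with ``[kx, ky] = [k0 cos(theta), k0 sin(theta)]``.  The emitted fluorescence
``S * I`` is blurred by the microscope point-spread function ``H`` and corrupted
by detector noise, giving one raw frame

.. math::

    D_{\\theta,\\phi}(x,y) = [S(x,y)\\,I_{\\theta,\\phi}(x,y)] \\otimes H(x,y) + N(x,y).

The optical transfer function (OTF) is the ideal incoherent diffraction-limited
one: the autocorrelation of a circular pupil, radially
``(2/pi)(arccos(rho) - rho sqrt(1 - rho^2))`` with ``rho = k / kc`` and cutoff
``kc = 2 NA / lambda``.  Blur is applied as multiplication by the OTF in
frequency space, i.e. circular convolution.

Conventions (fixed so simulations are bit-reproducible across front-ends):
pixel indices are 0-based, ``x`` is the column index and ``y`` the row index;
the stored OTF uses the centred-DFT layout (zero frequency at the array
centre); the stored PSF is centred at pixel ``(n//2, n//2)`` and sums to 1.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np

__all__ = [
    "OpticalConfig",
    "IlluminationParams",
    "TransferFunctions",
    "NoiseSpec",
    "make_otf",
    "illumination_pattern",
    "apply_forward",
]


@dataclass(frozen=True)
class OpticalConfig:
    """Optical parameters of the (simulated) microscope.

    Parameters
    ----------
    numerical_aperture : float
        Objective NA, dimensionless.
    emission_wavelength : float
        Fluorescence emission wavelength in nanometres.
    pixel_size : float
        Sample-plane pixel size in nanometres per pixel.
    image_size : int
        Side length of the (square) simulated image, in pixels.
        Must be even and at least 16.
    """

    numerical_aperture: float = 1.2
    emission_wavelength: float = 520.0
    pixel_size: float = 60.0
    image_size: int = 512

    def __post_init__(self) -> None:
        if self.numerical_aperture <= 0:
            raise ValueError("numerical_aperture must be > 0")
        if self.emission_wavelength <= 0:
            raise ValueError("emission_wavelength must be > 0 (nanometres)")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be > 0 (nanometres per pixel)")
        if self.image_size < 16 or self.image_size % 2:
            raise ValueError("image_size must be an even integer >= 16")

    @property
    def cutoff_frequency(self) -> float:
        """Incoherent OTF cutoff ``kc = 2 NA / lambda`` in cycles per pixel."""
        return 2.0 * self.numerical_aperture / self.emission_wavelength * self.pixel_size


@dataclass(frozen=True)
class IlluminationParams:
    """One sinusoidal illumination pattern.

    ``k0`` is the stripe spatial frequency in cycles per pixel, ``theta`` the
    orientation relative to the horizontal axis (radians), ``phi`` the lateral
    phase (radians), ``m`` in [0, 1] the modulation depth controlling how much
    super-resolution information the raw frame carries, and ``i0`` the mean
    illumination intensity.
    """

    k0: float
    theta: float
    phi: float
    m: float = 1.0
    i0: float = 1.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.m <= 1.0:
            raise ValueError("modulation depth m must lie in [0, 1]")
        if self.k0 <= 0:
            raise ValueError("k0 must be > 0 (cycles per pixel)")
        if self.i0 <= 0:
            raise ValueError("i0 must be > 0")

    @property
    def kx(self) -> float:
        return self.k0 * np.cos(self.theta)

    @property
    def ky(self) -> float:
        return self.k0 * np.sin(self.theta)


@dataclass(frozen=True)
class TransferFunctions:
    """Matched OTF/PSF pair on the discrete grid of an ``n x n`` image.

    ``otf`` is real, in [0, 1], centred-DFT layout, equal to 1 at zero
    frequency and 0 beyond ``cutoff_frequency``.  ``psf`` is its real-space
    transform pair, centred at ``(n//2, n//2)`` and normalised to unit sum
    (tiny negative ringing from discretisation is retained so the pair stays
    an exact transform pair).
    """

    otf: np.ndarray
    psf: np.ndarray
    cutoff_frequency: float

    @property
    def image_size(self) -> int:
        return self.otf.shape[0]


@dataclass(frozen=True)
class NoiseSpec:
    """Detector-noise model for the forward simulation.

    ``model='gaussian'`` adds white Gaussian noise of standard deviation
    ``level * sigma`` where ``sigma`` is the standard deviation of the
    noiseless blurred frame (the input to the noise stage).  ``model='poisson'``
    treats ``level`` as a photon-count scale: the frame is drawn as
    ``Poisson(level * frame) / level``.  ``model='none'`` disables noise.
    """

    model: str = "gaussian"
    level: float = 0.0
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        if self.model not in ("gaussian", "poisson", "none"):
            raise ValueError(f"unknown noise model {self.model!r}")
        if self.level < 0:
            raise ValueError("noise level must be >= 0")


def make_otf(cfg: OpticalConfig) -> TransferFunctions:
    """Build the diffraction-limited incoherent OTF and matching PSF.

    The OTF is the radially symmetric "chat" function
    ``(2/pi)(arccos(rho) - rho sqrt(1-rho^2))``, ``rho = k/kc``, evaluated on
    the centred discrete frequency grid of an ``image_size``-squared image; the
    PSF is its inverse DFT, normalised to unit sum.  If the optical cutoff
    exceeds the grid Nyquist frequency a warning is issued: the simulation is
    still valid but band-limited by the grid rather than by the optics.
    """
    n = cfg.image_size
    kc = cfg.cutoff_frequency
    if kc > 0.5:
        warnings.warn(
            f"optical cutoff {kc:.3f} cycles/pixel exceeds the grid Nyquist "
            "frequency 0.5; the simulation is band-limited by sampling, not "
            "by the optics",
            stacklevel=2,
        )
    freqs = np.fft.fftshift(np.fft.fftfreq(n))
    ky, kx = np.meshgrid(freqs, freqs, indexing="ij")
    rho = np.hypot(kx, ky) / kc
    otf = np.zeros((n, n))
    inside = rho < 1.0
    r = rho[inside]
    otf[inside] = (2.0 / np.pi) * (np.arccos(r) - r * np.sqrt(1.0 - r * r))
    psf = np.fft.fftshift(np.fft.ifft2(np.fft.ifftshift(otf)).real)
    psf = psf / psf.sum()
    return TransferFunctions(otf=otf, psf=psf, cutoff_frequency=kc)


def illumination_pattern(params: IlluminationParams, image_size: int) -> np.ndarray:
    """Evaluate the sinusoidal stripe pattern on the pixel grid.

    Returns ``I(x, y) = i0 [1 - (m/2) cos(2 pi (kx x + ky y) + phi)]`` as an
    ``image_size x image_size`` array indexed ``[y, x]`` (row, column); all
    values lie in ``[i0 (1 - m/2), i0 (1 + m/2)]``.
    """
    coords = np.arange(image_size)
    y, x = np.meshgrid(coords, coords, indexing="ij")
    arg = 2.0 * np.pi * (params.kx * x + params.ky * y) + params.phi
    return params.i0 * (1.0 - 0.5 * params.m * np.cos(arg))


def _as_rng(noise: NoiseSpec, rng: Optional[np.random.Generator]) -> np.random.Generator:
    if rng is not None:
        return rng
    return np.random.default_rng(noise.seed)


def apply_forward(
    sample: np.ndarray,
    illum: np.ndarray,
    tf: TransferFunctions,
    noise: NoiseSpec = NoiseSpec(model="none"),
    rng: Optional[np.random.Generator] = None,
) -> np.ndarray:
    """Form one raw SIM frame: ``D = (S * I) (x) H + N``.

    The blur is a circular convolution, applied as multiplication by the OTF
    in frequency space.  Gaussian noise is i.i.d. per pixel with standard
    deviation ``level * std(blurred frame)``.  The output is not clipped;
    clipping and quantisation happen only at export.

    Parameters
    ----------
    sample : 2-D array
        Ground-truth fluorophore density, values expected in [0, 1].
    illum : 2-D array
        Illumination intensity, same shape as ``sample``.
    tf : TransferFunctions
        Matched OTF/PSF pair on the same grid.
    noise : NoiseSpec
        Noise model; ``rng`` overrides ``noise.seed`` when given.
    """
    sample = np.asarray(sample, dtype=float)
    illum = np.asarray(illum, dtype=float)
    if sample.shape != illum.shape or sample.shape != tf.otf.shape:
        raise ValueError(
            f"shape mismatch: sample {sample.shape}, illumination {illum.shape}, "
            f"transfer functions {tf.otf.shape}"
        )
    emitted = sample * illum
    blurred = np.fft.ifft2(np.fft.fft2(emitted) * np.fft.ifftshift(tf.otf)).real
    if noise.model == "none" or noise.level == 0.0:
        return blurred
    gen = _as_rng(noise, rng)
    if noise.model == "gaussian":
        sigma = noise.level * blurred.std()
        return blurred + gen.normal(0.0, sigma, size=blurred.shape)
    # poisson: level is the photon count corresponding to unit intensity
    photons = gen.poisson(np.clip(blurred, 0.0, None) * noise.level)
    return photons / noise.level
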