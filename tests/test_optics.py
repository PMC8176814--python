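"""Physical forward model: OTF/PSF synthesis, stripe patterns, image formation."""

import numpy as np
import pytest
import sympy
from hypothesis import given, settings, strategies as st

import simrecon as sr
from simrecon.optics import apply_forward, illumination_pattern, make_otf


@pytest.fixture(scope="module")
def cfg():
    return sr.OpticalConfig(numerical_aperture=1.2, emission_wavelength=520.0,
                            pixel_size=60.0, image_size=64)


@pytest.fixture(scope="module")
def tf(cfg):
    return make_otf(cfg)


class TestOpticalConfig:
    @pytest.mark.parametrize("field,value", [
        ("numerical_aperture", 0.0), ("numerical_aperture", -1.0),
        ("emission_wavelength", 0.0), ("pixel_size", -5.0),
        ("image_size", 15), ("image_size", 33),
    ])
    def test_rejects_invalid_parameters(self, field, value):
        kwargs = {field: value}
        with pytest.raises(ValueError):
            sr.OpticalConfig(**kwargs)

    def test_cutoff_is_two_na_over_lambda_in_cycles_per_pixel(self, cfg):
        assert cfg.cutoff_frequency == pytest.approx(2 * 1.2 / 520.0 * 60.0)


class TestMakeOtf:
    def test_unity_at_zero_frequency(self, cfg, tf):
        n = cfg.image_size
        assert tf.otf[n // 2, n // 2] == pytest.approx(1.0)

    def test_zero_beyond_cutoff(self, cfg, tf):
        n = cfg.image_size
        freqs = np.fft.fftshift(np.fft.fftfreq(n))
        ky, kx = np.meshgrid(freqs, freqs, indexing="ij")
        beyond = np.hypot(kx, ky) > tf.cutoff_frequency
        assert np.all(tf.otf[beyond] == 0.0)

    def test_half_cutoff_value_matches_arbitrary_precision_pupil_autocorrelation(self):
        # chat function at rho = 1/2, evaluated independently with sympy
        rho = sympy.Rational(1, 2)
        expected = float((2 / sympy.pi) * (sympy.acos(rho) - rho * sympy.sqrt(1 - rho**2)))
        # place a grid frequency exactly at kc/2: choose cfg with kc = 0.25
        cfg = sr.OpticalConfig(numerical_aperture=1.0, emission_wavelength=480.0,
                               pixel_size=60.0, image_size=64)
        assert cfg.cutoff_frequency == pytest.approx(0.25)
        tf = make_otf(cfg)
        n = 64
        # kc/2 = 0.125 cycles/pixel = 8 bins from centre on a 64-grid
        assert tf.otf[n // 2, n // 2 + 8] == pytest.approx(expected, abs=1e-12)
        assert expected == pytest.approx(0.391, abs=5e-4)

    def test_psf_is_normalised_real_transform_pair_of_otf(self, tf):
        assert tf.psf.sum() == pytest.approx(1.0, abs=1e-12)
        assert tf.psf.min() > -1e-8  # discretisation ringing only
        back = np.fft.fftshift(np.fft.fft2(np.fft.ifftshift(tf.psf))).real
        assert np.allclose(back, tf.otf, atol=1e-8)

    def test_warns_when_cutoff_exceeds_grid_nyquist(self):
        cfg = sr.OpticalConfig(numerical_aperture=1.4, emission_wavelength=500.0,
                               pixel_size=100.0, image_size=32)
        assert cfg.cutoff_frequency > 0.5
        with pytest.warns(UserWarning, match="Nyquist"):
            make_otf(cfg)


class TestIlluminationPattern:
    def test_zero_modulation_gives_constant_mean_intensity(self):
        p = sr.IlluminationParams(k0=0.2, theta=0.3, phi=1.0, m=0.0, i0=2.5)
        img = illumination_pattern(p, 32)
        assert np.allclose(img, 2.5)

    def test_origin_value_at_full_modulation(self):
        # I(0,0) = I0 (1 - m/2 cos(phi)) = 0.5 for phi=0, m=1, I0=1
        p = sr.IlluminationParams(k0=0.2, theta=0.3, phi=0.0, m=1.0, i0=1.0)
        assert illumination_pattern(p, 16)[0, 0] == pytest.approx(0.5)

    @settings(deadline=None, max_examples=25)
    @given(k0=st.floats(0.05, 0.45), theta=st.floats(0, 2 * np.pi),
           m=st.floats(0, 1), i0=st.floats(0.1, 3.0))
    def test_three_phase_mean_is_homogeneous(self, k0, theta, m, i0):
        """Mean over phases {0, 2pi/3, 4pi/3} is I0 at every pixel."""
        total = sum(
            illumination_pattern(
                sr.IlluminationParams(k0=k0, theta=theta, phi=phi, m=m, i0=i0), 32)
            for phi in (0.0, 2 * np.pi / 3, 4 * np.pi / 3)
        )
        assert np.abs(total / 3 - i0).max() < 1e-9

    def test_range_bounds(self):
        p = sr.IlluminationParams(k0=0.13, theta=1.1, phi=0.7, m=0.8, i0=1.5)
        img = illumination_pattern(p, 64)
        assert img.min() >= 1.5 * (1 - 0.4) - 1e-12
        assert img.max() <= 1.5 * (1 + 0.4) + 1e-12

    def test_rejects_invalid_modulation_depth(self):
        with pytest.raises(ValueError):
            sr.IlluminationParams(k0=0.2, theta=0.0, phi=0.0, m=1.5)


def brute_force_circular_convolution(img, kernel):
    """O(n^4) direct-space circular convolution oracle."""
    n = img.shape[0]
    out = np.zeros_like(img)
    for x in range(n):
        for y in range(n):
            acc = 0.0
            for u in range(n):
                for v in range(n):
                    acc += kernel[u, v] * img[(x - u) % n, (y - v) % n]
            out[x, y] = acc
    return out


class TestApplyForward:
    def test_identity_otf_returns_emitted_light(self, cfg):
        n = 8
        rng = np.random.default_rng(0)
        s, i = rng.random((n, n)), rng.random((n, n))
        ident = sr.TransferFunctions(otf=np.ones((n, n)),
                                     psf=np.zeros((n, n)), cutoff_frequency=1.0)
        out = apply_forward(s, i, ident, sr.NoiseSpec(model="none"))
        assert np.allclose(out, s * i, atol=1e-12)

    def test_matches_direct_space_convolution_oracle(self):
        # hand-built 8x8 chat-function OTF (below the config minimum size,
        # which keeps the O(n^4) oracle instant)
        n, kc = 8, 0.3
        freqs = np.fft.fftshift(np.fft.fftfreq(n))
        ky, kx = np.meshgrid(freqs, freqs, indexing="ij")
        rho = np.hypot(kx, ky) / kc
        otf = np.zeros((n, n))
        inside = rho < 1
        otf[inside] = (2 / np.pi) * (np.arccos(rho[inside])
                                     - rho[inside] * np.sqrt(1 - rho[inside] ** 2))
        tf = sr.TransferFunctions(otf=otf, psf=np.zeros((n, n)), cutoff_frequency=kc)
        rng = np.random.default_rng(1)
        s, i = rng.random((n, n)), rng.random((n, n))
        fast = apply_forward(s, i, tf, sr.NoiseSpec(model="none"))
        kernel = np.fft.ifft2(np.fft.ifftshift(otf)).real  # origin-indexed PSF
        slow = brute_force_circular_convolution(s * i, kernel)
        assert np.abs(fast - slow).max() < 1e-8

    def test_gaussian_noise_level_scales_with_blurred_frame_std(self, cfg):
        big = sr.OpticalConfig(image_size=512)
        tf = make_otf(big)
        gt = sr.generate_procedural_image(512, seed=2)
        illum = illumination_pattern(
            sr.IlluminationParams(k0=0.2, theta=0.4, phi=0.1, m=0.9), 512)
        clean = apply_forward(gt, illum, tf, sr.NoiseSpec(model="none"))
        noisy = apply_forward(gt, illum, tf, sr.NoiseSpec(model="gaussian", level=2.0),
                              rng=np.random.default_rng(3))
        measured = (noisy - clean).std()
        assert measured == pytest.approx(2.0 * clean.std(), rel=0.05)

    def test_linearity_without_noise(self, cfg, tf):
        rng = np.random.default_rng(4)
        s1, s2 = rng.random((64, 64)), rng.random((64, 64))
        illum = illumination_pattern(
            sr.IlluminationParams(k0=0.2, theta=0.9, phi=0.0), 64)
        none = sr.NoiseSpec(model="none")
        lhs = apply_forward(0.3 * s1 + 0.6 * s2, illum, tf, none)
        rhs = 0.3 * apply_forward(s1, illum, tf, none) + 0.6 * apply_forward(s2, illum, tf, none)
        assert np.allclose(lhs, rhs, atol=1e-10)

    def test_centred_point_source_reproduces_psf(self, cfg, tf):
        n = cfg.image_size
        point = np.zeros((n, n)); point[n // 2, n // 2] = 1.0
        out = apply_forward(point, np.ones((n, n)), tf, sr.NoiseSpec(model="none"))
        assert np.abs(out - tf.psf).max() < 1e-8

    def test_energy_conserved_without_noise(self, cfg, tf):
        rng = np.random.default_rng(5)
        s = rng.random((64, 64))
        illum = illumination_pattern(sr.IlluminationParams(k0=0.22, theta=0.2, phi=1.2), 64)
        out = apply_forward(s, illum, tf, sr.NoiseSpec(model="none"))
        assert out.sum() == pytest.approx((s * illum).sum(), rel=1e-6)

    def test_spectrum_confined_to_otf_support(self, cfg, tf):
        """Raw-frame spectra vanish outside the OTF support: the pattern only
        moves super-resolution content inside the passband, which is the basis
        of the SIM reconstruction problem."""
        gt = sr.generate_procedural_image(64, seed=6)
        illum = illumination_pattern(sr.IlluminationParams(k0=0.2, theta=0.5, phi=0.3), 64)
        out = apply_forward(gt, illum, tf, sr.NoiseSpec(model="none"))
        spec = np.abs(np.fft.fftshift(np.fft.fft2(out)))
        outside = tf.otf == 0.0
        assert spec[outside].max() < 1e-8 * spec.max()

    def test_shape_mismatch_rejected(self, cfg, tf):
        with pytest.raises(ValueError, match="shape"):
            apply_forward(np.ones((32, 32)), np.ones((64, 64)), tf)

    def test_poisson_noise_preserves_mean(self, cfg, tf):
        gt = sr.generate_procedural_image(64, seed=7)
        illum = np.ones((64, 64))
        clean = apply_forward(gt, illum, tf, sr.NoiseSpec(model="none"))
        noisy = apply_forward(gt, illum, tf,
                              sr.NoiseSpec(model="poisson", level=5000.0),
                              rng=np.random.default_rng(8))
        assert noisy.mean() == pytest.approx(clean.mean(), rel=0.01)
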