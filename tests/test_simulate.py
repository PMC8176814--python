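"""Stack simulator: ground-truth preparation, parameter sampling, datasets."""

import hashlib
import json

import numpy as np
import pytest

import simrecon as sr


@pytest.fixture(scope="module")
def cfg():
    return sr.OpticalConfig(image_size=64)


class TestPrepareGroundTruth:
    def test_colour_image_becomes_square_grayscale_in_unit_range(self):
        rng = np.random.default_rng(0)
        img = rng.integers(0, 256, size=(96, 128, 3), dtype=np.uint8)
        out = sr.prepare_ground_truth(img, size=64)
        assert out.shape == (64, 64)
        assert out.min() >= 0.0 and out.max() <= 1.0

    def test_idempotent_on_conforming_input(self):
        rng = np.random.default_rng(1)
        img = rng.random((64, 64))
        out = sr.prepare_ground_truth(img, size=64)
        assert np.allclose(out, img)

    def test_constant_white_maps_to_one(self):
        img = np.full((64, 64), 255, dtype=np.uint8)
        assert np.allclose(sr.prepare_ground_truth(img, size=64), 1.0)

    def test_empty_image_rejected(self):
        with pytest.raises(ValueError):
            sr.prepare_ground_truth(np.empty((0, 0)), size=64)


class TestStackLayout:
    def test_frame_count_is_orientations_times_phases(self):
        assert sr.StackLayout(3, 3).n_frames == 9
        assert sr.StackLayout(5, 5).n_frames == 25

    def test_fewer_than_three_phases_flagged_underdetermined(self):
        assert sr.StackLayout(3, 2).underdetermined
        assert not sr.StackLayout(3, 3).underdetermined


class TestSampleStackParams:
    def test_zero_jitter_gives_canonical_phases_and_angles(self, cfg):
        layout = sr.StackLayout()
        ranges = sr.SimulationRanges.for_config(cfg, phase_jitter_sd=0.0,
                                                angle_jitter_sd=0.0)
        params = sr.sample_stack_params(layout, ranges, rng=0,
                                        orientation_offset=0.0)
        assert len(params) == 9
        phases = np.array([p.phi for p in params]).reshape(3, 3)
        assert np.allclose(phases, [0, 2 * np.pi / 3, 4 * np.pi / 3])
        thetas = np.array([p.theta for p in params]).reshape(3, 3)[:, 0]
        assert np.allclose(np.diff(thetas), np.pi / 3)
        # one k0 and m per stack
        assert len({p.k0 for p in params}) == 1
        assert len({p.m for p in params}) == 1

    def test_deterministic_given_seed(self, cfg):
        layout = sr.StackLayout()
        ranges = sr.SimulationRanges.for_config(cfg)
        a = sr.sample_stack_params(layout, ranges, rng=42)
        b = sr.sample_stack_params(layout, ranges, rng=42)
        assert a == b

    def test_phase_jitter_sd_calibrated(self, cfg):
        """Monte-Carlo: the sample SD of phase residuals matches the setting."""
        layout = sr.StackLayout(n_orientations=1, n_phases=3)
        ranges = sr.SimulationRanges.for_config(cfg, phase_jitter_sd=0.1,
                                                angle_jitter_sd=0.0)
        base = layout.base_phases()
        residuals = []
        rng = np.random.default_rng(2)
        for _ in range(3500):
            params = sr.sample_stack_params(layout, ranges, rng)
            residuals.extend(p.phi - b for p, b in zip(params, base))
        assert np.std(residuals) == pytest.approx(0.1, rel=0.05)

    def test_empty_ranges_rejected(self):
        with pytest.raises(ValueError):
            sr.SimulationRanges(k0_range=(0.3, 0.2))


class TestSimulateStack:
    @pytest.mark.parametrize("n_orient,n_phase", [(3, 3), (5, 5)])
    def test_frame_count_follows_layout(self, cfg, n_orient, n_phase):
        layout = sr.StackLayout(n_orient, n_phase)
        ranges = sr.SimulationRanges.for_config(cfg)
        gt = sr.generate_procedural_image(64, seed=3)
        params = sr.sample_stack_params(layout, ranges, rng=4)
        stack = sr.simulate_stack(gt, params, cfg, layout=layout)
        assert len(stack) == n_orient * n_phase
        assert stack.frames.shape[1:] == (64, 64)

    def test_noiseless_ideal_mean_is_widefield_image(self, cfg):
        """With canonical phases the stripes cancel: the stack mean equals the
        homogeneously illuminated blurred sample."""
        layout = sr.StackLayout()
        ranges = sr.SimulationRanges.for_config(cfg, phase_jitter_sd=0.0,
                                                angle_jitter_sd=0.0)
        gt = sr.generate_procedural_image(64, seed=5)
        params = sr.sample_stack_params(layout, ranges, rng=6)
        tf = sr.make_otf(cfg)
        stack = sr.simulate_stack(gt, params, cfg, layout=layout, tf=tf)
        i0 = params[0].i0
        widefield = sr.apply_forward(gt, np.full((64, 64), i0), tf,
                                     sr.NoiseSpec(model="none"))
        assert np.abs(stack.frames.mean(axis=0) - widefield).max() < 1e-6

    def test_per_orientation_mean_matches_widefield(self, cfg):
        layout = sr.StackLayout()
        ranges = sr.SimulationRanges.for_config(cfg, phase_jitter_sd=0.0,
                                                angle_jitter_sd=0.0)
        gt = sr.generate_procedural_image(64, seed=7)
        params = sr.sample_stack_params(layout, ranges, rng=8)
        stack = sr.simulate_stack(gt, params, cfg, layout=layout)
        full_mean = stack.frames.mean(axis=0)
        for o in range(3):
            orient_mean = stack.frames[o * 3 : (o + 1) * 3].mean(axis=0)
            assert np.abs(orient_mean - full_mean).max() < 1e-6

    def test_layout_mismatch_rejected(self, cfg):
        gt = sr.generate_procedural_image(64, seed=9)
        params = sr.sample_stack_params(sr.StackLayout(),
                                        sr.SimulationRanges.for_config(cfg), rng=10)
        with pytest.raises(ValueError):
            sr.simulate_stack(gt, params, cfg, layout=sr.StackLayout(5, 5))


class TestProceduralImages:
    def test_deterministic_given_seed(self):
        a = sr.generate_procedural_image(64, seed=11)
        b = sr.generate_procedural_image(64, seed=11)
        assert np.array_equal(a, b)

    def test_output_in_unit_range(self):
        for seed in range(5):
            img = sr.generate_procedural_image(48, seed=seed)
            assert img.min() >= 0.0 and img.max() <= 1.0

    def test_high_frequency_content_above_half_cutoff(self):
        """At least 90% of generated images carry spectral energy beyond half
        the OTF cutoff — the content a reconstruction network must recover."""
        cfg = sr.OpticalConfig(image_size=64)
        half_kc = cfg.cutoff_frequency / 2
        freqs = np.fft.fftshift(np.fft.fftfreq(64))
        ky, kx = np.meshgrid(freqs, freqs, indexing="ij")
        beyond = np.hypot(kx, ky) > half_kc
        n_ok = 0
        for seed in range(30):
            img = sr.generate_procedural_image(64, seed=seed)
            spec = np.abs(np.fft.fftshift(np.fft.fft2(img))) ** 2
            frac = spec[beyond].sum() / spec.sum()
            n_ok += frac > 1e-4
        assert n_ok >= 27

    def test_small_sizes_rejected(self):
        with pytest.raises(ValueError):
            sr.generate_procedural_image(8, seed=0)


class TestBuildDataset:
    def test_manifest_bytes_reproducible_and_roundtrip(self, cfg, tmp_path):
        out1, out2 = tmp_path / "a", tmp_path / "b"
        for out in (out1, out2):
            sr.build_dataset("procedural", 4, out, cfg=cfg, seed=13)
        m1 = (out1 / "manifest.json").read_bytes()
        m2 = (out2 / "manifest.json").read_bytes()
        assert m1 == m2

        stacks, targets, manifest = sr.load_dataset(out1)
        assert stacks.shape == (4, 9, 64, 64)
        assert targets.shape == (4, 64, 64)
        # re-simulating with the recorded parameters reproduces the frames
        rec = manifest["pairs"][0]
        params = [sr.IlluminationParams(**p) for p in rec["frame_params"]]
        assert rec["noise"]["level"] > 0  # stored frames include seeded noise
        clean = sr.simulate_stack(targets[0], params, cfg,
                                  sr.NoiseSpec(model="none"))
        resid = stacks[0] - clean.frames
        # residual is pure Gaussian noise at the recorded level
        sigma = rec["noise"]["level"] * clean.frames.std(axis=(1, 2))
        assert np.abs(resid.std(axis=(1, 2)) / sigma - 1).max() < 0.1

    def test_procedural_targets_are_distinct(self, cfg, tmp_path):
        sr.build_dataset("procedural", 12, tmp_path / "d", cfg=cfg, seed=14,
                         validation_fraction=0.0)
        stacks, targets, _ = sr.load_dataset(tmp_path / "d")
        hashes = {hashlib.sha1(t.tobytes()).hexdigest() for t in targets}
        assert len(hashes) == 12

    def test_validation_split_recorded(self, cfg, tmp_path):
        manifest = sr.build_dataset("procedural", 8, tmp_path / "v", cfg=cfg,
                                    seed=15, validation_fraction=0.25)
        flags = [rec["validation"] for rec in manifest["pairs"]]
        assert sum(flags) == 2

    def test_source_folder_inputs(self, cfg, tmp_path):
        import imageio.v3 as iio

        src = tmp_path / "src"
        src.mkdir()
        rng = np.random.default_rng(16)
        for i in range(2):
            iio.imwrite(src / f"img{i}.png",
                        rng.integers(0, 255, (80, 100, 3), dtype=np.uint8))
        manifest = sr.build_dataset(src, 3, tmp_path / "o", cfg=cfg, seed=17)
        assert manifest["n_pairs"] == 3
        assert "img0" in manifest["pairs"][0]["source_id"]

    def test_empty_source_rejected(self, cfg, tmp_path):
        empty = tmp_path / "none"
        empty.mkdir()
        with pytest.raises(ValueError, match="no images"):
            sr.build_dataset(empty, 2, tmp_path / "x", cfg=cfg)


class TestSimulatePairs:
    def test_deterministic_and_shaped(self, cfg):
        s1, t1, r1 = sr.simulate_pairs(3, cfg=cfg, seed=18)
        s2, t2, _ = sr.simulate_pairs(3, cfg=cfg, seed=18)
        assert np.array_equal(s1, s2) and np.array_equal(t1, t2)
        assert s1.shape == (3, 9, 64, 64) and t1.shape == (3, 64, 64)
        assert len(r1) == 3
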