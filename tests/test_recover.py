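"""Collaborative flux recovery: cubelets, thresholding, matching, Wiener, stages."""

import numpy as np
import pytest

from caspi import (
    FluxCube,
    LaserPrior,
    RecoverConfig,
    SceneSpec,
    SimConfig,
    caspi,
    discrete_gaussian_pulse,
    multipath_flux,
    noise_stats,
    recover_stage,
    simulate_cube,
)
from caspi.core import NoiseStats
from caspi.recover import (
    aggregate,
    block_match,
    extract_cubelet,
    guided_estimate,
    hard_threshold_estimate,
    noise_band,
    select_initial,
    wiener_refine,
)


@pytest.fixture
def band_and_laser():
    laser = LaserPrior("gaussian", dt=100e-12, fwhm=800e-12)
    return noise_band(laser, 64), laser


class TestExtractCubelet:
    def test_corner_window(self, rng):
        cube = rng.random((10, 12, 16))
        np.testing.assert_array_equal(
            extract_cubelet(cube, (0, 0), 4, 4), cube[:4, :4]
        )

    def test_out_of_bounds_raises(self, rng):
        cube = rng.random((10, 12, 16))
        with pytest.raises(ValueError, match="out of bounds"):
            extract_cubelet(cube, (7, 0), 4, 4)

    def test_roundtrip_writeback(self, rng):
        cube = rng.random((10, 12, 16))
        before = cube.copy()
        block = extract_cubelet(cube, (3, 5), 4, 4).copy()
        cube[3:7, 5:9] = block
        np.testing.assert_array_equal(cube, before)


class TestHardThreshold:
    def test_noiseless_bandlimited_block_preserved(self, band_and_laser, rng):
        # a block with exactly zero content in the pure noise band passes
        # through thresholding unchanged (the threshold itself is zero)
        band, laser = band_and_laser
        spec = np.zeros((8, 8, 64), dtype=complex)
        keep_t = ~band.member
        spec[0, 0, keep_t] = rng.normal(size=keep_t.sum()) + 1j * rng.normal(size=keep_t.sum())
        spec[0, 0, 0] = 50.0
        block = np.real(np.fft.ifftn(spec))
        stats = noise_stats(np.fft.fftn(block), band)
        assert stats.mean_abs < 1e-10
        out = hard_threshold_estimate(block, band, stats)
        assert np.abs(out - block).max() < 1e-8 * np.abs(block).max()

    def test_pure_noise_reduced_to_dc(self, band_and_laser, rng):
        band, _ = band_and_laser
        block = rng.normal(0, 1.0, (8, 8, 64))
        stats = noise_stats(np.fft.fftn(block), band)
        out = hard_threshold_estimate(block, band, stats)
        energy_in = ((block - block.mean()) ** 2).sum()
        energy_out = ((out - out.mean()) ** 2).sum()
        assert energy_out < 0.01 * energy_in  # >= 99% non-DC energy removed

    def test_homogeneous_in_joint_scaling(self, band_and_laser, rng):
        band, _ = band_and_laser
        block = rng.normal(2, 1.0, (4, 4, 64))
        stats = noise_stats(np.fft.fftn(block), band)
        out1 = hard_threshold_estimate(block, band, stats)
        stats2 = noise_stats(np.fft.fftn(3.0 * block), band)
        out2 = hard_threshold_estimate(3.0 * block, band, stats2)
        np.testing.assert_allclose(out2, 3.0 * out1, rtol=1e-10)


class TestGuidedEstimate:
    def test_flat_guide_gives_spatial_mean(self, rng):
        block = rng.random((4, 4, 8))
        out = guided_estimate(block, np.ones((4, 4)))
        expected = np.tile(block.mean(axis=(0, 1)), (4, 4, 1))
        np.testing.assert_allclose(out, expected, atol=1e-12)

    def test_matches_brute_force_circular_convolution(self, rng):
        # the spectral mask is exactly circular convolution with the unit-sum
        # guide along the spatial axes; oracle: explicit double loop
        block = rng.random((4, 4, 6))
        guide = rng.random((4, 4)) + 0.1
        out = guided_estimate(block, guide)
        g = guide / guide.sum()
        ref = np.zeros_like(block)
        for i in range(4):
            for j in range(4):
                for a in range(4):
                    for b in range(4):
                        ref[i, j] += g[a, b] * block[(i - a) % 4, (j - b) % 4]
        np.testing.assert_allclose(out, ref, atol=1e-12)

    def test_smooth_separable_block_pattern_preserved(self):
        # rank-1 block with a smooth intensity as its own guide: the spatial
        # pattern survives the (low-pass) guided filtering
        i, j = np.meshgrid(np.arange(8), np.arange(8), indexing="ij")
        # cosine patterns: zero-phase spectra, so the guide's (squared)
        # spectral mask rescales but does not shift them
        spatial = 1.5 + np.cos(2 * np.pi * i / 8) * 0.5 + np.cos(2 * np.pi * j / 8) * 0.3
        temporal = np.exp(-np.arange(16) / 5.0)
        block = spatial[:, :, None] * temporal[None, None, :]
        out = guided_estimate(block, spatial)
        corr = np.corrcoef(out.sum(axis=2).ravel(), spatial.ravel())[0, 1]
        # the mask rescales each cosine by its own (positive) coefficient, so
        # the pattern is attenuated but not displaced
        assert corr > 0.95

    def test_spatial_sums_preserved_per_bin(self, rng):
        block = rng.random((6, 6, 12))
        guide = rng.random((6, 6)) + 0.1
        out = guided_estimate(block, guide)
        np.testing.assert_allclose(
            out.sum(axis=(0, 1)), block.sum(axis=(0, 1)), rtol=1e-10
        )

    def test_all_zero_guide_raises(self, rng):
        with pytest.raises(ValueError, match="zero"):
            guided_estimate(rng.random((4, 4, 8)), np.zeros((4, 4)))


class TestSelectInitial:
    def test_noise_free_chooses_thresholding(self, band_and_laser):
        band, _ = band_and_laser
        pulse = discrete_gaussian_pulse(20, 800e-12, 100e-12, 64)
        block = np.tile(pulse, (4, 4, 1))
        stats = noise_stats(np.fft.fftn(block), band)
        out = select_initial(block, band, stats, 1.25, np.ones((4, 4)))
        # thresholding branch chosen (R huge): output is NOT the spatial mean
        # (which the guided branch with a flat patch would give), and it keeps
        # the block up to the tiny Gaussian band tail it may zero out
        assert np.abs(out - block).max() < 1e-4 * block.max()

    def test_pure_noise_chooses_guided(self, band_and_laser, rng):
        band, _ = band_and_laser
        block = rng.normal(0, 1, (4, 4, 64))
        stats = noise_stats(np.fft.fftn(block), band)
        out = select_initial(block, band, stats, 1.25, np.ones((4, 4)))
        expected = np.tile(block.mean(axis=(0, 1)), (4, 4, 1))  # guided, flat
        np.testing.assert_allclose(out, expected, atol=1e-12)

    def test_branch_invariant_to_scaling(self, band_and_laser, rng):
        from caspi import snr_ratio

        band, _ = band_and_laser
        block = rng.normal(1, 1, (4, 4, 64))
        r1 = snr_ratio(noise_stats(np.fft.fftn(block), band))
        r2 = snr_ratio(noise_stats(np.fft.fftn(17.0 * block), band))
        assert r1 == pytest.approx(r2, rel=1e-9)


class TestBlockMatch:
    def test_constant_guide_tie_break(self):
        cfg = RecoverConfig(cy=4, cx=4, n_sim=4, s_intra=9, min_sep=0)
        guide = np.ones((16, 16))
        got = block_match(guide, (6, 6), cfg)
        # reference first, then row-major scan of the clamped window
        assert got[0] == (6, 6)
        assert got[1:] == [(2, 2), (2, 3), (2, 4)]

    def test_min_sep_skips_adjacent(self):
        cfg = RecoverConfig(cy=4, cx=4, n_sim=4, s_intra=9, min_sep=3)
        got = block_match(np.ones((16, 16)), (6, 6), cfg)
        for i, a in enumerate(got):
            for b in got[i + 1 :]:
                assert max(abs(a[0] - b[0]), abs(a[1] - b[1])) >= 3

    def test_repeated_texture_found(self, rng):
        cfg = RecoverConfig(cy=4, cx=4, n_sim=3, s_intra=17, min_sep=0)
        tile = rng.random((8, 8))
        guide = np.tile(tile, (3, 3))  # exact repeats at offsets of 8
        got = block_match(guide, (8, 8), cfg)
        assert got[0] == (8, 8)
        # all returned anchors are exact matches (distance 0)
        patches = np.lib.stride_tricks.sliding_window_view(guide, (4, 4), axis=(0, 1))
        for a in got[1:]:
            assert ((patches[a] - patches[8, 8]) ** 2).sum() == pytest.approx(0.0, abs=1e-20)

    def test_self_distance_zero_and_reference_first(self, rng):
        cfg = RecoverConfig(cy=4, cx=4, n_sim=5, s_intra=9)
        guide = rng.random((20, 20))
        got = block_match(guide, (10, 10), cfg)
        assert got[0] == (10, 10)
        assert len(set(got)) == len(got)

    def test_fewer_candidates_than_nsim(self):
        cfg = RecoverConfig(cy=4, cx=4, n_sim=50, s_intra=5, min_sep=0)
        got = block_match(np.ones((8, 8)), (2, 2), cfg)
        assert 0 < len(got) <= 25  # whole clamped window, flagged by length


class TestGatherSet:
    def test_reference_first_and_shape(self, rng):
        from caspi.recover import gather_set

        cube = rng.random((12, 12, 8))
        anchors = [(4, 4), (0, 0), (6, 2)]
        cs = gather_set(cube, anchors, 4, 4)
        assert cs.data.shape == (4, 4, 8, 3)
        np.testing.assert_array_equal(cs.data[..., 0], cube[4:8, 4:8])
        assert cs.anchors[0] == (4, 4)

    def test_duplicate_anchors_rejected(self, rng):
        from caspi.recover import gather_set

        with pytest.raises(ValueError, match="unique"):
            gather_set(rng.random((12, 12, 8)), [(0, 0), (0, 0)], 4, 4)


class TestAggregate:
    def test_constant_blocks_conserved(self):
        shape = (6, 6, 4)
        blocks = [np.full((4, 4, 4), 3.7) for _ in range(4)]
        anchors = [(0, 0), (0, 2), (2, 0), (2, 2)]
        out = aggregate(blocks, anchors, [1.0, 0.2, 5.0, 0.01], shape)
        np.testing.assert_allclose(out, 3.7)

    def test_weight_limit_selects_first_block(self):
        shape = (4, 4, 2)
        b1, b2 = np.ones((4, 4, 2)), 2 * np.ones((4, 4, 2))
        out = aggregate([b1, b2], [(0, 0), (0, 0)], [1.0, 1e-12], shape)
        np.testing.assert_allclose(out, 1.0, rtol=1e-9)

    def test_equal_weights_match_brute_force(self, rng):
        # brute-force accumulation oracle on a 12x12x16 cube
        shape = (12, 12, 16)
        anchors = [(r, c) for r in range(0, 9, 2) for c in range(0, 9, 2)]
        blocks = [rng.random((4, 4, 16)) for _ in anchors]
        out = aggregate(blocks, anchors, [1.0] * len(anchors), shape)
        num = np.zeros(shape)
        cnt = np.zeros(shape)
        for blk, (r, c) in zip(blocks, anchors):
            num[r : r + 4, c : c + 4] += blk
            cnt[r : r + 4, c : c + 4] += 1
        np.testing.assert_allclose(out, num / cnt, rtol=1e-12)

    def test_uncovered_pixel_raises(self):
        with pytest.raises(ValueError, match="uncovered"):
            aggregate([np.ones((2, 2, 3))], [(0, 0)], [1.0], (5, 5, 3))


class TestWienerRefine:
    def test_zero_initial_energy_gives_zero(self, rng):
        noisy = rng.random((4, 4, 8))
        out = wiener_refine(noisy, np.zeros((4, 4, 8)), NoiseStats(0, 1.0, 0, 1))
        np.testing.assert_allclose(out, 0.0, atol=1e-12)

    def test_zero_noise_passthrough(self, rng):
        noisy = rng.random((4, 4, 8))
        a2 = rng.random((4, 4, 8))
        out = wiener_refine(noisy, a2, NoiseStats(0, 0.0, 0, 1))
        np.testing.assert_allclose(out, noisy)

    def test_coefficients_strictly_inside_unit_interval(self, rng):
        a2 = rng.random((4, 4, 8)) + 0.1
        w = a2 / (a2 + 0.5)
        assert np.all(w > 0) and np.all(w < 1)


class TestRecoverStage:
    def small_scene(self, seed=0, n_sig=2.0, n_bkg=50.0):
        laser = LaserPrior("gaussian", dt=100e-12, fwhm=400e-12)
        cfg = SimConfig(nt=64, dt=100e-12, n_cycle=1000, laser=laser, seed=seed)
        depth = np.full((16, 16), 0.4)
        depth[:, 8:] = 0.7
        scene = SceneSpec(np.ones((16, 16)), depth=depth, n_sig=n_sig, n_bkg=n_bkg)
        return scene, cfg, laser

    def test_noise_free_cube_self_consistent(self):
        scene, cfg, laser = self.small_scene(n_bkg=5.0)
        _, truth = simulate_cube(scene, cfg)
        rcfg = RecoverConfig(s_intra=9)
        out = caspi(truth, laser, rcfg)
        rel = np.linalg.norm(out.flux - truth.flux) / np.linalg.norm(truth.flux)
        assert rel < 1e-3

    def test_stagewise_error_reduction_low_sbr(self):
        # at the standard operating point (full search window) each stage
        # strictly reduces the flux error on a low-SBR staircase scene
        from caspi.scenes import step_depth_scene

        laser = LaserPrior("gaussian", dt=100e-12, fwhm=400e-12)
        cfg = SimConfig(nt=128, dt=100e-12, n_cycle=1000, laser=laser, seed=11)
        scene = step_depth_scene(32, 32)
        cube, truth = simulate_cube(scene, cfg)
        x = cube.counts.astype(float) / cfg.n_cycle
        rcfg = RecoverConfig()
        local = recover_stage(x, rcfg, laser, "local")
        final = recover_stage(
            x, rcfg, laser, "nonlocal", np.clip(local, 0, None).sum(axis=2)
        )
        e_raw = np.linalg.norm(x - truth.flux)
        e_local = np.linalg.norm(local - truth.flux)
        e_final = np.linalg.norm(final - truth.flux)
        assert e_local < e_raw
        assert e_final < e_local

    def test_mirror_equivariance_away_from_borders(self):
        scene, cfg, laser = self.small_scene(seed=5)
        cube, _ = simulate_cube(scene, cfg)
        x = cube.counts.astype(float)
        rcfg = RecoverConfig(s_intra=9)
        a = recover_stage(x, rcfg, laser, "local")
        b = recover_stage(x[::-1].copy(), rcfg, laser, "local")
        mid = np.s_[6:10, 6:10]  # central region, clamp-asymmetry-free
        np.testing.assert_allclose(a[::-1][mid], b[mid], rtol=1e-7, atol=1e-9)

    def test_nsim_one_equals_local(self):
        # a singleton similarity axis degenerates to local recovery when the
        # branch thresholds and guide source coincide
        scene, cfg, laser = self.small_scene(seed=7)
        cube, _ = simulate_cube(scene, cfg)
        x = cube.counts.astype(float) / cfg.n_cycle
        rcfg = RecoverConfig(s_intra=9, n_sim=1, rth_nonlocal=1.25)
        guide = np.ones((16, 16))
        local = recover_stage(x, rcfg, laser, "local", guide_image=guide)
        nonlocal_ = recover_stage(x, rcfg, laser, "nonlocal", guide_image=guide)
        np.testing.assert_allclose(nonlocal_, local, rtol=1e-9, atol=1e-12)


class TestCaspiEndToEnd:
    def test_all_zero_cube(self):
        laser = LaserPrior("gaussian", dt=100e-12, fwhm=400e-12)
        from caspi import TransientCube

        cube = TransientCube(np.zeros((12, 12, 64), dtype=int), 100e-12, 100)
        out = caspi(cube, laser, RecoverConfig(s_intra=9))
        np.testing.assert_array_equal(out.flux, 0.0)

    def test_deterministic(self):
        laser = LaserPrior("gaussian", dt=100e-12, fwhm=400e-12)
        cfg = SimConfig(nt=64, dt=100e-12, n_cycle=500, laser=laser, seed=2)
        scene = SceneSpec(
            np.ones((12, 12)), depth=np.full((12, 12), 0.5), n_sig=2.0, n_bkg=30.0
        )
        cube, _ = simulate_cube(scene, cfg)
        rcfg = RecoverConfig(s_intra=9)
        out1 = caspi(cube, laser, rcfg)
        out2 = caspi(cube, laser, rcfg)
        np.testing.assert_array_equal(out1.flux, out2.flux)
        assert np.all(out1.flux >= 0)

    def test_multipath_two_peaks_retained(self):
        # both ground-truth peaks present after recovery at N_sig = 10
        laser = LaserPrior("gaussian", dt=100e-12, fwhm=400e-12)
        cfg = SimConfig(nt=128, dt=100e-12, n_cycle=2000, laser=laser, seed=4)
        scene = SceneSpec(
            np.ones((16, 16)), depth=np.full((16, 16), 0.5), n_sig=10.0, n_bkg=1.0
        )
        flux = multipath_flux(scene, cfg, np.full((16, 16), 1.2), 0.6)
        cube, truth = simulate_cube(flux, cfg)
        rec = caspi(cube, laser, RecoverConfig(s_intra=9))
        from caspi.core import SPEED_OF_LIGHT

        m1 = round(2 * 0.5 / (SPEED_OF_LIGHT * cfg.dt))
        m2 = round(2 * 1.2 / (SPEED_OF_LIGHT * cfg.dt))
        hits = 0
        for i in range(16):
            for j in range(16):
                t = rec.flux[i, j]
                # peak bins: local arg-max within +-3 of each true peak
                w1 = t[max(0, m1 - 3) : m1 + 4]
                w2 = t[max(0, m2 - 3) : m2 + 4]
                p1 = np.argmax(w1) + max(0, m1 - 3)
                p2 = np.argmax(w2) + max(0, m2 - 3)
                if abs(p1 - m1) <= 1 and abs(p2 - m2) <= 1 and w1.max() > 0 and w2.max() > 0:
                    hits += 1
        assert hits >= 0.9 * 256


class TestSequences:
    def test_4d_sequence_local_equals_per_frame(self):
        laser = LaserPrior("gaussian", dt=100e-12, fwhm=400e-12)
        cfg = SimConfig(nt=64, dt=100e-12, n_cycle=500, laser=laser, seed=9)
        scene = SceneSpec(
            np.ones((12, 12)), depth=np.full((12, 12), 0.5), n_sig=3.0, n_bkg=20.0
        )
        frames = []
        for s in range(3):
            cfg_s = SimConfig(nt=64, dt=100e-12, n_cycle=500, laser=laser, seed=s)
            c, _ = simulate_cube(scene, cfg_s)
            frames.append(c.counts.astype(float))
        seq = np.stack(frames, axis=3)
        rcfg = RecoverConfig(s_intra=9, s_inter=3)
        out = recover_stage(seq, rcfg, laser, "local")
        for f in range(3):
            ref = recover_stage(seq[..., f], rcfg, laser, "local")
            np.testing.assert_allclose(out[..., f], ref, rtol=1e-12)

    def test_4d_sequence_nonlocal_runs_and_improves(self):
        laser = LaserPrior("gaussian", dt=100e-12, fwhm=400e-12)
        scene = SceneSpec(
            np.ones((12, 12)), depth=np.full((12, 12), 0.5), n_sig=2.0, n_bkg=30.0
        )
        frames, truths = [], []
        for s in range(3):
            cfg_s = SimConfig(nt=64, dt=100e-12, n_cycle=500, laser=laser, seed=s)
            c, t = simulate_cube(scene, cfg_s)
            frames.append(c.counts.astype(float) / 500)
            truths.append(t.flux)
        seq = np.stack(frames, axis=3)
        truth = np.stack(truths, axis=3)
        rcfg = RecoverConfig(s_intra=9, s_inter=3)
        local = recover_stage(seq, rcfg, laser, "local")
        guide = np.clip(local, 0, None).sum(axis=2)
        final = recover_stage(seq, rcfg, laser, "nonlocal", guide)
        assert np.linalg.norm(final - truth) < np.linalg.norm(seq - truth)
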