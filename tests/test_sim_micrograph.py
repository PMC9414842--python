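"""Simulator unit tests: spherical projection, CTF, noise, dataset sampling."""

import numpy as np
import pytest

from liporsc.sim_micrograph import (BilayerProfile, CTFParams, LiposomeSpec,
                                    ParticleTruth, add_noise, apply_ctf,
                                    ctf_array, occupancy_count,
                                    project_radial_density,
                                    project_sphere_profile, render_scene,
                                    sample_dataset, sample_diameters)


class TestSphereProjection:
    def test_uniform_ball_matches_closed_form(self):
        """Projected uniform ball equals 2*rho*sqrt(R^2 - r^2) away from the rim."""
        radius, rho, px = 80.0, 1.3, 2.1
        img = project_radial_density(lambda r: np.where(r <= radius, rho, 0.0),
                                     radius, px, (128, 128))
        ax = np.arange(128) * px - 64 * px
        r = np.hypot(ax[:, None], ax[None, :])
        closed = np.where(r < radius, 2 * rho * np.sqrt(np.clip(radius ** 2 - r ** 2, 0, None)), 0)
        sel = r < radius - 3 * px
        err = np.abs(img[sel] - closed[sel]) / closed[sel].max()
        assert err.max() < 0.005

    def test_thin_shell_center_and_voxel_oracle(self):
        """Shell projection matches a brute-force voxelized 3D line integral."""
        profile = BilayerProfile(headgroup_offset=0.0, headgroup_sigma=2.5,
                                 headgroup_amp=1.0, tail_amp=0.0)
        radius, px = 100.0, 2.1
        n = 128
        img = project_sphere_profile(profile, radius, px, (n, n))
        # center value: the line crosses the (double-amplitude) Gaussian shell
        # twice; each crossing integrates to 2 * sqrt(2 pi) * sigma
        assert img[n // 2, n // 2] == pytest.approx(2 * 2 * np.sqrt(2 * np.pi) * 2.5,
                                                    rel=1e-3)
        # voxelized oracle: sample the 3D density on a fine grid, sum along z
        dz = 0.7
        half = radius + profile.support + 2 * px
        zs = np.arange(-half, half, dz)
        ax = np.arange(n) * px - (n // 2) * px
        oracle = np.zeros((n, n))
        for z in zs:
            rho = np.sqrt(ax[:, None] ** 2 + ax[None, :] ** 2 + z ** 2)
            oracle += (profile(rho - radius)) * dz
        rms = np.sqrt(((img - oracle) ** 2).mean()) / np.sqrt((oracle ** 2).mean())
        assert rms < 0.01

    def test_zero_profile_projects_to_zero(self):
        profile = BilayerProfile(headgroup_amp=0.0, tail_amp=0.0)
        img = project_sphere_profile(profile, 90.0, 2.1, (128, 128))
        assert np.allclose(img, 0.0)

    def test_projection_is_linear(self):
        p1 = BilayerProfile(headgroup_amp=0.002, tail_amp=-0.001)
        p2 = BilayerProfile(headgroup_amp=0.004, tail_amp=-0.002)
        a = project_sphere_profile(p1, 90.0, 2.1, (128, 128))
        b = project_sphere_profile(p2, 90.0, 2.1, (128, 128))
        assert np.allclose(2 * a, b, atol=1e-12)

    @pytest.mark.parametrize("radius", [-5.0, 0.0])
    def test_nonpositive_radius_rejected(self, radius, profile):
        with pytest.raises(ValueError):
            project_sphere_profile(profile, radius, 2.1, (128, 128))

    def test_sphere_beyond_grid_rejected(self, profile):
        with pytest.raises(ValueError, match="beyond"):
            project_sphere_profile(profile, 200.0, 2.1, (128, 128))


class TestCTF:
    def test_zero_frequency_is_minus_amplitude_contrast(self):
        for w in (0.0, 0.1, 1.0):
            ctf = CTFParams(amplitude_contrast=w, defocus_um=3.8, pixel_size_a=2.1)
            c = ctf_array((32, 32), ctf)
            assert c[0, 0] == pytest.approx(-w, abs=1e-12)

    def test_pure_amplitude_contrast_negates_image(self):
        ctf = CTFParams(defocus_um=0.0, cs_mm=0.0, amplitude_contrast=1.0,
                        pixel_size_a=2.1)
        img = np.random.default_rng(0).normal(size=(64, 64))
        assert np.allclose(apply_ctf(img, ctf), -img, atol=1e-12)

    def test_round_trip_where_ctf_strong(self):
        """Dividing by the CTF where |CTF| > 0.1 recovers the input to <1%."""
        ctf = CTFParams(defocus_um=3.8, pixel_size_a=2.1)
        rng = np.random.default_rng(1)
        img = rng.normal(size=(128, 128))
        c = ctf_array((128, 128), ctf)
        strong = np.abs(c) > 0.1
        fwd = np.fft.fft2(apply_ctf(img, ctf))
        rec = np.where(strong, fwd / np.where(strong, c, 1.0), 0.0)
        orig = np.where(strong, np.fft.fft2(img), 0.0)
        err = np.linalg.norm(rec - orig) / np.linalg.norm(orig)
        assert err < 0.01

    def test_ctf_is_linear_operator(self):
        ctf = CTFParams(pixel_size_a=2.1)
        rng = np.random.default_rng(2)
        a, b = rng.normal(size=(2, 64, 64))
        lhs = apply_ctf(a + 0.5 * b, ctf)
        rhs = apply_ctf(a, ctf) + 0.5 * apply_ctf(b, ctf)
        assert np.allclose(lhs, rhs, atol=1e-12)

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            CTFParams(pixel_size_a=0.0)
        with pytest.raises(ValueError):
            CTFParams(amplitude_contrast=1.5)


class TestNoise:
    def test_fixed_seed_bit_identical(self):
        img = np.zeros((64, 64)) + 0.05
        a = add_noise(img, 60.0, 2.1, seed=42)
        b = add_noise(img, 60.0, 2.1, seed=42)
        assert np.array_equal(a, b)

    def test_mean_preserved_and_rms_scales_with_dose(self):
        """Relative RMS error scales as 1/sqrt(dose) within 10% over a decade."""
        rng_img = np.zeros((256, 256))
        rms = {}
        for dose in (30.0, 300.0):
            errs = [np.sqrt(((add_noise(rng_img, dose, 2.1, seed=s) - rng_img) ** 2).mean())
                    for s in range(5)]
            rms[dose] = np.mean(errs)
            expected = 1.0 / np.sqrt(dose * 2.1 ** 2)
            assert rms[dose] == pytest.approx(expected, rel=0.02)
        assert rms[30.0] / rms[300.0] == pytest.approx(np.sqrt(10), rel=0.1)
        # mean within 3 standard errors
        noisy = add_noise(rng_img + 0.1, 60.0, 2.1, seed=0)
        se = 1.0 / np.sqrt(60.0 * 2.1 ** 2 * noisy.size)
        assert abs(noisy.mean() - 0.1) < 3 * se

    def test_nonpositive_dose_rejected(self):
        with pytest.raises(ValueError):
            add_noise(np.zeros((8, 8)), 0.0, 2.1, seed=0)


class TestScene:
    def test_single_liposome_matches_direct_projection(self, profile):
        spec = LiposomeSpec((300.0, 350.0), 100.0, profile)
        scene = render_scene([spec], [], None, (512, 512), 2.1)
        direct = project_sphere_profile(profile, 100.0, 2.1, (512, 512),
                                        center=(300.0, 350.0))
        assert np.allclose(scene, direct)

    def test_energy_additive_for_disjoint_components(self, profile,
                                                     channel_phantom_128):
        l1 = LiposomeSpec((250.0, 250.0), 90.0, profile)
        l2 = LiposomeSpec((800.0, 800.0), 90.0, profile)
        s1 = render_scene([l1], [], None, (512, 512), 2.1)
        s2 = render_scene([l2], [], None, (512, 512), 2.1)
        both = render_scene([l1, l2], [], None, (512, 512), 2.1)
        assert np.allclose(both, s1 + s2, atol=1e-12)

    def test_equatorial_particle_projects_at_radius(self, profile,
                                                    channel_phantom_128):
        """A particle at theta=90 sits on the projected membrane circle."""
        spec = LiposomeSpec((537.6, 537.6), 100.0, profile)
        pt = ParticleTruth(liposome_id=0, theta=90.0, phi=0.0, psi=0.0,
                           offset=(537.6 + 100.0, 537.6))
        scene = render_scene([spec], [pt], channel_phantom_128, (512, 512), 2.1)
        lipo_only = render_scene([spec], [], None, (512, 512), 2.1)
        diff = scene - lipo_only
        yx = np.unravel_index(np.argmax(np.abs(diff)), diff.shape)
        pos = np.array([yx[1], yx[0]]) * 2.1
        assert np.hypot(pos[0] - (537.6 + 100.0), pos[1] - 537.6) < 25.0


class TestDatasetSampling:
    def test_diameter_distribution_mean_and_support(self):
        rng = np.random.default_rng(0)
        d = sample_diameters(10_000, rng)
        assert d.mean() == pytest.approx(20.0, rel=0.02)
        assert d.min() >= 15.0 and d.max() <= 70.0

    def test_occupancy_rule_one_to_two_per_20nm(self):
        rng = np.random.default_rng(1)
        counts = [occupancy_count(20.0, rng) for _ in range(2000)]
        assert set(counts) == {1, 2}
        # area scaling: a 40-nm liposome carries ~4x the particles
        big = np.mean([occupancy_count(40.0, rng) for _ in range(2000)])
        assert big == pytest.approx(4 * np.mean(counts), rel=0.1)

    def test_zero_liposomes_gives_pure_noise(self):
        mics = sample_dataset(1, seed=3, grid_shape=(256, 256),
                              liposomes_per_micrograph=0)
        mic = mics[0]
        assert mic.liposomes == [] and mic.particles == []
        assert abs(mic.data.mean()) < 3.0 / np.sqrt(60 * 2.1 ** 2 * mic.data.size)

    def test_same_seed_reproduces_bit_identically(self, channel_phantom_128):
        a = sample_dataset(2, seed=7, grid_shape=(512, 512),
                           liposomes_per_micrograph=2,
                           particle_volume=channel_phantom_128)
        b = sample_dataset(2, seed=7, grid_shape=(512, 512),
                           liposomes_per_micrograph=2,
                           particle_volume=channel_phantom_128)
        for ma, mb in zip(a, b):
            assert np.array_equal(ma.data, mb.data)
            assert ma.particles == mb.particles

    def test_infeasible_packing_rejected(self):
        with pytest.raises(ValueError):
            sample_dataset(1, seed=0, grid_shape=(256, 256),
                           liposomes_per_micrograph=40)
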