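"""RSC geometry, constrained assignment, backprojection and FSC tests."""

import numpy as np
import pytest

from liporsc.fourier import FourierProjector, rotation_matrix_zyz
from liporsc.liposome_model import LiposomeFit
from liporsc.particle_ops import ParticlePick, ParticleStack
from liporsc.rsc_reconstruct import (DensityMap, OrientationPrior,
                                     ParticleOrientation, assign_orientations,
                                     backproject, compute_fsc,
                                     orientation_prior, reconstruct_halves)
from liporsc.util import masked_pearson, soft_spherical_mask

PX = 4.2
BOX = 64


def geodesic_error_deg(a, o):
    ra = rotation_matrix_zyz(*a)
    rb = rotation_matrix_zyz(o.theta, o.phi, o.psi)
    c = (np.trace(ra @ rb.T) - 1) / 2
    return np.degrees(np.arccos(np.clip(c, -1, 1)))


class TestOrientationPrior:
    @pytest.mark.parametrize("offset_frac,expected_tilt",
                             [(0.0, 0.0), (0.5, 30.0), (1.0, 90.0)])
    def test_arcsin_relation(self, offset_frac, expected_tilt):
        """sin(tilt) = r/R: r = 0, R/2, R give tilts 0, 30, 90 degrees."""
        fit = LiposomeFit(center=(420.0, 420.0), radius=100.0, converged=True)
        pick = ParticlePick(position=((420.0 + offset_frac * 100.0) / PX,
                                      420.0 / PX), score=1.0)
        prior = orientation_prior(pick, fit, PX)
        assert prior.tilt_center == pytest.approx(expected_tilt, abs=1e-9)
        assert prior.inplane_center == pytest.approx(0.0, abs=1e-9)

    def test_bearing_sets_inplane_center(self):
        fit = LiposomeFit(center=(420.0, 420.0), radius=100.0, converged=True)
        pick = ParticlePick(position=(420.0 / PX, (420.0 + 70.0) / PX), score=1.0)
        prior = orientation_prior(pick, fit, PX)
        assert prior.inplane_center == pytest.approx(90.0, abs=1e-9)

    def test_offset_beyond_radius_clipped(self):
        fit = LiposomeFit(center=(0.0, 0.0), radius=100.0, converged=True)
        pick = ParticlePick(position=(130.0 / PX, 0.0), score=1.0)
        assert orientation_prior(pick, fit, PX).tilt_center == pytest.approx(90.0)

    def test_nonpositive_radius_rejected(self):
        fit = LiposomeFit(center=(0.0, 0.0), radius=0.0)
        with pytest.raises(ValueError):
            orientation_prior(ParticlePick(position=(1.0, 1.0), score=1.0), fit, PX)


class TestAssignment:
    def _make_particles(self, vol, n, rng, shift=False):
        proj = FourierProjector(vol)
        truth, imgs, priors = [], [], []
        for _ in range(n):
            theta = np.degrees(np.arccos(rng.uniform(-1, 1)))
            phi, psi = rng.uniform(0, 360), rng.uniform(0, 360)
            img = proj.project(theta, phi, psi)
            if shift:
                from scipy import ndimage
                s = rng.uniform(-3, 3, 2)
                img = ndimage.shift(img, (s[1], s[0]), order=1)
            truth.append((theta, phi, psi))
            imgs.append(img)
            tc = theta if theta <= 90 else 180 - theta
            priors.append(OrientationPrior(tilt_center=tc, inplane_center=phi,
                                           tilt_width=5, inplane_width=5))
        return truth, np.array(imgs), priors

    def test_noise_free_recovery_within_half_step(self, asymmetric_phantom_64):
        """Median angular error below half the 5-degree azimuth step."""
        rng = np.random.default_rng(3)
        truth, imgs, priors = self._make_particles(asymmetric_phantom_64, 12, rng)
        stack = ParticleStack(images=imgs, pixel_size=PX)
        ref = DensityMap(data=asymmetric_phantom_64, pixel_size=PX)
        oris = assign_orientations(stack, priors, ref, azimuth_step=5.0)
        errs = [geodesic_error_deg(a, o) for a, o in zip(truth, oris)]
        assert np.median(errs) < 2.5

    def test_degenerate_prior_recovers_exactly(self, asymmetric_phantom_64):
        """Zero-width priors with the truth on the grid return the truth."""
        ref = DensityMap(data=asymmetric_phantom_64, pixel_size=PX)
        proj = FourierProjector(asymmetric_phantom_64)
        theta, phi, psi = 40.0, 120.0, 35.0
        img = proj.project(theta, phi, psi)
        stack = ParticleStack(images=img[None], pixel_size=PX)
        prior = OrientationPrior(tilt_center=theta, inplane_center=phi,
                                 tilt_width=1e-6, inplane_width=1e-6)
        oris = assign_orientations(stack, [prior], ref, azimuth_step=5.0,
                                   n_local=1, max_shift_px=0)
        assert oris[0].theta == pytest.approx(theta)
        assert oris[0].phi == pytest.approx(phi)
        assert oris[0].psi == pytest.approx(psi)

    def test_scrambled_priors_score_worse(self, asymmetric_phantom_64):
        """Wrong liposome links (scrambled priors) lose correlation (paired)."""
        rng = np.random.default_rng(5)
        truth, imgs, priors = self._make_particles(asymmetric_phantom_64, 30, rng)
        stack = ParticleStack(images=imgs, pixel_size=PX)
        ref = DensityMap(data=asymmetric_phantom_64, pixel_size=PX)
        good = assign_orientations(stack, priors, ref, azimuth_step=10.0)
        scrambled = priors[10:] + priors[:10]
        bad = assign_orientations(stack, scrambled, ref, azimuth_step=10.0)
        diffs = [g.score - b.score for g, b in zip(good, bad)]
        # paired comparison: matched priors must win clearly on average
        t = np.mean(diffs) / (np.std(diffs) / np.sqrt(len(diffs)))
        assert t > 3

    def test_empty_stack_rejected(self, asymmetric_phantom_64):
        ref = DensityMap(data=asymmetric_phantom_64, pixel_size=PX)
        stack = ParticleStack(images=np.zeros((0, BOX, BOX)), pixel_size=PX)
        with pytest.raises(ValueError):
            assign_orientations(stack, [], ref)


class TestBackprojection:
    def test_round_trip_phantom_recovery(self, asymmetric_phantom_64):
        """Projections at known angles reconstruct the phantom (corr >= 0.99)."""
        rng = np.random.default_rng(1)
        proj = FourierProjector(asymmetric_phantom_64)
        oris, imgs = [], []
        for _ in range(60):
            theta = np.degrees(np.arccos(rng.uniform(-1, 1)))
            phi, psi = rng.uniform(0, 360), rng.uniform(0, 360)
            imgs.append(proj.project(theta, phi, psi))
            oris.append(ParticleOrientation(theta=theta, phi=phi, psi=psi, score=1.0))
        stack = ParticleStack(images=np.array(imgs), pixel_size=PX)
        rec = backproject(stack, oris)
        mask = soft_spherical_mask(BOX, 16)
        assert masked_pearson(rec.data, asymmetric_phantom_64, mask) >= 0.99

    def test_symmetrize_after_equals_symmetric_reconstruction(self,
                                                              channel_phantom_64):
        """C1 reconstruction + C4 averaging == C4-imposed reconstruction."""
        from liporsc.fourier import symmetrize_z
        rng = np.random.default_rng(2)
        proj = FourierProjector(channel_phantom_64)
        oris, imgs = [], []
        for _ in range(20):
            theta = np.degrees(np.arccos(rng.uniform(-1, 1)))
            phi, psi = rng.uniform(0, 360), rng.uniform(0, 360)
            imgs.append(proj.project(theta, phi, psi))
            oris.append(ParticleOrientation(theta=theta, phi=phi, psi=psi, score=1.0))
        stack = ParticleStack(images=np.array(imgs), pixel_size=PX)
        c1 = backproject(stack, oris, symmetry=1)
        c4 = backproject(stack, oris, symmetry=4)
        assert np.allclose(symmetrize_z(c1.data, 4), c4.data, atol=1e-10)

    def test_duplicating_stack_leaves_map_unchanged(self, channel_phantom_64):
        rng = np.random.default_rng(3)
        proj = FourierProjector(channel_phantom_64)
        oris, imgs = [], []
        for _ in range(10):
            theta = np.degrees(np.arccos(rng.uniform(-1, 1)))
            phi, psi = rng.uniform(0, 360), rng.uniform(0, 360)
            imgs.append(proj.project(theta, phi, psi))
            oris.append(ParticleOrientation(theta=theta, phi=phi, psi=psi, score=1.0))
        once = backproject(ParticleStack(images=np.array(imgs), pixel_size=PX), oris)
        twice = backproject(ParticleStack(images=np.array(imgs * 2), pixel_size=PX),
                            oris * 2)
        assert np.allclose(once.data, twice.data, atol=1e-9)

    def test_invalid_symmetry_rejected(self, channel_phantom_64):
        stack = ParticleStack(images=np.zeros((1, BOX, BOX)), pixel_size=PX)
        with pytest.raises(ValueError):
            backproject(stack, [ParticleOrientation(0, 0, 0, 1.0)], symmetry=3)

    def test_gold_standard_halves_share_no_particle(self):
        rng = np.random.default_rng(4)
        imgs = rng.normal(size=(21, BOX, BOX))
        oris = [ParticleOrientation(theta=0, phi=0, psi=0, score=1.0)] * 21
        stack = ParticleStack(images=imgs, pixel_size=PX)
        full, h1, h2 = reconstruct_halves(stack, oris, seed=9, fsc_weight=False)
        # the halves partition the stack: rebuilding from all particles differs
        # from each half, and the two halves differ from each other
        assert not np.allclose(h1.data, h2.data)


class TestFSC:
    def test_identical_maps_give_unity_everywhere(self, channel_phantom_64):
        m = DensityMap(data=channel_phantom_64, pixel_size=PX)
        curve = compute_fsc(m, m)
        assert np.allclose(curve.fsc[: BOX // 2], 1.0, atol=1e-9)
        assert curve.resolution_a == pytest.approx(2 * PX)

    def test_independent_noise_maps_decorrelate(self):
        """Per-shell FSC of independent noise within +/- 3/sqrt(N_shell)."""
        rng = np.random.default_rng(0)
        a = DensityMap(data=rng.normal(size=(BOX,) * 3), pixel_size=PX)
        b = DensityMap(data=rng.normal(size=(BOX,) * 3), pixel_size=PX)
        curve = compute_fsc(a, b)
        for k in range(2, BOX // 2):
            n_vox = 4 * np.pi * k ** 2
            assert abs(curve.fsc[k]) < 3.0 / np.sqrt(n_vox)

    def test_band_limited_common_signal_crossing(self):
        """Shared signal band-limited at 1/10 A^-1 -> resolution within 1 shell."""
        n, px = 64, 2.1
        rng = np.random.default_rng(1)
        sig = rng.normal(size=(n,) * 3)
        f = np.fft.fftshift(np.fft.fftn(sig))
        ax = np.arange(n) - n // 2
        r = np.sqrt(ax[:, None, None] ** 2 + ax[None, :, None] ** 2
                    + ax[None, None, :] ** 2)
        cutoff_shell = n * px / 10.0  # shell index of 1/(10 A)
        f[r > cutoff_shell] = 0.0
        sig = np.fft.ifftn(np.fft.ifftshift(f)).real
        sig *= 10.0 / np.sqrt((sig ** 2).mean())
        m1 = DensityMap(data=sig + rng.normal(size=(n,) * 3), pixel_size=px)
        m2 = DensityMap(data=sig + rng.normal(size=(n,) * 3), pixel_size=px)
        curve = compute_fsc(m1, m2)
        shell_width_a = 1.0 / (1 / 10.0 + 1.0 / (n * px)) - 10.0
        assert abs(curve.resolution_a - 10.0) <= abs(shell_width_a) + 0.5

    def test_mismatched_grids_rejected(self):
        a = DensityMap(data=np.zeros((32,) * 3), pixel_size=PX)
        b = DensityMap(data=np.zeros((64,) * 3), pixel_size=PX)
        with pytest.raises(ValueError):
            compute_fsc(a, b)
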