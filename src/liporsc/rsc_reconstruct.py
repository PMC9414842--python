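"""Spherically constrained orientation priors, reconstruction, and FSC.

The geometric core of the method: a membrane protein embedded in a spherical
vesicle has its membrane-normal axis along the sphere radius. For a particle
picked at in-plane distance ``r`` from the center of a liposome of radius
``R``, the tilt of that axis from the beam direction satisfies

    sin(tilt) = r / R

up to the near/far ambiguity (``tilt`` vs ``180 deg - tilt``: the particle may
sit on the hemisphere facing the beam or the one facing away). The in-plane
direction of the axis is the bearing from the liposome center to the pick.
Only the spin about the membrane normal is unconstrained (uniform).

Orientation assignment is constrained projection matching: exhaustive search
over the unconstrained spin and the discrete near/far choice, local search
within the prior widths for tilt and in-plane angle, scoring by normalized
Fourier-domain correlation between the CTF-modulated reference slice and the
particle image. Reconstruction is direct Fourier inversion with CTF^2
Wiener-style weighting; Cn symmetry is imposed by real-space averaging over
the n rotations about z.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .fourier import FourierProjector, backproject_slices, rotation_matrix_zyz, \
    symmetrize_z
from .liposome_model import LiposomeFit
from .particle_ops import ParticlePick, ParticleStack
from .sim_micrograph import CTFParams, ctf_array

FSC_THRESHOLD = 0.143
DEFAULT_AZIMUTH_STEP_DEG = 5.0
DEFAULT_TILT_WIDTH_DEG = 10.0
DEFAULT_INPLANE_WIDTH_DEG = 10.0


@dataclass(frozen=True)
class OrientationPrior:
    """Sphere-derived orientation prior for one particle.

    ``tilt_center`` is in [0, 90]; the near/far ambiguity means the true tilt
    is in ``{tilt_center, 180 - tilt_center}``. ``inplane_center`` is the
    bearing (deg) from the liposome center to the pick. The spin about the
    membrane normal is uniform and carries no prior.
    """

    tilt_center: float
    inplane_center: float
    tilt_width: float = DEFAULT_TILT_WIDTH_DEG
    inplane_width: float = DEFAULT_INPLANE_WIDTH_DEG

    def __post_init__(self):
        if self.tilt_width <= 0 or self.inplane_width <= 0:
            raise ValueError("prior widths must be positive")


@dataclass
class DensityMap:
    """Cubic 3D density grid with pixel size and symmetry label."""

    data: np.ndarray
    pixel_size: float
    symmetry: str = "C1"

    def __post_init__(self):
        d = np.asarray(self.data)
        if d.ndim != 3 or len(set(d.shape)) != 1 or d.shape[0] % 2:
            raise ValueError("map must be cubic with even edge length")


@dataclass
class FSCCurve:
    """Fourier shell correlation curve and the resolution at its threshold."""

    frequency: np.ndarray          # 1/A, shell centers
    fsc: np.ndarray
    threshold: float = FSC_THRESHOLD
    resolution_a: float = np.nan


@dataclass(frozen=True)
class ParticleOrientation:
    theta: float
    phi: float
    psi: float
    score: float
    shift_x: float = 0.0   # particle offset from box center, px (applied
    shift_y: float = 0.0   # as a recentering phase ramp at insertion)
    side_margin: float = np.inf  # near-vs-far hemisphere score separation


# ---------------------------------------------------------------------------
# Priors
# ---------------------------------------------------------------------------

def orientation_prior(pick: ParticlePick, fit: LiposomeFit, pixel_size: float,
                      tilt_width: float = DEFAULT_TILT_WIDTH_DEG,
                      inplane_width: float = DEFAULT_INPLANE_WIDTH_DEG,
                      position_sigma_a: float = 0.0) -> OrientationPrior:
    """Prior from pick position and fitted liposome geometry.

    ``sin(tilt) = r / R`` with r the pick's in-plane offset from the liposome
    center (clipped to R); the in-plane center is the bearing from liposome
    center to pick. When ``position_sigma_a`` is given, the widths are
    broadened by the angular uncertainty such a positional error induces:
    the bearing is ill-determined for picks near the projected center and
    the tilt for picks near the rim.
    """
    if fit.radius <= 0:
        raise ValueError("liposome radius must be positive")
    dx = pick.position[0] * pixel_size - fit.center[0]
    dy = pick.position[1] * pixel_size - fit.center[1]
    r = np.hypot(dx, dy)
    ratio = min(r / fit.radius, 1.0)
    tilt = float(np.degrees(np.arcsin(ratio)))
    bearing = float(np.degrees(np.arctan2(dy, dx))) % 360.0
    if position_sigma_a > 0:
        inplane_width = max(inplane_width,
                            float(np.degrees(np.arctan2(position_sigma_a,
                                                        max(r, 1e-6)))))
        cos_t = np.sqrt(max(1.0 - ratio ** 2, 0.0))
        dtilt = np.degrees(position_sigma_a / (fit.radius * max(cos_t, 0.15)))
        tilt_width = max(tilt_width, float(min(dtilt, 45.0)))
    return OrientationPrior(tilt_center=tilt, inplane_center=bearing,
                            tilt_width=min(tilt_width, 90.0),
                            inplane_width=min(inplane_width, 180.0))


# ---------------------------------------------------------------------------
# Constrained projection matching
# ---------------------------------------------------------------------------

def _grid(width: float, n_local: int | None, step: float = 6.0) -> np.ndarray:
    """Symmetric offsets covering [-width, width]; auto point count if None."""
    if n_local is None:
        n_local = int(2 * np.ceil(width / step) + 1)
        n_local = min(max(n_local, 3), 11)
    return np.linspace(-width, width, n_local)


def _candidate_angles(prior: OrientationPrior, azimuth_step: float,
                      n_local: int | None = 3) -> np.ndarray:
    """(m, 3) array of (theta, phi, psi) candidates within the prior support."""
    centers = [prior.tilt_center]
    if abs(180.0 - 2 * prior.tilt_center) > 1e-9:
        centers.append(180.0 - prior.tilt_center)
    tilts = []
    for center in centers:
        for dt in _grid(prior.tilt_width, n_local):
            t = center + dt if center <= 90 else center - dt
            tilts.append(np.clip(t, 0.0, 180.0))
    phis = prior.inplane_center + _grid(prior.inplane_width, n_local)
    psis = np.arange(0.0, 360.0, azimuth_step)
    cand = np.array([(t, p, s) for t in tilts for p in phis for s in psis])
    return cand


def assign_orientations(stack: ParticleStack, priors: list[OrientationPrior],
                        reference: DensityMap, ctf: CTFParams | None = None,
                        azimuth_step: float = DEFAULT_AZIMUTH_STEP_DEG,
                        n_local: int | None = None, lowpass_frac: float = 0.6,
                        max_shift_px: float = 5.0, n_rescore: int = 24,
                        chunk: int = 600) -> list[ParticleOrientation]:
    """Best-correlation angles per particle, restricted to the prior support.

    Two stages: all angular candidates are scored without shifts on Fourier
    components within ``lowpass_frac`` of Nyquist (alignment does not benefit
    from the noise-dominated highest shells and the truncation keeps the
    search fast); the ``n_rescore`` best are then rescored with an in-plane
    translation search up to ``max_shift_px`` (picking centers particles only
    to a few pixels), and the best angle+shift wins.
    """
    if stack.images.shape[0] == 0:
        raise ValueError("empty particle stack")
    if len(priors) != stack.images.shape[0]:
        raise ValueError("one prior per particle required")
    n = stack.images.shape[1]
    if reference.data.shape[0] != n:
        raise ValueError("reference box must match the particle box")
    proj = FourierProjector(reference.data)
    c2d = (ctf_array((n, n), ctf, shifted=True)
           if ctf is not None else np.ones((n, n)))
    k = np.arange(n) - n // 2
    k2 = k[:, None] ** 2 + k[None, :] ** 2
    pmask = (k2 <= (lowpass_frac * n / 2) ** 2).ravel()
    c_flat = c2d.ravel()[pmask]
    out: list[ParticleOrientation] = []
    for img, prior in zip(stack.images, priors):
        s_img_full = np.fft.fftshift(np.fft.fft2(np.fft.ifftshift(img)))
        s_img = s_img_full.ravel()[pmask]
        norm_img = np.linalg.norm(s_img)
        cand = _candidate_angles(prior, azimuth_step, n_local)
        all_scores = np.empty(len(cand))
        for i0 in range(0, len(cand), chunk):
            sub = cand[i0:i0 + chunk]
            mats = np.array([rotation_matrix_zyz(*a) for a in sub])
            slices = proj.sample_slices(mats, pmask) * c_flat
            norms = np.sqrt((slices.real ** 2 + slices.imag ** 2).sum(axis=1))
            cross = (slices @ np.conj(s_img)).real
            all_scores[i0:i0 + chunk] = cross / np.maximum(norms * norm_img, 1e-30)
        # confidence of the near/far decision: gap between the hemispheres'
        # best scores (small gap = the flip is not resolved by the data)
        near = cand[:, 0] <= 90.0
        margin = np.inf
        if near.any() and (~near).any():
            margin = float(abs(all_scores[near].max() - all_scores[~near].max()))
        if max_shift_px > 0:
            top = np.argsort(all_scores)[-n_rescore:]
            best = _rescore_with_shifts(proj, cand[top], s_img_full, c2d,
                                        max_shift_px)
        else:
            kbest = int(np.argmax(all_scores))
            best = (*cand[kbest], float(all_scores[kbest]), 0.0, 0.0)
        out.append(ParticleOrientation(theta=float(best[0]), phi=float(best[1]),
                                       psi=float(best[2]), score=best[3],
                                       shift_x=best[4], shift_y=best[5],
                                       side_margin=margin))
    return out


def _rescore_with_shifts(proj, cands, s_img_full, c2d, max_shift_px):
    """Translation-aware rescoring: normalized CC peak within a shift window."""
    n = s_img_full.shape[0]
    c = n // 2
    w = int(np.ceil(max_shift_px))
    mats = np.array([rotation_matrix_zyz(*a) for a in cands])
    slices = proj.slices_for(mats) * c2d
    norm_img = np.linalg.norm(s_img_full)
    best = None
    for ang, sl in zip(cands, slices):
        x = s_img_full * np.conj(sl)
        cc = np.fft.fftshift(np.fft.ifft2(np.fft.ifftshift(x))).real * n * n
        win = cc[c - w:c + w + 1, c - w:c + w + 1]
        iy, ix = np.unravel_index(np.argmax(win), win.shape)
        denom = max(np.linalg.norm(sl) * norm_img, 1e-30)
        score = float(win[iy, ix] / denom)
        # parabolic sub-pixel refinement along each axis
        dy, dx = float(iy - w), float(ix - w)
        for axis, idx in ((0, iy), (1, ix)):
            if 0 < idx < win.shape[axis] - 1:
                tri = win[idx - 1:idx + 2, ix] if axis == 0 else win[iy, idx - 1:idx + 2]
                dd = 0.5 * (tri[0] - tri[2]) / max(tri[0] - 2 * tri[1] + tri[2], 1e-30) \
                    if (tri[0] - 2 * tri[1] + tri[2]) != 0 else 0.0
                dd = float(np.clip(dd, -0.5, 0.5))
                if axis == 0:
                    dy += dd
                else:
                    dx += dd
        if best is None or score > best[3]:
            best = (*ang, score, dx, dy)
    return best


def refine_orientations(stack: ParticleStack,
                        orientations: list[ParticleOrientation],
                        reference: DensityMap, ctf: CTFParams | None = None,
                        width_deg: float = 6.0, step_deg: float = 2.0,
                        lowpass_frac: float = 0.7, max_shift_px: float = 5.0,
                        n_rescore: int = 8) -> list[ParticleOrientation]:
    """Local polish of assigned orientations on a finer angular grid.

    Searches a +/- ``width_deg`` cube around each particle's current angles
    at ``step_deg`` spacing (no hemisphere flip — the discrete ambiguity was
    settled in the first pass), rescoring the best candidates with the
    translation search. Removes most of the first pass's grid-discretization
    error.
    """
    n = stack.images.shape[1]
    proj = FourierProjector(reference.data)
    c2d = (ctf_array((n, n), ctf, shifted=True)
           if ctf is not None else np.ones((n, n)))
    k = np.arange(n) - n // 2
    pmask = ((k[:, None] ** 2 + k[None, :] ** 2)
             <= (lowpass_frac * n / 2) ** 2).ravel()
    c_flat = c2d.ravel()[pmask]
    offs = np.arange(-width_deg, width_deg + step_deg / 2, step_deg)
    out = []
    for img, ori in zip(stack.images, orientations):
        s_img_full = np.fft.fftshift(np.fft.fft2(np.fft.ifftshift(img)))
        s_img = s_img_full.ravel()[pmask]
        norm_img = np.linalg.norm(s_img)
        cand = np.array([(np.clip(ori.theta + dt, 0.0, 180.0),
                          ori.phi + dp, ori.psi + ds)
                         for dt in offs for dp in offs for ds in offs])
        mats = np.array([rotation_matrix_zyz(*a) for a in cand])
        slices = proj.sample_slices(mats, pmask) * c_flat
        norms = np.sqrt((slices.real ** 2 + slices.imag ** 2).sum(axis=1))
        scores = (slices @ np.conj(s_img)).real / np.maximum(norms * norm_img,
                                                             1e-30)
        top = np.argsort(scores)[-n_rescore:]
        best = _rescore_with_shifts(proj, cand[top], s_img_full, c2d,
                                    max_shift_px)
        out.append(ParticleOrientation(theta=float(best[0]), phi=float(best[1]),
                                       psi=float(best[2]), score=best[3],
                                       shift_x=best[4], shift_y=best[5],
                                       side_margin=ori.side_margin))
    return out


# ---------------------------------------------------------------------------
# Reconstruction
# ---------------------------------------------------------------------------

def backproject(stack: ParticleStack, orientations: list[ParticleOrientation],
                ctf: CTFParams | None = None, symmetry: int = 1,
                min_particles: int = 10, reg: float = 1e-3) -> DensityMap:
    """Direct Fourier inversion of a stack at assigned angles, Cn-symmetrized."""
    if symmetry not in (1, 2, 4):
        raise ValueError("symmetry must be 1, 2 or 4")
    m = stack.images.shape[0]
    if m < min_particles:
        import warnings

        warnings.warn(f"only {m} particles in reconstruction", stacklevel=2)
    n = stack.images.shape[1]
    mats = np.array([rotation_matrix_zyz(o.theta, o.phi, o.psi) for o in orientations])
    shifts = np.array([[o.shift_x, o.shift_y] for o in orientations])
    ctfs = None
    if ctf is not None:
        c = ctf_array((n, n), ctf, shifted=True)
        ctfs = np.broadcast_to(c, (m, n, n))
    vol = backproject_slices(stack.images, mats, ctfs, shifts=shifts, reg=reg)
    if symmetry > 1:
        vol = symmetrize_z(vol, symmetry)
    return DensityMap(data=vol, pixel_size=stack.pixel_size, symmetry=f"C{symmetry}")


def filter_map_by_fsc(map_: DensityMap, curve: FSCCurve) -> DensityMap:
    """Per-shell signal weighting of a combined map from its half-map FSC.

    Each Fourier shell is scaled by sqrt(2 FSC / (1 + FSC)) (clipped at 0),
    the standard estimate of the signal fraction in the full reconstruction;
    shells where the halves do not agree are suppressed.
    """
    n = map_.data.shape[0]
    f3 = np.fft.fftshift(np.fft.fftn(np.fft.ifftshift(map_.data)))
    ax = np.arange(n) - n // 2
    r = np.sqrt(ax[:, None, None] ** 2 + ax[None, :, None] ** 2
                + ax[None, None, :] ** 2)
    shells = np.clip(np.round(r).astype(int), 0, len(curve.fsc) - 1)
    fsc = np.clip(curve.fsc, 0.0, 1.0)
    cref = np.sqrt(2.0 * fsc / (1.0 + fsc))
    out = np.fft.fftshift(np.fft.ifftn(np.fft.ifftshift(f3 * cref[shells]))).real
    return DensityMap(data=out, pixel_size=map_.pixel_size, symmetry=map_.symmetry)


def reconstruct_halves(stack: ParticleStack, orientations: list[ParticleOrientation],
                       ctf: CTFParams | None = None, symmetry: int = 1,
                       seed: int = 0, fsc_weight: bool = True, **kw):
    """Gold-standard split reconstruction.

    Particles are shuffled with ``seed`` and assigned to halves by even/odd
    index; the two halves share no particle. Returns (full, half1, half2);
    with ``fsc_weight`` the full map is per-shell filtered by the half-map
    FSC signal estimate.
    """
    m = stack.images.shape[0]
    order = np.random.default_rng(seed).permutation(m)
    halves = []
    for par in (order[0::2], order[1::2]):
        sub = ParticleStack(images=stack.images[par], pixel_size=stack.pixel_size,
                            box_nm=stack.box_nm, mask_nm=stack.mask_nm,
                            picks=[stack.picks[i] for i in par] if stack.picks else None)
        sub_ori = [orientations[i] for i in par]
        halves.append(backproject(sub, sub_ori, ctf=ctf, symmetry=symmetry,
                                  min_particles=1, **kw))
    full = backproject(stack, orientations, ctf=ctf, symmetry=symmetry,
                       min_particles=1, **kw)
    if fsc_weight:
        full = filter_map_by_fsc(full, compute_fsc(halves[0], halves[1]))
    return full, halves[0], halves[1]


# ---------------------------------------------------------------------------
# FSC
# ---------------------------------------------------------------------------

def compute_fsc(half1: DensityMap, half2: DensityMap,
                threshold: float = FSC_THRESHOLD) -> FSCCurve:
    """Fourier shell correlation between two half-maps.

    Shell width is one Fourier voxel; the resolution is the reciprocal of the
    first crossing below ``threshold``, linearly interpolated between shells.
    If the curve never crosses, the Nyquist resolution (2 * pixel) is
    reported.
    """
    a, b = half1.data, half2.data
    if a.shape != b.shape or half1.pixel_size != half2.pixel_size:
        raise ValueError("half-maps must share grid and pixel size")
    n = a.shape[0]
    fa = np.fft.fftshift(np.fft.fftn(np.fft.ifftshift(a)))
    fb = np.fft.fftshift(np.fft.fftn(np.fft.ifftshift(b)))
    ax = np.arange(n) - n // 2
    r = np.sqrt(ax[:, None, None] ** 2 + ax[None, :, None] ** 2
                + ax[None, None, :] ** 2)
    shells = np.round(r).astype(int).ravel()
    n_shells = n // 2 + 1
    sel = shells < n_shells
    cross = np.bincount(shells[sel], weights=(fa * np.conj(fb)).real.ravel()[sel],
                        minlength=n_shells)
    pa = np.bincount(shells[sel], weights=(np.abs(fa) ** 2).ravel()[sel],
                     minlength=n_shells)
    pb = np.bincount(shells[sel], weights=(np.abs(fb) ** 2).ravel()[sel],
                     minlength=n_shells)
    denom = np.sqrt(pa * pb)
    fsc = np.where(denom > 0, cross / np.maximum(denom, 1e-300), 0.0)
    freq = np.arange(n_shells) / (n * half1.pixel_size)
    res = 2.0 * half1.pixel_size
    below = np.where(fsc < threshold)[0]
    below = below[below > 0]
    if below.size:
        k = below[0]
        f0, f1 = freq[k - 1], freq[k]
        c0, c1 = fsc[k - 1], fsc[k]
        fc = f0 + (c0 - threshold) * (f1 - f0) / max(c0 - c1, 1e-12)
        res = float(1.0 / fc) if fc > 0 else np.inf
    return FSCCurve(frequency=freq, fsc=fsc, threshold=threshold, resolution_a=res)
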