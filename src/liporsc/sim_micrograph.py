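"""Synthetic proteoliposome micrograph generation.

The generative model: each liposome is a spherical lipid bilayer whose 3D
density depends only on the distance to the bilayer midplane; its image
contribution is the line-of-sight (Abel-type) projection of that spherical
shell. Membrane-protein particles sit in the bilayer with their membrane
normal along the sphere radius, so a particle at polar angle ``theta`` on a
liposome of midplane radius R projects at in-plane offset ``r = R sin(theta)``
— the geometric fact the spherically constrained reconstruction exploits.
Scenes are modulated by a standard phase/amplitude CTF and corrupted by
Poisson shot noise for a given electron dose.

Default acquisition parameters follow a typical 300 kV / K2 proteoliposome
collection: 60 e-/A^2 total dose, ~-3.8 um underfocus, 0.525 A physical pixel
(simulated by default at 2.1 A, i.e. 4x binned, to keep desk-scale runtimes),
liposome diameters 15-70 nm with mean 20 nm, and one to two channel tetramers
per 20-nm liposome.

Intensity units: images hold dimensionless projected contrast (0 = solvent);
density profiles are in contrast per Angstrom of path length, so a projection
through the structure integrates to a small fraction (|contrast| << 1).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .fourier import FourierProjector
from .util import radial_distance_grid

# Default simulated pixel: 4x binning of the 0.525 A physical pixel.
PHYSICAL_PIXEL_A = 0.525
DEFAULT_PIXEL_A = 2.1
DEFAULT_DOSE_E_PER_A2 = 60.0
DEFAULT_DEFOCUS_UM = 3.8

# Three-Gaussian bilayer parameterization: headgroup peaks at +/-19 A from the
# midplane (sigma 4 A) and a broad acyl-chain trough at the midplane. Values
# chosen to give the familiar double-ring projected appearance of vesicles at
# realistic (few-percent) contrast; all overridable.
DEFAULT_HEADGROUP_OFFSET_A = 19.0
DEFAULT_HEADGROUP_SIGMA_A = 4.0
DEFAULT_HEADGROUP_AMP = 0.0030
DEFAULT_TAIL_AMP = -0.0015
DEFAULT_TAIL_SIGMA_A = 9.0


@dataclass(frozen=True)
class BilayerProfile:
    """1D density of a lipid bilayer across its midplane (even function).

    ``__call__(t)`` evaluates the density (relative to solvent) at signed
    distance ``t`` (A) from the midplane. The profile decays to
    ``solvent_level`` beyond ``headgroup_offset + 4 * headgroup_sigma``.
    """

    headgroup_offset: float = DEFAULT_HEADGROUP_OFFSET_A
    headgroup_sigma: float = DEFAULT_HEADGROUP_SIGMA_A
    headgroup_amp: float = DEFAULT_HEADGROUP_AMP
    tail_amp: float = DEFAULT_TAIL_AMP
    tail_sigma: float = DEFAULT_TAIL_SIGMA_A
    solvent_level: float = 0.0

    def __call__(self, t: np.ndarray) -> np.ndarray:
        t = np.asarray(t, dtype=np.float64)
        hg = self.headgroup_amp * (
            np.exp(-((t - self.headgroup_offset) ** 2) / (2 * self.headgroup_sigma ** 2))
            + np.exp(-((t + self.headgroup_offset) ** 2) / (2 * self.headgroup_sigma ** 2)))
        tail = self.tail_amp * np.exp(-(t ** 2) / (2 * self.tail_sigma ** 2))
        return self.solvent_level + hg + tail

    @property
    def support(self) -> float:
        """Half-width (A) beyond which the profile is at solvent level."""
        return self.headgroup_offset + 4.0 * self.headgroup_sigma


@dataclass(frozen=True)
class LiposomeSpec:
    """One spherical liposome: center (x, y) in A, midplane radius in A."""

    center: tuple[float, float]
    radius: float
    profile: BilayerProfile = field(default_factory=BilayerProfile)

    def __post_init__(self):
        if self.radius <= 0:
            raise ValueError("liposome radius must be positive")


@dataclass(frozen=True)
class ParticleTruth:
    """Ground-truth placement of one particle on its liposome sphere.

    theta/phi locate the particle on the sphere (theta in [0, 180]; theta
    > 90 is the far hemisphere), psi is the spin about the membrane normal.
    ``offset`` is the projected (x, y) position in A in the micrograph frame.
    """

    liposome_id: int
    theta: float
    phi: float
    psi: float
    offset: tuple[float, float]


@dataclass(frozen=True)
class CTFParams:
    """Contrast-transfer-function parameters (underfocus positive)."""

    defocus_um: float = DEFAULT_DEFOCUS_UM
    voltage_kv: float = 300.0
    cs_mm: float = 2.7
    amplitude_contrast: float = 0.1
    pixel_size_a: float = DEFAULT_PIXEL_A

    def __post_init__(self):
        if self.pixel_size_a <= 0:
            raise ValueError("pixel size must be positive")
        if not 0.0 <= self.amplitude_contrast <= 1.0:
            raise ValueError("amplitude contrast must be in [0, 1]")

    @property
    def wavelength_a(self) -> float:
        v = self.voltage_kv * 1e3
        return 12.2639 / np.sqrt(v * (1.0 + 0.97845e-6 * v))


@dataclass
class Micrograph:
    """2D intensity grid plus ground truth and acquisition metadata."""

    data: np.ndarray
    pixel_size: float
    liposomes: list[LiposomeSpec] = field(default_factory=list)
    particles: list[ParticleTruth] = field(default_factory=list)
    ctf: CTFParams | None = None
    seed: int | None = None
    overlap_warning: bool = False

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape


# ---------------------------------------------------------------------------
# Spherical projection
# ---------------------------------------------------------------------------

def abel_project(g, r_values: np.ndarray, rho_max: float, dz: float = 0.5) -> np.ndarray:
    """Line-of-sight projection of a radially symmetric 3D density.

    P(r) = 2 * integral_0^inf g(sqrt(r^2 + z^2)) dz, truncated at rho_max
    (where g is assumed zero) and evaluated by the trapezoid rule with step
    ``dz`` (A).
    """
    r = np.asarray(r_values, dtype=np.float64)
    z_max = np.sqrt(max(rho_max ** 2 - np.min(r) ** 2, 0.0))
    if z_max == 0:
        return np.zeros_like(r)
    z = np.arange(0.0, z_max + dz, dz)
    rho = np.sqrt(r[:, None] ** 2 + z[None, :] ** 2)
    vals = np.asarray(g(rho))
    vals[rho > rho_max] = 0.0
    return 2.0 * np.trapezoid(vals, dx=dz, axis=1)


def project_radial_density(g, rho_max: float, pixel_size: float,
                           grid_shape: tuple[int, int],
                           center: tuple[float, float] | None = None,
                           dz: float = 0.5) -> np.ndarray:
    """Project an arbitrary radially symmetric density g(rho) onto a 2D grid."""
    ny, nx = grid_shape
    if center is None:
        center = ((nx // 2) * pixel_size, (ny // 2) * pixel_size)
    dr = pixel_size / 4.0
    r_tab = np.arange(0.0, rho_max + 2 * pixel_size, dr)
    p_tab = abel_project(g, r_tab, rho_max, dz=dz)
    r_grid = radial_distance_grid(grid_shape, center, pixel_size)
    return np.interp(r_grid, r_tab, p_tab, right=0.0)


def projected_shell_profile(profile: BilayerProfile, radius: float,
                            r_values: np.ndarray, dz: float = 0.5) -> np.ndarray:
    """Projection P(r) of the spherical bilayer shell at given in-plane radii."""
    if radius <= 0:
        raise ValueError("radius must be positive")
    lvl = profile.solvent_level
    rho_max = radius + profile.support
    return abel_project(lambda rho: profile(rho - radius) - lvl, r_values, rho_max, dz=dz)


def project_sphere_profile(profile: BilayerProfile, radius: float, pixel_size: float,
                           grid_shape: tuple[int, int],
                           center: tuple[float, float] | None = None,
                           dz: float = 0.5) -> np.ndarray:
    """Line-of-sight projection of a spherical bilayer onto a pixel grid.

    The 3D density is ``g(rho) = profile(rho - radius)`` (solvent level
    subtracted); the result is circularly symmetric about ``center``.
    Raises if the shell (radius + profile support) does not fit in the grid.
    """
    if radius <= 0:
        raise ValueError("radius must be positive")
    ny, nx = grid_shape
    if center is None:
        center = ((nx // 2) * pixel_size, (ny // 2) * pixel_size)
    extent = radius + profile.support
    cx, cy = center
    if (cx - extent < -pixel_size / 2 or cy - extent < -pixel_size / 2
            or cx + extent > (nx - 0.5) * pixel_size or cy + extent > (ny - 0.5) * pixel_size):
        raise ValueError("sphere (radius + profile tails) extends beyond the grid")
    dr = pixel_size / 4.0
    r_tab = np.arange(0.0, radius + profile.support + 2 * pixel_size, dr)
    p_tab = projected_shell_profile(profile, radius, r_tab, dz=dz)
    r_grid = radial_distance_grid(grid_shape, center, pixel_size)
    return np.interp(r_grid, r_tab, p_tab, right=0.0)


# ---------------------------------------------------------------------------
# CTF
# ---------------------------------------------------------------------------

def ctf_array(shape: tuple[int, int], ctf: CTFParams, shifted: bool = False) -> np.ndarray:
    """Evaluate CTF(f) = -(sqrt(1-w^2) sin chi + w cos chi) on an FFT grid.

    chi(f) = pi * lambda * dz * f^2 - (pi/2) * Cs * lambda^3 * f^4 with
    underfocus dz positive, so CTF(0) = -w (the CTFFIND/RELION convention).
    ``shifted`` returns the zero-frequency-centered layout.
    """
    ny, nx = shape
    fy = np.fft.fftfreq(ny, d=ctf.pixel_size_a)
    fx = np.fft.fftfreq(nx, d=ctf.pixel_size_a)
    if shifted:
        fy, fx = np.fft.fftshift(fy), np.fft.fftshift(fx)
    f2 = fy[:, None] ** 2 + fx[None, :] ** 2
    lam = ctf.wavelength_a
    dz_a = ctf.defocus_um * 1e4
    cs_a = ctf.cs_mm * 1e7
    chi = np.pi * lam * dz_a * f2 - 0.5 * np.pi * cs_a * lam ** 3 * f2 ** 2
    w = ctf.amplitude_contrast
    return -(np.sqrt(1.0 - w ** 2) * np.sin(chi) + w * np.cos(chi))


def apply_ctf(image: np.ndarray, ctf: CTFParams) -> np.ndarray:
    """Multiply an image by the CTF in the Fourier domain (real in, real out)."""
    if ctf.pixel_size_a is None or ctf.pixel_size_a <= 0:
        raise ValueError("CTF pixel size is required")
    if np.iscomplexobj(image):
        raise ValueError("image must be real-valued")
    c = ctf_array(image.shape, ctf)
    return np.fft.ifft2(np.fft.fft2(image) * c).real


# ---------------------------------------------------------------------------
# Noise
# ---------------------------------------------------------------------------

def add_noise(image: np.ndarray, dose: float, pixel_size: float,
              seed: int | np.random.Generator) -> np.ndarray:
    """Poisson shot noise at expected counts ``dose * pixel^2 * (1 + image)``.

    The image is interpreted as fractional contrast about the solvent
    intensity; the returned image is the measured contrast, so its mean
    matches the input in expectation and its pixel variance is
    ``1 / (dose * pixel^2)`` at zero contrast.
    """
    if dose <= 0:
        raise ValueError("dose must be positive")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    counts_per_px = dose * pixel_size ** 2
    lam = np.clip(counts_per_px * (1.0 + image), 0.0, None)
    counts = rng.poisson(lam)
    return counts / counts_per_px - 1.0


# ---------------------------------------------------------------------------
# Scene composition and dataset sampling
# ---------------------------------------------------------------------------

def render_scene(liposomes: list[LiposomeSpec], particles: list[ParticleTruth],
                 particle_volume: np.ndarray | None, grid_shape: tuple[int, int],
                 pixel_size: float) -> np.ndarray:
    """Sum of liposome shell projections and oriented particle projections.

    Each particle's volume is projected with orientation
    ``R = Rz(phi) @ Ry(theta) @ Rz(psi)`` (membrane normal = particle z axis,
    pointing along the sphere radius) and added at its projected offset.
    """
    img = np.zeros(grid_shape, dtype=np.float64)
    for lp in liposomes:
        img += project_sphere_profile(lp.profile, lp.radius, pixel_size,
                                      grid_shape, center=lp.center)
    if particles:
        if particle_volume is None:
            raise ValueError("particles given but no particle volume")
        proj = FourierProjector(np.asarray(particle_volume) * pixel_size)
        box = proj.n
        for pt in particles:
            pimg = proj.project(pt.theta, pt.phi, pt.psi)
            x_px = pt.offset[0] / pixel_size
            y_px = pt.offset[1] / pixel_size
            ix, iy = int(round(x_px)), int(round(y_px))
            frac = (y_px - iy, x_px - ix)
            if any(abs(f) > 1e-9 for f in frac):
                pimg = ndimage.shift(pimg, frac, order=1, mode="constant", cval=0.0)
            y0, x0 = iy - box // 2, ix - box // 2
            ys, xs = slice(max(y0, 0), min(y0 + box, grid_shape[0])), \
                slice(max(x0, 0), min(x0 + box, grid_shape[1]))
            if ys.stop <= ys.start or xs.stop <= xs.start:
                continue
            img[ys, xs] += pimg[ys.start - y0:ys.stop - y0, xs.start - x0:xs.stop - x0]
    return img


def sample_diameters(n: int, rng: np.random.Generator, mean_nm: float = 20.0,
                     support_nm: tuple[float, float] = (15.0, 70.0),
                     concentration: float = 12.0) -> np.ndarray:
    """Liposome diameters (nm) from a scaled Beta on ``support_nm``.

    The Beta shape parameters are chosen so the distribution mean equals
    ``mean_nm`` exactly; the default concentration gives a right-skewed
    distribution with most vesicles near 20 nm and a tail to 70 nm.
    """
    lo, hi = support_nm
    if not lo < mean_nm < hi:
        raise ValueError("mean diameter must lie inside the support")
    m = (mean_nm - lo) / (hi - lo)
    a, b = concentration * m, concentration * (1.0 - m)
    return lo + (hi - lo) * rng.beta(a, b, size=n)


def occupancy_count(diameter_nm: float, rng: np.random.Generator,
                    per_20nm: tuple[int, int] = (1, 2)) -> int:
    """Number of particles for a liposome: 1-2 per 20-nm vesicle, scaled by area.

    A base count is drawn uniformly from ``per_20nm`` and scaled by the
    surface-area ratio (d / 20)^2, with a floor of one particle.
    """
    base = rng.integers(per_20nm[0], per_20nm[1] + 1)
    return max(1, int(np.rint(base * (diameter_nm / 20.0) ** 2)))


def _place_liposomes(rng, diameters_a, grid_shape, pixel_size, profile,
                     margin_a=20.0, max_tries=2000):
    ny, nx = grid_shape
    placed: list[LiposomeSpec] = []
    for d in diameters_a:
        radius = d / 2.0
        extent = radius + profile.support + margin_a
        if 2 * extent >= min(nx, ny) * pixel_size:
            raise ValueError("liposome too large for the micrograph grid")
        for _ in range(max_tries):
            cx = rng.uniform(extent, nx * pixel_size - extent)
            cy = rng.uniform(extent, ny * pixel_size - extent)
            ok = all(np.hypot(cx - lp.center[0], cy - lp.center[1])
                     > radius + lp.radius + 2 * profile.support
                     for lp in placed)
            if ok:
                placed.append(LiposomeSpec((cx, cy), radius, profile))
                break
        else:
            raise ValueError("could not place liposomes: packing density infeasible")
    return placed


def sample_particles(rng, liposomes: list[LiposomeSpec],
                     per_20nm: tuple[int, int] = (1, 2),
                     min_chord_a: float = 50.0) -> list[ParticleTruth]:
    """Place particles uniformly on each liposome sphere (random spin)."""
    out: list[ParticleTruth] = []
    for lid, lp in enumerate(liposomes):
        n_p = occupancy_count(lp.radius * 2 / 10.0, rng, per_20nm)
        pts: list[np.ndarray] = []
        for _ in range(n_p):
            for _ in range(200):
                cos_t = rng.uniform(-1.0, 1.0)
                theta = np.degrees(np.arccos(cos_t))
                phi = rng.uniform(0.0, 360.0)
                st = np.sin(np.radians(theta))
                xyz = lp.radius * np.array([st * np.cos(np.radians(phi)),
                                            st * np.sin(np.radians(phi)), cos_t])
                if all(np.linalg.norm(xyz - q) > min_chord_a for q in pts):
                    pts.append(xyz)
                    psi = rng.uniform(0.0, 360.0)
                    off = (lp.center[0] + xyz[0], lp.center[1] + xyz[1])
                    out.append(ParticleTruth(lid, theta, phi, psi, off))
                    break
    return out


def sample_dataset(n_micrographs: int, seed: int,
                   grid_shape: tuple[int, int] = (1024, 1024),
                   pixel_size: float = DEFAULT_PIXEL_A,
                   mean_diameter_nm: float = 20.0,
                   support_nm: tuple[float, float] = (15.0, 70.0),
                   liposomes_per_micrograph: int = 8,
                   particles_per_20nm: tuple[int, int] = (1, 2),
                   dose: float = DEFAULT_DOSE_E_PER_A2,
                   defocus_range_um: tuple[float, float] = (3.3, 4.3),
                   profile: BilayerProfile | None = None,
                   particle_volume: np.ndarray | None = None,
                   add_shot_noise: bool = True) -> list[Micrograph]:
    """Generate micrographs with attached ground truth.

    Defaults encode the study conditions: mean 20 nm diameters on [15, 70] nm,
    1-2 particles per 20-nm liposome (area-scaled), 60 e-/A^2 dose, defocus
    near -3.8 um. The liposome count per micrograph defaults to a typical
    areal density for such collections (26 per 0.16 um^2 field of view)
    scaled to the simulated field of view.
    """
    profile = profile or BilayerProfile()
    root = np.random.SeedSequence(seed)
    out: list[Micrograph] = []
    for i, ss in enumerate(root.spawn(n_micrographs)):
        rng = np.random.default_rng(ss)
        diameters_a = sample_diameters(liposomes_per_micrograph, rng,
                                       mean_nm=mean_diameter_nm,
                                       support_nm=support_nm) * 10.0
        liposomes = _place_liposomes(rng, diameters_a, grid_shape, pixel_size, profile)
        particles = (sample_particles(rng, liposomes, particles_per_20nm)
                     if particle_volume is not None else [])
        ctf = CTFParams(defocus_um=rng.uniform(*defocus_range_um),
                        pixel_size_a=pixel_size)
        img = render_scene(liposomes, particles, particle_volume, grid_shape, pixel_size)
        img = apply_ctf(img, ctf)
        if add_shot_noise:
            img = add_noise(img, dose, pixel_size, rng)
        out.append(Micrograph(data=img.astype(np.float64), pixel_size=pixel_size,
                              liposomes=liposomes, particles=particles,
                              ctf=ctf, seed=seed))
    return out
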