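"""Liposome detection, spherical-bilayer model fitting, and membrane subtraction.

Vesicle sizes vary continuously, so their images cannot be averaged away;
instead each liposome's membrane contribution is modeled as the CTF-convolved
projection of a spherical bilayer shell and subtracted, leaving the embedded
protein densities for alignment.

Because the shell projection and the CTF are both isotropic, the convolved
model image is exactly circularly symmetric about the liposome center. Fitting
therefore reduces to a 1D radial profile evaluated at sub-pixel centers: a
derivative-free simplex search over (center_x, center_y, radius) with the
amplitude and local background solved in closed form per iterate, minimizing
the squared residual in an annulus around the membrane circle.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from scipy import optimize
from skimage.feature import match_template, peak_local_max

from .sim_micrograph import BilayerProfile, CTFParams, Micrograph, apply_ctf, \
    project_sphere_profile

DEFAULT_RADIUS_BOUNDS_A = (60.0, 400.0)
DEFAULT_ANNULUS_HALFWIDTH_A = 60.0


@dataclass
class LiposomeFit:
    """Fitted spherical-bilayer model of one liposome."""

    center: tuple[float, float]     # (x, y) in A
    radius: float                   # midplane radius, A
    amplitude: float = 1.0          # scale of the shared bilayer profile
    background: float = 0.0         # local additive offset
    residual_rms: float = np.nan    # RMS of the annulus residual
    converged: bool = False
    score: float = np.nan           # detection NCC score, if any


def _image_of(m) -> np.ndarray:
    return m.data if isinstance(m, Micrograph) else np.asarray(m)


def _ctf_pad_a(ctf: CTFParams, pixel_size: float) -> float:
    """Radius (A) containing the CTF point-spread delocalization at Nyquist."""
    if ctf is None:
        return 60.0
    return ctf.wavelength_a * ctf.defocus_um * 1e4 * (0.5 / pixel_size) + 60.0


@lru_cache(maxsize=16)
def _ctf_grid_cached(shape: tuple[int, int], ctf: CTFParams) -> np.ndarray:
    from .sim_micrograph import ctf_array

    return ctf_array(shape, ctf)


@lru_cache(maxsize=16)
def _radial_bins_cached(n: int, bin_width_px: float):
    c = n // 2
    yy, xx = np.indices((n, n))
    bins = np.round(np.hypot(yy - c, xx - c) / bin_width_px).astype(int).ravel()
    counts = np.bincount(bins)
    return bins, counts


def ctf_convolved_shell_profile(profile: BilayerProfile, radius: float,
                                ctf: CTFParams | None, pixel_size: float,
                                bin_width_px: float = 0.25):
    """Radial profile of the CTF-convolved projected shell.

    Renders the shell projection on a padded patch, applies the CTF there,
    and radially averages (the result is radial by symmetry; averaging only
    suppresses interpolation noise). Returns ``(r_A, values)`` with ``r_A``
    sampled every ``bin_width_px`` pixels.
    """
    from scipy.fft import next_fast_len

    pad = _ctf_pad_a(ctf, pixel_size) if ctf is not None else 40.0
    half_a = radius + profile.support + pad
    n = next_fast_len(int(2 * np.ceil(half_a / pixel_size)) + 2, real=True)
    n += n % 2
    patch = project_sphere_profile(profile, radius, pixel_size, (n, n))
    if ctf is not None:
        patch = np.fft.irfft2(np.fft.rfft2(patch)
                              * _ctf_grid_cached((n, n), ctf)[:, :n // 2 + 1],
                              s=(n, n))
    bins, counts = _radial_bins_cached(n, bin_width_px)
    sums = np.bincount(bins, weights=patch.ravel())
    vals = sums / np.maximum(counts, 1)
    r_a = np.arange(len(vals)) * bin_width_px * pixel_size
    keep = r_a <= half_a
    return r_a[keep], vals[keep]


def render_fitted_liposome(fit: LiposomeFit, profile: BilayerProfile,
                           ctf: CTFParams | None, pixel_size: float,
                           grid_shape: tuple[int, int],
                           table=None) -> np.ndarray:
    """CTF-convolved model image of one fitted liposome on the full grid.

    Only the disk within the model support is rendered (zero elsewhere);
    ``table`` may carry a precomputed ``(r_A, values)`` radial profile.
    """
    if table is None:
        if ctf is None:
            from .sim_micrograph import projected_shell_profile

            r_tab = np.arange(0.0, fit.radius + profile.support + 2 * pixel_size,
                              pixel_size / 4.0)
            table = (r_tab, projected_shell_profile(profile, fit.radius, r_tab))
        else:
            table = ctf_convolved_shell_profile(profile, fit.radius, ctf,
                                                pixel_size)
    r_tab, v_tab = table
    out = np.zeros(grid_shape, dtype=np.float64)
    cx, cy = fit.center
    half = r_tab[-1]
    x0 = max(int((cx - half) / pixel_size) - 1, 0)
    x1 = min(int((cx + half) / pixel_size) + 2, grid_shape[1])
    y0 = max(int((cy - half) / pixel_size) - 1, 0)
    y1 = min(int((cy + half) / pixel_size) + 2, grid_shape[0])
    if x1 <= x0 or y1 <= y0:
        return out
    yy = np.arange(y0, y1) * pixel_size - cy
    xx = np.arange(x0, x1) * pixel_size - cx
    r = np.hypot(yy[:, None], xx[None, :])
    out[y0:y1, x0:x1] = fit.amplitude * np.interp(r, r_tab, v_tab, right=0.0)
    return out


# ---------------------------------------------------------------------------
# Detection
# ---------------------------------------------------------------------------

def detect_liposomes(micrograph, ctf: CTFParams | None,
                     radius_range: tuple[float, float] = (75.0, 350.0),
                     pixel_size: float | None = None,
                     profile: BilayerProfile | None = None,
                     n_radii: int = 8, threshold: float = 0.12,
                     min_separation_frac: float = 0.5) -> list[LiposomeFit]:
    """Multi-radius ring-template NCC detection of liposome candidates.

    Templates are CTF-convolved shell projections at ``n_radii`` radii spanning
    ``radius_range``; candidates are local maxima of the max-over-radii
    normalized cross-correlation above ``threshold``, then greedily suppressed
    so no two kept circles have center separation below
    ``min_separation_frac * (R_i + R_j)``.
    """
    img = _image_of(micrograph)
    if pixel_size is None:
        pixel_size = micrograph.pixel_size if isinstance(micrograph, Micrograph) else None
    if pixel_size is None:
        raise ValueError("pixel_size required when passing a bare array")
    profile = profile or BilayerProfile()
    lo, hi = radius_range
    if lo < DEFAULT_RADIUS_BOUNDS_A[0] or hi > DEFAULT_RADIUS_BOUNDS_A[1]:
        raise ValueError("radius_range outside model bounds")
    radii = np.geomspace(lo, hi, n_radii)
    best = np.full(img.shape, -np.inf)
    best_r = np.zeros(img.shape)
    for radius in radii:
        r_tab, v_tab = ctf_convolved_shell_profile(profile, radius, ctf, pixel_size)
        # compact ring template: keep the membrane annulus plus a short skirt
        half = radius + profile.support + 40.0
        nt = int(2 * np.ceil(half / pixel_size)) + 1
        c = nt // 2
        yy, xx = np.indices((nt, nt))
        r = np.hypot(yy - c, xx - c) * pixel_size
        tmpl = np.interp(r, r_tab, v_tab, right=0.0)
        if nt >= min(img.shape):
            continue
        ncc = match_template(img, tmpl, pad_input=True, mode="constant")
        upd = ncc > best
        best[upd] = ncc[upd]
        best_r[upd] = radius
    min_dist = max(int(lo / pixel_size), 1)
    peaks = peak_local_max(best, min_distance=min_dist, threshold_abs=threshold,
                           exclude_border=False)
    cands = []
    for y, x in peaks:
        center = (x * pixel_size, y * pixel_size)
        radius, score = _refine_radius(img, center, best_r[y, x], profile, ctf,
                                       pixel_size, radius_range)
        cands.append(LiposomeFit(center=center, radius=radius, score=score))
    cands.sort(key=lambda f: -f.score)
    kept: list[LiposomeFit] = []
    for cand in cands:
        ok = all(np.hypot(cand.center[0] - k.center[0], cand.center[1] - k.center[1])
                 >= min_separation_frac * (cand.radius + k.radius) for k in kept)
        if ok:
            kept.append(cand)
    return kept


def _refine_radius(img, center, radius0, profile, ctf, pixel_size, radius_range,
                   n_steps: int = 18):
    """Refine a candidate's radius by NCC over a fine radius ladder.

    Scans the whole allowed radius range (the coarse multi-radius detection
    map can lock onto the wrong ring when vesicles sit close together)."""
    cx, cy = center
    best_r, best_s = radius0, -np.inf
    for radius in np.geomspace(radius_range[0], radius_range[1], n_steps):
        r_tab, v_tab = ctf_convolved_shell_profile(profile, radius, ctf, pixel_size)
        half = radius + profile.support + 40.0
        ny, nx = img.shape
        x0, x1 = max(int((cx - half) / pixel_size), 0), min(int((cx + half) / pixel_size) + 1, nx)
        y0, y1 = max(int((cy - half) / pixel_size), 0), min(int((cy + half) / pixel_size) + 1, ny)
        yy = np.arange(y0, y1) * pixel_size - cy
        xx = np.arange(x0, x1) * pixel_size - cx
        r = np.hypot(yy[:, None], xx[None, :])
        m = np.interp(r, r_tab, v_tab, right=0.0)
        d = img[y0:y1, x0:x1]
        mz, dz = m - m.mean(), d - d.mean()
        denom = np.sqrt((mz ** 2).sum() * (dz ** 2).sum())
        s = float((mz * dz).sum() / denom) if denom > 0 else -np.inf
        if s > best_s:
            best_r, best_s = float(radius), s
    return best_r, best_s


# ---------------------------------------------------------------------------
# Fitting
# ---------------------------------------------------------------------------

def _annulus_residual(img, cx, cy, radius, table, pixel_size, halfwidth,
                      return_fit=False, trim=0.15):
    """Annulus objective with amplitude/background solved exactly.

    Returns the *unexplained variance fraction*: residual mean square divided
    by the annulus data variance. Normalizing per annulus is essential — the
    raw residual MS of a wrong circle over plain background equals the noise
    variance, the same value a perfect fit attains, so raw MS cannot rank
    circles that cover different pixels.
    """
    r_tab, v_tab = table
    half = radius + halfwidth + 2 * pixel_size
    ny, nx = img.shape
    x0 = max(int((cx - half) / pixel_size) - 1, 0)
    x1 = min(int((cx + half) / pixel_size) + 2, nx)
    y0 = max(int((cy - half) / pixel_size) - 1, 0)
    y1 = min(int((cy + half) / pixel_size) + 2, ny)
    yy = np.arange(y0, y1) * pixel_size - cy
    xx = np.arange(x0, x1) * pixel_size - cx
    r = np.hypot(yy[:, None], xx[None, :])
    sel = np.abs(r - radius) <= halfwidth
    if sel.sum() < 16:
        return (np.inf, 0.0, 0.0, np.inf) if return_fit else np.inf
    m = np.interp(r[sel], r_tab, v_tab, right=0.0)
    d = img[y0:y1, x0:x1][sel]
    a_mat = np.column_stack([m, np.ones_like(m)])
    coef, *_ = np.linalg.lstsq(a_mat, d, rcond=None)
    if trim > 0:
        # robust refit: embedded particles are outliers against the membrane
        # model; drop the highest-residual pixels and re-solve
        resid0 = np.abs(d - a_mat @ coef)
        keep = resid0 <= np.quantile(resid0, 1.0 - trim)
        if keep.sum() >= 16:
            coef, *_ = np.linalg.lstsq(a_mat[keep], d[keep], rcond=None)
            a_mat, d = a_mat[keep], d[keep]
    resid = d - a_mat @ coef
    ms = float(np.mean(resid ** 2))
    var_d = float(np.var(d))
    frac = ms / var_d if var_d > 0 else np.inf
    if return_fit:
        return frac, float(coef[0]), float(coef[1]), float(np.sqrt(ms))
    return frac


def fit_liposome(micrograph, init: LiposomeFit, ctf: CTFParams | None,
                 profile: BilayerProfile | None = None,
                 pixel_size: float | None = None,
                 radius_bounds: tuple[float, float] = DEFAULT_RADIUS_BOUNDS_A,
                 annulus_halfwidth: float = DEFAULT_ANNULUS_HALFWIDTH_A,
                 max_iter: int = 300) -> LiposomeFit:
    """Refine one liposome fit by Nelder-Mead over (x, y, R).

    The amplitude and background are linear and solved per iterate, so the
    simplex works in three dimensions only. A fit that diverges or pins to the
    radius bounds is flagged non-converged (best iterate retained).
    """
    img = _image_of(micrograph)
    if pixel_size is None:
        pixel_size = micrograph.pixel_size if isinstance(micrograph, Micrograph) else None
    if pixel_size is None:
        raise ValueError("pixel_size required when passing a bare array")
    profile = profile or BilayerProfile()
    if not radius_bounds[0] <= init.radius <= radius_bounds[1]:
        raise ValueError("initial radius outside bounds")

    cache: dict[float, tuple] = {}

    def table_for(radius: float):
        key = round(radius, 2)
        if key not in cache:
            cache[key] = ctf_convolved_shell_profile(profile, radius, ctf, pixel_size)
        return cache[key]

    def objective(p):
        cx, cy, radius = p
        if not radius_bounds[0] <= radius <= radius_bounds[1]:
            return 1e9 * (1 + abs(radius))
        return _annulus_residual(img, cx, cy, radius, table_for(radius),
                                 pixel_size, annulus_halfwidth)

    def refine(x0):
        step = np.array([2 * pixel_size, 2 * pixel_size, max(0.03 * x0[2], pixel_size)])
        simplex = np.vstack([x0, x0 + np.diag(step)])
        return optimize.minimize(objective, x0, method="Nelder-Mead",
                                 options={"initial_simplex": simplex,
                                          "xatol": 0.04 * pixel_size, "fatol": 1e-9,
                                          "maxiter": max_iter})

    x0 = np.array([init.center[0], init.center[1], init.radius])
    res = refine(x0)
    # guard against a wrong-radius local minimum (e.g. locking onto an inner
    # CTF fringe): sweep the radius at the refined center and restart while a
    # distinctly better annulus objective exists elsewhere
    sweep = np.linspace(radius_bounds[0], radius_bounds[1], 26)
    for _ in range(3):
        sweep_obj = [objective(np.array([res.x[0], res.x[1], r])) for r in sweep]
        r_best = sweep[int(np.argmin(sweep_obj))]
        if not (min(sweep_obj) < 0.95 * res.fun
                and abs(r_best - res.x[2]) > 2 * pixel_size):
            break
        res2 = refine(np.array([res.x[0], res.x[1], r_best]))
        if res2.fun >= res.fun:
            break
        res = res2
    cx, cy, radius = res.x
    frac, amp, bg, rms = _annulus_residual(img, cx, cy, radius, table_for(radius),
                                           pixel_size, annulus_halfwidth,
                                           return_fit=True)
    at_bound = (radius - radius_bounds[0] < 0.01 * radius
                or radius_bounds[1] - radius < 0.01 * radius)
    converged = bool(np.isfinite(frac)) and not at_bound and res.status in (0, 2)
    return LiposomeFit(center=(float(cx), float(cy)), radius=float(radius),
                       amplitude=amp, background=bg,
                       residual_rms=rms, converged=converged,
                       score=init.score)


def fit_micrograph(micrograph, ctf: CTFParams | None = None,
                   profile: BilayerProfile | None = None,
                   radius_range: tuple[float, float] = (75.0, 350.0),
                   pixel_size: float | None = None,
                   **detect_kwargs) -> list[LiposomeFit]:
    """Detect then refine every liposome in a micrograph."""
    if ctf is None and isinstance(micrograph, Micrograph):
        ctf = micrograph.ctf
    cands = detect_liposomes(micrograph, ctf, radius_range=radius_range,
                             profile=profile, pixel_size=pixel_size,
                             **detect_kwargs)
    fits = [fit_liposome(micrograph, c, ctf, profile=profile,
                         pixel_size=pixel_size) for c in cands]
    # refined fits can converge onto the same vesicle from duplicate
    # detections; keep the lower-residual fit of any coincident pair
    fits.sort(key=lambda f: f.residual_rms if np.isfinite(f.residual_rms) else np.inf)
    kept: list[LiposomeFit] = []
    for f in fits:
        dup = any(np.hypot(f.center[0] - k.center[0], f.center[1] - k.center[1])
                  < 0.5 * max(f.radius, k.radius) for k in kept)
        if not dup:
            kept.append(f)
    return kept


# ---------------------------------------------------------------------------
# Subtraction
# ---------------------------------------------------------------------------

def subtract_liposomes(micrograph, fits: list[LiposomeFit],
                       ctf: CTFParams | None = None,
                       profile: BilayerProfile | None = None,
                       pixel_size: float | None = None):
    """Subtract the fitted, CTF-convolved membrane models from a micrograph.

    Only converged fits are subtracted (the fitted local background is a
    property of the image, not of the membrane, and is left in place).
    Returns ``(subtracted_image, info)``; ``info['overlaps']`` flags pairs of
    fitted circles that overlap.
    """
    img = _image_of(micrograph).copy()
    if pixel_size is None:
        pixel_size = micrograph.pixel_size if isinstance(micrograph, Micrograph) else None
    if pixel_size is None:
        raise ValueError("pixel_size required when passing a bare array")
    if ctf is None and isinstance(micrograph, Micrograph):
        ctf = micrograph.ctf
    profile = profile or BilayerProfile()
    used = [f for f in fits if f.converged]
    overlaps = []
    for i in range(len(used)):
        for j in range(i + 1, len(used)):
            d = np.hypot(used[i].center[0] - used[j].center[0],
                         used[i].center[1] - used[j].center[1])
            if d < used[i].radius + used[j].radius:
                overlaps.append((i, j))
    # render every un-convolved shell on the full grid, then apply the CTF
    # once (it is linear): this matches the imaging model exactly, with no
    # radial-binning approximation in what gets subtracted
    canvas = np.zeros_like(img)
    for f in used:
        canvas += render_fitted_liposome(f, profile, None, pixel_size, img.shape)
    if used:
        img -= apply_ctf(canvas, ctf) if ctf is not None else canvas
    info = {"n_subtracted": len(used), "n_skipped": len(fits) - len(used),
            "overlaps": overlaps}
    return img, info
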