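"""Particle picking, liposome-distance screening, and box extraction.

Picking runs template matching (normalized cross-correlation, maximum over
templates and in-plane rotations) on liposome-subtracted micrographs. Picks
are then screened by their distance to the nearest fitted membrane circle —
membrane proteins must sit in a membrane, so picks more than a cutoff
(default 80 A) from every liposome are rejected. "Distance" is the 2D
distance to the projected membrane circle, ``| ||p - c|| - R |``, not to the
liposome center: a center-based rule would scale with vesicle size and make a
fixed cutoff meaningless for large vesicles.

Default extraction geometry: 27 nm box with a 17 nm circular mask.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import ndimage
from skimage.feature import match_template, peak_local_max

from .liposome_model import LiposomeFit
from .sim_micrograph import Micrograph
from .util import soft_circular_mask

DEFAULT_SCREEN_CUTOFF_A = 80.0
DEFAULT_BOX_NM = 27.0
DEFAULT_MASK_NM = 17.0


@dataclass(frozen=True)
class ParticlePick:
    """One picked particle candidate."""

    position: tuple[float, float]        # (x, y) in pixels
    score: float                         # NCC score
    micrograph_id: int = 0
    nearest_liposome: int = -1
    membrane_distance: float = np.nan    # A, to the nearest membrane circle
    kept: bool = True


@dataclass
class ParticleStack:
    """Boxed particle images plus per-particle metadata."""

    images: np.ndarray                   # (n, box, box)
    pixel_size: float
    box_nm: float = DEFAULT_BOX_NM
    mask_nm: float = DEFAULT_MASK_NM
    picks: list[ParticlePick] = None
    n_dropped_edge: int = 0

    def __post_init__(self):
        if self.mask_nm >= self.box_nm:
            raise ValueError("mask diameter must be smaller than the box")


def _image_of(m) -> np.ndarray:
    return m.data if isinstance(m, Micrograph) else np.asarray(m)


# ---------------------------------------------------------------------------
# Picking
# ---------------------------------------------------------------------------

def pick_particles(micrograph, templates, threshold: float = 0.15,
                   n_rotations: int = 8, min_distance_px: int | None = None,
                   micrograph_id: int = 0) -> list[ParticlePick]:
    """Template-matching particle picker.

    The score map is the maximum, over all templates and ``n_rotations``
    in-plane rotations of each, of the normalized cross-correlation with the
    micrograph; picks are its local maxima above ``threshold`` after
    non-maximum suppression at ``min_distance_px`` (default: half a template
    edge).
    """
    img = _image_of(micrograph)
    templates = [np.asarray(t, dtype=np.float64) for t in templates]
    if not templates:
        raise ValueError("at least one template required")
    box = templates[0].shape[0]
    if min_distance_px is None:
        min_distance_px = max(box // 2, 1)
    best = np.full(img.shape, -np.inf)
    for tmpl in templates:
        for k in range(n_rotations):
            ang = 360.0 * k / n_rotations
            t = tmpl if ang == 0 else ndimage.rotate(tmpl, ang, reshape=False,
                                                     order=1, mode="constant")
            ncc = match_template(img, t, pad_input=True, mode="constant")
            np.maximum(best, ncc, out=best)
    peaks = peak_local_max(best, min_distance=min_distance_px,
                           threshold_abs=threshold, exclude_border=False)
    return [ParticlePick(position=(float(x), float(y)), score=float(best[y, x]),
                         micrograph_id=micrograph_id)
            for y, x in peaks]


def make_templates(volume: np.ndarray, n_templates: int = 10,
                   pixel_size: float | None = None, ctf=None,
                   crop_px: int | None = None) -> list[np.ndarray]:
    """Reference projections over a tilt series, for use as picking templates.

    Stands in for the class averages a full 2D classification would supply:
    evenly spaced tilts from top view to side view (varied azimuths),
    CTF-modulated when ``ctf`` is given (micrographs carry the CTF, so
    templates must too), and cropped to ``crop_px`` so the NCC normalization
    window hugs the particle.
    """
    from .fourier import FourierProjector
    from .sim_micrograph import apply_ctf

    proj = FourierProjector(np.asarray(volume) * (pixel_size or 1.0))
    tilts = np.linspace(0.0, 90.0, n_templates)
    out = []
    for i, t in enumerate(tilts):
        img = proj.project(t, 37.0 * i, 0.0)
        if ctf is not None:
            img = apply_ctf(img, ctf)
        if crop_px:
            n = img.shape[0]
            lo = (n - crop_px) // 2
            img = img[lo:lo + crop_px, lo:lo + crop_px]
        out.append(img)
    return out


# ---------------------------------------------------------------------------
# Screening
# ---------------------------------------------------------------------------

def annotate_membrane_distance(picks: list[ParticlePick], fits: list[LiposomeFit],
                               pixel_size: float) -> list[ParticlePick]:
    """Return picks annotated with the distance to the nearest membrane circle."""
    out = []
    for p in picks:
        px_a = (p.position[0] * pixel_size, p.position[1] * pixel_size)
        best_d, best_i = np.inf, -1
        for i, f in enumerate(fits):
            d = abs(np.hypot(px_a[0] - f.center[0], px_a[1] - f.center[1]) - f.radius)
            if d < best_d:
                best_d, best_i = d, i
        out.append(replace(p, membrane_distance=float(best_d), nearest_liposome=best_i))
    return out


def screen_particles(picks: list[ParticlePick], fits: list[LiposomeFit],
                     pixel_size: float,
                     cutoff: float = DEFAULT_SCREEN_CUTOFF_A) -> list[ParticlePick]:
    """Keep picks within ``cutoff`` (A) of some fitted membrane circle.

    With no fits every pick is excluded (membrane distance undefined).
    The returned picks carry their membrane distance and owning liposome.
    """
    if cutoff < 0:
        raise ValueError("cutoff must be non-negative")
    if not fits:
        import warnings

        warnings.warn("no liposome fits: all picks excluded", stacklevel=2)
        return []
    annotated = annotate_membrane_distance(picks, fits, pixel_size)
    return [replace(p, kept=True) for p in annotated if p.membrane_distance <= cutoff]


# ---------------------------------------------------------------------------
# Extraction
# ---------------------------------------------------------------------------

def extract_boxes(micrograph, picks: list[ParticlePick],
                  pixel_size: float | None = None,
                  box_nm: float = DEFAULT_BOX_NM, mask_nm: float = DEFAULT_MASK_NM,
                  normalize: bool = True, apply_mask: bool = True) -> ParticleStack:
    """Extract boxed particle images at integer pixel positions.

    Picks whose box would cross the micrograph edge are dropped (counted in
    ``n_dropped_edge``). With ``normalize`` each box is standardized to mean 0
    / variance 1 using the pixels outside the mask radius; with ``apply_mask``
    a soft circular mask (3-pixel raised-cosine edge) is applied afterwards.
    """
    img = _image_of(micrograph)
    if pixel_size is None:
        pixel_size = micrograph.pixel_size if isinstance(micrograph, Micrograph) else None
    if pixel_size is None:
        raise ValueError("pixel_size required when passing a bare array")
    box = int(round(box_nm * 10.0 / pixel_size))
    box -= box % 2
    if box > min(img.shape):
        raise ValueError("box larger than micrograph")
    mask_r_px = mask_nm * 10.0 / (2 * pixel_size)
    mask = soft_circular_mask((box, box), mask_r_px * pixel_size,
                              pixel_size=pixel_size,
                              edge_width=3 * pixel_size)
    outside = soft_circular_mask((box, box), mask_r_px * pixel_size,
                                 pixel_size=pixel_size, edge_width=0.0) == 0
    images, kept_picks, dropped = [], [], 0
    for p in picks:
        ix, iy = int(round(p.position[0])), int(round(p.position[1]))
        y0, x0 = iy - box // 2, ix - box // 2
        if y0 < 0 or x0 < 0 or y0 + box > img.shape[0] or x0 + box > img.shape[1]:
            dropped += 1
            continue
        crop = img[y0:y0 + box, x0:x0 + box].astype(np.float64).copy()
        if normalize:
            mu = crop[outside].mean()
            sd = crop[outside].std()
            crop = (crop - mu) / (sd if sd > 0 else 1.0)
        if apply_mask:
            crop = crop * mask
        images.append(crop)
        kept_picks.append(p)
    arr = np.array(images) if images else np.zeros((0, box, box))
    return ParticleStack(images=arr, pixel_size=pixel_size, box_nm=box_nm,
                         mask_nm=mask_nm, picks=kept_picks, n_dropped_edge=dropped)
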