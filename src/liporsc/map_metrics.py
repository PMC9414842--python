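"""Rotational-symmetry scoring and map-to-map comparison.

The central structural question the reconstruction raises is whether a map is
four-fold or only two-fold symmetric about the pore axis. The score used here
is the masked Pearson correlation between a map and its copy rotated by
360/n degrees about z: a C2-but-not-C4 map scores high at n = 2 and visibly
lower at n = 4.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .fourier import rotate_about_z as _rotate_z
from .rsc_reconstruct import DensityMap
from .util import masked_pearson, soft_spherical_mask


@dataclass
class SymmetryReport:
    """Correlation of a map with its 360/n-degree rotation about z."""

    order: int
    correlation: float
    mask_radius_a: float
    axis: str = "z"


def _mask_for(map_: DensityMap, mask_radius_a: float | None,
              inner_radius_a: float = 0.0) -> np.ndarray:
    n = map_.data.shape[0]
    if mask_radius_a is None:
        mask_radius_a = 0.45 * n * map_.pixel_size
    r_px = mask_radius_a / map_.pixel_size
    if r_px > n // 2:
        raise ValueError("mask radius outside the grid")
    return soft_spherical_mask(n, r_px, edge_width_px=3.0,
                               inner_radius_px=inner_radius_a / map_.pixel_size)


def symmetry_correlation(map_: DensityMap, order: int,
                         mask_radius_a: float | None = None,
                         inner_radius_a: float = 0.0) -> SymmetryReport:
    """Masked Pearson correlation between a map and its Cn-generating rotation.

    ``order == 1`` is the identity and returns exactly 1.
    """
    if order < 1:
        raise ValueError("symmetry order must be >= 1")
    mask = _mask_for(map_, mask_radius_a, inner_radius_a)
    if mask_radius_a is None:
        mask_radius_a = 0.45 * map_.data.shape[0] * map_.pixel_size
    if order == 1:
        return SymmetryReport(order=1, correlation=1.0, mask_radius_a=mask_radius_a)
    rot = _rotate_z(map_.data, 360.0 / order)
    corr = masked_pearson(map_.data, rot, mask)
    return SymmetryReport(order=order, correlation=corr, mask_radius_a=mask_radius_a)


def compare_maps(map_a: DensityMap, map_b: DensityMap,
                 mask: np.ndarray | None = None,
                 mask_radius_a: float | None = None,
                 resample: bool = False):
    """Masked correlation plus a per-shell correlation curve between two maps.

    Returns ``(correlation, frequency_1_per_A, shell_correlation)``. Grids
    must match unless ``resample`` is set, in which case B is resampled onto
    A's grid by zoom interpolation.
    """
    a, b = map_a.data, map_b.data
    if a.shape != b.shape or map_a.pixel_size != map_b.pixel_size:
        if not resample:
            raise ValueError("maps differ in grid/pixel size (pass resample=True)")
        # resample B onto A's grid (assumes equal physical box extents)
        b = ndimage.zoom(map_b.data, np.array(a.shape) / np.array(map_b.data.shape),
                         order=1)
    if mask is None:
        mask = _mask_for(map_a, mask_radius_a)
    corr = masked_pearson(a, b, mask)
    # shell-resolved correlation of the masked maps
    n = a.shape[0]
    w = mask
    fa = np.fft.fftshift(np.fft.fftn(np.fft.ifftshift(a * w)))
    fb = np.fft.fftshift(np.fft.fftn(np.fft.ifftshift(b * w)))
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
    shell_corr = np.where(denom > 0, cross / np.maximum(denom, 1e-300), 0.0)
    freq = np.arange(n_shells) / (n * map_a.pixel_size)
    return corr, freq, shell_corr
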