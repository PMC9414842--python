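"""Small shared numerical helpers (grids, masks, binning, correlation)."""

from __future__ import annotations

import numpy as np


def radial_distance_grid(shape: tuple[int, int], center: tuple[float, float],
                         pixel_size: float = 1.0) -> np.ndarray:
    """Distance (in physical units) of every pixel center from ``center``.

    ``center`` is (x, y) in physical units; pixels are centered, 0-based,
    origin at the top-left pixel center.
    """
    ny, nx = shape
    y = np.arange(ny) * pixel_size - center[1]
    x = np.arange(nx) * pixel_size - center[0]
    return np.hypot(y[:, None], x[None, :])


def soft_circular_mask(shape: tuple[int, int], radius: float,
                       center: tuple[float, float] | None = None,
                       pixel_size: float = 1.0, edge_width: float = 0.0) -> np.ndarray:
    """Circular mask with an optional raised-cosine edge of ``edge_width``."""
    ny, nx = shape
    if center is None:
        center = ((nx // 2) * pixel_size, (ny // 2) * pixel_size)
    r = radial_distance_grid(shape, center, pixel_size)
    if edge_width <= 0:
        return (r <= radius).astype(np.float64)
    m = np.clip((radius + edge_width - r) / edge_width, 0.0, 1.0)
    return 0.5 - 0.5 * np.cos(np.pi * m)


def soft_spherical_mask(n: int, radius_px: float, edge_width_px: float = 3.0,
                        inner_radius_px: float = 0.0) -> np.ndarray:
    """Soft spherical (or spherical-shell) mask on an n^3 grid centered at n//2."""
    ax = np.arange(n) - n // 2
    r = np.sqrt(ax[:, None, None] ** 2 + ax[None, :, None] ** 2 + ax[None, None, :] ** 2)
    if edge_width_px <= 0:
        m = (r <= radius_px).astype(np.float64)
    else:
        m = 0.5 - 0.5 * np.cos(np.pi * np.clip((radius_px + edge_width_px - r) / edge_width_px, 0, 1))
    if inner_radius_px > 0:
        if edge_width_px <= 0:
            m *= (r >= inner_radius_px)
        else:
            m *= 0.5 - 0.5 * np.cos(np.pi * np.clip((r - (inner_radius_px - edge_width_px)) / edge_width_px, 0, 1))
    return m


def masked_pearson(a: np.ndarray, b: np.ndarray, mask: np.ndarray | None = None) -> float:
    """Pearson correlation of two arrays under an optional (soft) weight mask."""
    a = np.asarray(a, dtype=np.float64).ravel()
    b = np.asarray(b, dtype=np.float64).ravel()
    if mask is None:
        w = np.ones_like(a)
    else:
        w = np.asarray(mask, dtype=np.float64).ravel()
    wsum = w.sum()
    am = (w * a).sum() / wsum
    bm = (w * b).sum() / wsum
    da, db = a - am, b - bm
    cov = (w * da * db).sum()
    va = (w * da * da).sum()
    vb = (w * db * db).sum()
    if va == 0 or vb == 0:
        return 0.0
    return float(cov / np.sqrt(va * vb))


def bin_image(img: np.ndarray, factor: int) -> np.ndarray:
    """Block-average binning; trims edges that do not divide evenly."""
    if factor == 1:
        return img
    ny, nx = img.shape[-2:]
    ny2, nx2 = (ny // factor) * factor, (nx // factor) * factor
    v = img[..., :ny2, :nx2]
    shape = v.shape[:-2] + (ny2 // factor, factor, nx2 // factor, factor)
    return v.reshape(shape).mean(axis=(-3, -1))


def derive_seed(root_seed: int, *path: int | str) -> int:
    """Deterministically derive a sub-seed below 2^31 from a root seed and a path."""
    import hashlib

    token = "/".join([str(int(root_seed))] + [str(p) for p in path])
    digest = hashlib.sha256(token.encode()).digest()
    return int.from_bytes(digest[:4], "little") % (2 ** 31 - 1)
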