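"""Central-slice Fourier projection and direct Fourier inversion.

Conventions
-----------
* Volumes are numpy arrays indexed ``[z, y, x]`` with a cubic, even-sized grid.
* Images are indexed ``[y, x]`` with the same pixel size as the volume.
* An orientation is the ZYZ triple ``(theta, phi, psi)`` in degrees building

      R = Rz(phi) @ Ry(theta) @ Rz(psi)

  which places a particle in the laboratory frame (``x_lab = R @ x_particle``).
  For a particle sitting in a spherical membrane, ``theta`` is the tilt of the
  membrane normal from the beam axis, ``phi`` the azimuth of the normal in the
  image plane (the bearing from liposome center to particle), and ``psi`` the
  spin about the membrane normal.
* The micrograph records the projection of the laboratory-frame density along
  ``z`` (the beam axis); by the projection theorem that projection's 2D
  transform is the central slice of the volume transform sampled at
  ``q = R^T (kx, ky, 0)``.

Interpolation is trilinear for both slice extraction and slice insertion.
"""

from __future__ import annotations

import numpy as np


def rotation_matrix_zyz(theta: float, phi: float, psi: float) -> np.ndarray:
    """Rotation matrix Rz(phi) @ Ry(theta) @ Rz(psi), angles in degrees."""
    t, f, p = np.deg2rad([theta, phi, psi])

    def rz(a):
        c, s = np.cos(a), np.sin(a)
        return np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])

    def ry(a):
        c, s = np.cos(a), np.sin(a)
        return np.array([[c, 0.0, s], [0.0, 1.0, 0.0], [-s, 0.0, c]])

    return rz(f) @ ry(t) @ rz(p)


def _shifted_fft3(vol: np.ndarray) -> np.ndarray:
    return np.fft.fftshift(np.fft.fftn(np.fft.ifftshift(vol)))


def _image_from_slice(s: np.ndarray) -> np.ndarray:
    return np.fft.fftshift(np.fft.ifft2(np.fft.ifftshift(s))).real


def _slice_freq_coords(n: int) -> np.ndarray:
    """Integer frequency coordinates (kx, ky, 0) of an n x n shifted FFT grid.

    Returns an array of shape (n*n, 3) ordered like the raveled [ky, kx] grid.
    """
    k = np.arange(n) - n // 2
    ky, kx = np.meshgrid(k, k, indexing="ij")
    return np.column_stack([kx.ravel(), ky.ravel(), np.zeros(n * n)])


def trilinear_sample(f: np.ndarray, pts_zyx: np.ndarray) -> np.ndarray:
    """Sample complex 3D array at fractional [z, y, x] coordinates (0 outside)."""
    from scipy import ndimage

    coords = np.ascontiguousarray(pts_zyx.T)
    re = ndimage.map_coordinates(f.real, coords, order=1, mode="constant", cval=0.0)
    im = ndimage.map_coordinates(f.imag, coords, order=1, mode="constant", cval=0.0)
    return re + 1j * im


def trilinear_insert(acc: np.ndarray, pts_zyx: np.ndarray, values: np.ndarray) -> None:
    """Spread values into a 3D accumulator at fractional [z, y, x] coordinates."""
    n = acc.shape[0]
    p0 = np.floor(pts_zyx).astype(np.int64)
    d = pts_zyx - p0
    flat = acc.ravel()
    for dz in (0, 1):
        for dy in (0, 1):
            for dx in (0, 1):
                idx = p0 + np.array([dz, dy, dx])
                w = (np.where(dz, d[:, 0], 1 - d[:, 0])
                     * np.where(dy, d[:, 1], 1 - d[:, 1])
                     * np.where(dx, d[:, 2], 1 - d[:, 2]))
                ok = ((idx >= 0) & (idx < n)).all(axis=1) & (w > 0)
                if ok.any():
                    lin = (idx[ok, 0] * n + idx[ok, 1]) * n + idx[ok, 2]
                    np.add.at(flat, lin, w[ok] * values[ok])


class FourierProjector:
    """Projects a cubic volume along arbitrary view directions via central slices."""

    def __init__(self, volume: np.ndarray):
        volume = np.asarray(volume, dtype=np.float64)
        if volume.ndim != 3 or len(set(volume.shape)) != 1 or volume.shape[0] % 2:
            raise ValueError("volume must be cubic with even edge length")
        self.n = volume.shape[0]
        self.f3 = _shifted_fft3(volume)
        self._kxy0 = _slice_freq_coords(self.n)

    def slice_for(self, rot_matrix: np.ndarray) -> np.ndarray:
        """Complex central slice (shifted layout) for one orientation."""
        n = self.n
        q = self._kxy0 @ rot_matrix  # rows q_i = R^T k_i, in (x, y, z) order
        pts = q[:, ::-1] + n // 2    # to [z, y, x] index space
        s = trilinear_sample(self.f3, pts)
        return s.reshape(n, n)

    def slices_for(self, rot_matrices: np.ndarray) -> np.ndarray:
        """Central slices for a batch of orientations, shape (m, n, n)."""
        n, m = self.n, len(rot_matrices)
        # batch all sample points through one trilinear pass
        q = np.einsum("kd,mde->mke", self._kxy0, np.asarray(rot_matrices))
        pts = q.reshape(-1, 3)[:, ::-1] + n // 2
        s = trilinear_sample(self.f3, pts)
        return s.reshape(m, n, n)

    def sample_slices(self, rot_matrices: np.ndarray,
                      point_mask: np.ndarray | None = None) -> np.ndarray:
        """Central-slice samples at a masked subset of 2D frequency points.

        ``point_mask`` is a boolean array over the raveled [ky, kx] grid;
        returns shape (m, mask.sum()). Used for low-passed alignment scoring.
        """
        n = self.n
        kxy = self._kxy0 if point_mask is None else self._kxy0[point_mask]
        q = np.einsum("kd,mde->mke", kxy, np.asarray(rot_matrices))
        pts = q.reshape(-1, 3)[:, ::-1] + n // 2
        s = trilinear_sample(self.f3, pts)
        return s.reshape(len(rot_matrices), -1)

    def project(self, theta: float, phi: float, psi: float) -> np.ndarray:
        """Real-space projection image for one ZYZ orientation."""
        return _image_from_slice(self.slice_for(rotation_matrix_zyz(theta, phi, psi)))


def backproject_slices(images: np.ndarray, rot_matrices: np.ndarray,
                       ctf_images: np.ndarray | None = None,
                       shifts: np.ndarray | None = None,
                       reg: float = 1e-3) -> np.ndarray:
    """Direct Fourier inversion of projection images with CTF^2 weighting.

    Each image's 2D transform (times its CTF) is inserted as a central slice
    at ``R^T (kx, ky, 0)``; the accumulated transform is divided by the
    accumulated CTF^2 weight (Wiener-style, regularized by ``reg`` times the
    mean weight so that duplicating the input stack leaves the result fixed).
    ``shifts`` are per-image (dx, dy) particle offsets in pixels, removed by
    a phase ramp before insertion.
    """
    images = np.asarray(images, dtype=np.float64)
    m, n, _ = images.shape
    kxy0 = _slice_freq_coords(n)
    num = np.zeros((n, n, n), dtype=np.complex128)
    den = np.zeros((n, n, n), dtype=np.float64)
    kk = np.arange(n) - n // 2
    in_sphere = (kxy0[:, 0] ** 2 + kxy0[:, 1] ** 2) <= (n // 2 - 1) ** 2
    for i in range(m):
        s = np.fft.fftshift(np.fft.fft2(np.fft.ifftshift(images[i])))
        if shifts is not None and (shifts[i] != 0).any():
            dx, dy = shifts[i]
            ramp = np.exp(2j * np.pi * (kk[None, :] * dx + kk[:, None] * dy) / n)
            s = s * ramp
        c = np.ones((n, n)) if ctf_images is None else np.asarray(ctf_images[i], dtype=np.float64)
        q = kxy0 @ np.asarray(rot_matrices[i])
        pts = q[:, ::-1] + n // 2
        vals = (s * c).ravel()
        wts = (c * c).ravel()
        trilinear_insert(num, pts[in_sphere], vals[in_sphere])
        trilinear_insert(den, pts[in_sphere], wts[in_sphere])
    lam = reg * den[den > 0].mean() if (den > 0).any() else reg
    f3 = num / (den + lam)
    vol = np.fft.fftshift(np.fft.ifftn(np.fft.ifftshift(f3))).real
    return vol


def rotate_about_z(vol: np.ndarray, angle_deg: float) -> np.ndarray:
    """Rotate a [z, y, x] volume about the z axis through the (n//2) voxel.

    The map origin convention puts the object center on the n//2 voxel, not
    at the (n-1)/2 array midpoint scipy's rotate uses; a half-voxel center
    error translates rotated copies and corrupts symmetry scores.
    """
    from scipy import ndimage

    a = np.deg2rad(angle_deg)
    c, s = np.cos(a), np.sin(a)
    mat = np.array([[1.0, 0.0, 0.0], [0.0, c, s], [0.0, -s, c]])
    center = np.array(vol.shape) // 2
    offset = center - mat @ center
    return ndimage.affine_transform(vol, mat, offset=offset, order=1,
                                    mode="constant", cval=0.0)


def symmetrize_z(vol: np.ndarray, n_fold: int) -> np.ndarray:
    """Average a volume over the n rotations of Cn about the z axis (real space)."""
    if n_fold < 1:
        raise ValueError("symmetry order must be >= 1")
    if n_fold == 1:
        return np.asarray(vol, dtype=np.float64).copy()
    out = np.zeros_like(vol, dtype=np.float64)
    for k in range(n_fold):
        angle = 360.0 * k / n_fold
        if angle == 0:
            out += vol
        else:
            out += rotate_about_z(vol, angle)
    return out / n_fold
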