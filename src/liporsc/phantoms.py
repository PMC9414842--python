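"""Synthetic reference objects: a tetrameric channel density phantom and a
synthetic coordinate model of a C2-distorted tetramer.

Both objects are *synthetic stand-ins* built from simple geometric rules. The
density phantom emulates the overall architecture of a 6TM tetrameric channel
(a transmembrane bundle over an intracellular gating ring, four-fold subunit
placement); the coordinate model emulates a tetramer whose two opposing
subunits are displaced, breaking C4 down to C2. They exist so that every
pipeline stage and every geometric measurement can be exercised without
downloading deposited maps or models.
"""

from __future__ import annotations

import numpy as np

from .fourier import symmetrize_z

# Per-subunit Gaussian blobs: (radial offset A, tangential offset A,
# z offset A, sigma A, amplitude scale). Feature widths are helix-scale
# (sigma 5-6 A) so that Angstrom-level subunit displacements register in
# rotational-correlation scores the way they would in an experimental map.
_SUBUNIT_BLOBS = [
    (20.0, -4.0, 24.0, 6.0, 1.0),   # transmembrane helix bundle, lower
    (21.0, 4.0, 35.0, 6.0, 0.9),    # transmembrane helix bundle, upper
    (22.0, 0.0, 8.0, 5.0, 0.8),     # membrane-to-ring linker
    (23.0, -5.0, -8.0, 6.0, 1.0),   # RCK1 lobe of the gating ring
    (27.0, 4.0, -11.0, 5.0, 0.8),   # RCK1 outer helix
    (26.0, -4.0, -28.0, 6.0, 1.0),  # RCK2 lobe of the gating ring
    (30.0, 4.0, -30.0, 5.0, 0.8),   # RCK2 outer helix
    (34.0, 0.0, -12.0, 5.0, 0.7),   # shoulder helix at the subunit rim
]
_AXIAL_BLOBS = [
    (0.0, 30.0, 7.0, 0.6),     # pore region
    (0.0, -18.0, 8.0, 0.4),    # gating-ring vestibule
]


def _add_gaussian_blob(vol: np.ndarray, pixel_size: float, center_a: np.ndarray,
                       sigma_a: float, amp: float) -> None:
    n = vol.shape[0]
    c = np.asarray(center_a) / pixel_size + n // 2   # (x, y, z) in voxels
    sig = sigma_a / pixel_size
    lo = np.maximum(np.floor(c - 4 * sig).astype(int), 0)
    hi = np.minimum(np.ceil(c + 4 * sig).astype(int) + 1, n)
    if (hi <= lo).any():
        return
    zz = np.arange(lo[2], hi[2])[:, None, None] - c[2]
    yy = np.arange(lo[1], hi[1])[None, :, None] - c[1]
    xx = np.arange(lo[0], hi[0])[None, None, :] - c[0]
    vol[lo[2]:hi[2], lo[1]:hi[1], lo[0]:hi[0]] += amp * np.exp(
        -(zz ** 2 + yy ** 2 + xx ** 2) / (2 * sig ** 2))


def make_channel_phantom(box: int = 64, pixel_size: float = 4.2,
                         c2_shift_a: float = 0.0, amplitude: float = 0.0045,
                         symmetrize: bool = False) -> np.ndarray:
    """Tetrameric channel density phantom on a cubic [z, y, x] grid.

    Parameters
    ----------
    c2_shift_a:
        Axial displacement (A) applied to two opposing subunits. 0 gives an
        exactly four-fold arrangement; ~5 A emulates a C2-broken tetramer in
        which two opposing subunits sit lower than the other two.
    amplitude:
        Peak density in projected-contrast units per A of path length.
    symmetrize:
        If True, explicitly C4-average the result (only meaningful when
        ``c2_shift_a == 0``).
    """
    vol = np.zeros((box, box, box), dtype=np.float64)
    for i in range(4):
        ang = np.deg2rad(90.0 * i)
        u = np.array([np.cos(ang), np.sin(ang), 0.0])
        v = np.array([-np.sin(ang), np.cos(ang), 0.0])
        dz = c2_shift_a * (-0.5 if i % 2 == 0 else 0.5)
        for r_off, t_off, z_off, sig, rel in _SUBUNIT_BLOBS:
            center = r_off * u + t_off * v + np.array([0.0, 0.0, z_off + dz])
            _add_gaussian_blob(vol, pixel_size, center, sig, rel * amplitude)
    for r_off, z_off, sig, rel in _AXIAL_BLOBS:
        _add_gaussian_blob(vol, pixel_size, np.array([r_off, 0.0, z_off]), sig, rel * amplitude)
    if symmetrize:
        vol = symmetrize_z(vol, 4)
    return vol


def make_asymmetric_phantom(box: int = 64, pixel_size: float = 4.2,
                            n_blobs: int = 12, amplitude: float = 0.003,
                            seed: int = 0) -> np.ndarray:
    """Feature-rich phantom with no rotational symmetry.

    Random Gaussian blobs inside a 40 A sphere. Used wherever an orientation
    must be uniquely determined (a symmetric reference leaves the spin angle
    defined only modulo the symmetry order).
    """
    rng = np.random.default_rng(seed)
    vol = np.zeros((box, box, box), dtype=np.float64)
    for _ in range(n_blobs):
        d = rng.normal(size=3)
        d *= rng.uniform(0, 40.0) / np.linalg.norm(d)
        _add_gaussian_blob(vol, pixel_size, d[[0, 1, 2]], rng.uniform(5.0, 10.0),
                           amplitude * rng.uniform(0.5, 1.0))
    return vol


def make_synthetic_tetramer(diagonal_delta_a: float = 2.7,
                            segment_shift_a: float = 0.0,
                            ring_radius_a: float = 22.0,
                            key_residue: int = 785,
                            segment_range: tuple[int, int] = (700, 710)):
    """Synthetic C2-distorted tetramer coordinate model (gemmi Structure).

    A stand-in for a deposited channel model: four chains (A-D) each carry a
    short poly-alanine helix plus a valine at ``key_residue`` marking the ring
    of central-opening residues. Opposing chains A/C sit on one diagonal and
    B/D on the other; the two diagonals differ by ``diagonal_delta_a`` so that
    the opposing-subunit distance measured at ``key_residue`` differs by
    exactly that amount. ``segment_shift_a`` additionally drops the
    ``segment_range`` "shoulder" segment of chains A/C axially, emulating the
    high/low subunit displacement of a C2 tetramer.

    The geometry here is constructed, not experimental; it is used to exercise
    and cross-check measurement code, never as evidence about a real channel.
    """
    import gemmi

    st = gemmi.Structure()
    st.name = "synthetic_c2_tetramer"
    model = gemmi.Model("1")
    r_long = ring_radius_a + diagonal_delta_a / 4.0
    r_short = ring_radius_a - diagonal_delta_a / 4.0
    for i, ch_name in enumerate(["A", "B", "C", "D"]):
        ang = np.deg2rad(90.0 * i)
        radius = r_long if i % 2 == 0 else r_short
        u = np.array([np.cos(ang), np.sin(ang), 0.0])      # outward radial unit
        v = np.array([-np.sin(ang), np.cos(ang), 0.0])     # tangential unit
        dz_seg = -segment_shift_a if i % 2 == 0 else 0.0
        chain = gemmi.Chain(ch_name)

        def add_res(name: str, seqid: int, pos: np.ndarray, atoms):
            res = gemmi.Residue()
            res.name = name
            res.seqid = gemmi.SeqId(seqid, " ")
            for aname, offset in atoms:
                at = gemmi.Atom()
                at.name = aname
                at.element = gemmi.Element(aname[0])
                p = pos + np.asarray(offset)
                at.pos = gemmi.Position(*p)
                at.occ = 1.0
                at.b_iso = 20.0
                res.add_atom(at)
            chain.add_residue(res)

        # helical "shoulder" segment, 1.5 A rise per residue along z
        first, last = segment_range
        for k, seq in enumerate(range(first, last + 1)):
            helix_pos = (radius + 8.0) * u + 3.0 * v * np.sin(k * 1.7) \
                + np.array([0.0, 0.0, -20.0 + 1.5 * k + dz_seg])
            add_res("ALA", seq, helix_pos, [("CA", (0, 0, 0)), ("CB", tuple(1.5 * u))])
        # ring-marking valine at the central opening
        add_res("VAL", key_residue, radius * u + np.array([0.0, 0.0, -5.0]),
                [("CA", (0, 0, 0)), ("CB", tuple(1.5 * u))])
        model.add_chain(chain)
    st.add_model(model)
    st.setup_entities()
    return st
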