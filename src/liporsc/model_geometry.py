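"""Geometric measurements on tetrameric channel coordinate models.

Operations a structural biologist uses when comparing a C2-distorted tetramer
with C4 references: opposing-subunit diagonal distances at a marker residue
(e.g. the Ca of V785 ringing the central opening of a BK gating ring), rigid
superposition of selections, rotation of one domain relative to another about
a chosen axis, and displacement of a segment (e.g. a shoulder helix) between
two structures.

Models are read with gemmi (PDB or mmCIF); selections use the string syntax
``"chain:resno[-resno][:atom]"``, e.g. ``"A:700-710:CA"`` or ``"*:785"``
(all chains, Ca by default).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass
class Superposition:
    """Optimal rigid-body least-squares superposition (Kabsch)."""

    rotation: np.ndarray      # 3x3, det +1
    translation: np.ndarray   # applied after rotation
    rmsd: float
    n_atoms: int

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return coords @ self.rotation.T + self.translation


class ChannelModel:
    """Parsed coordinate model with selection helpers (wraps a gemmi Structure)."""

    def __init__(self, structure):
        self.structure = structure

    @classmethod
    def from_file(cls, path: str) -> "ChannelModel":
        import gemmi

        return cls(gemmi.read_structure(str(path)))

    @property
    def chain_names(self) -> list[str]:
        return [ch.name for ch in self.structure[0]]

    def atom_coord(self, chain: str, resno: int, atom: str = "CA") -> np.ndarray:
        for ch in self.structure[0]:
            if ch.name != chain:
                continue
            for res in ch:
                if res.seqid.num == resno:
                    for at in res:
                        if at.name == atom:
                            p = at.pos
                            return np.array([p.x, p.y, p.z])
        raise KeyError(f"atom {chain}:{resno}:{atom} not found")

    def select(self, selection: str) -> np.ndarray:
        """Coordinates for a ``chain:resno[-resno][:atom]`` selection string.

        ``chain`` may be ``*`` (all chains) or a comma list; atoms default to
        Ca. Rows are ordered by (chain, residue number).
        """
        parts = selection.split(":")
        if len(parts) < 2:
            raise ValueError(f"bad selection {selection!r}")
        chains, rng = parts[0], parts[1]
        atom = parts[2] if len(parts) > 2 else "CA"
        if "-" in rng:
            lo, hi = (int(v) for v in rng.split("-"))
        else:
            lo = hi = int(rng)
        wanted = None if chains == "*" else set(chains.split(","))
        coords = []
        for ch in self.structure[0]:
            if wanted is not None and ch.name not in wanted:
                continue
            for res in ch:
                if lo <= res.seqid.num <= hi:
                    for at in res:
                        if at.name == atom:
                            coords.append([at.pos.x, at.pos.y, at.pos.z])
        if not coords:
            raise ValueError(f"selection {selection!r} matched no atoms")
        return np.array(coords)

    def transformed(self, sup: Superposition) -> "ChannelModel":
        """A copy of the model with a rigid transform applied to every atom."""
        import gemmi

        st = self.structure.clone()
        mat = gemmi.Mat33(sup.rotation.tolist())
        vec = gemmi.Vec3(*sup.translation)
        st[0].transform_pos_and_adp(gemmi.Transform(mat, vec))
        return ChannelModel(st)


# ---------------------------------------------------------------------------
# Measurements
# ---------------------------------------------------------------------------

def diagonal_distances(model: ChannelModel, residue: int, atom: str = "CA"):
    """Opposing-subunit distances at a marker residue, and their difference.

    The four chains' marker atoms form a ring; the two "diagonals" are the
    chain pairing that maximizes the summed pair distances (made explicit so
    the measurement does not depend on chain naming). Returns
    ``(d1, d2, |d1 - d2|)`` with ``d1 >= d2``.
    """
    names = model.chain_names
    if len(names) != 4:
        raise ValueError(f"expected 4 chains, found {len(names)}")
    missing = []
    pts = {}
    for ch in names:
        try:
            pts[ch] = model.atom_coord(ch, residue, atom)
        except KeyError:
            missing.append(ch)
    if missing:
        raise ValueError(f"residue {residue} ({atom}) missing in chains {missing}")
    a, b, c, d = (pts[ch] for ch in names)
    pairings = [((a, b), (c, d)), ((a, c), (b, d)), ((a, d), (b, c))]
    dists = [(np.linalg.norm(p1 - p2), np.linalg.norm(q1 - q2))
             for (p1, p2), (q1, q2) in pairings]
    d1, d2 = max(dists, key=sum)
    d1, d2 = max(d1, d2), min(d1, d2)
    return float(d1), float(d2), float(abs(d1 - d2))


def superpose(coords_a: np.ndarray, coords_b: np.ndarray) -> Superposition:
    """Least-squares superposition moving B onto A (Kabsch, proper rotation)."""
    a = np.asarray(coords_a, dtype=np.float64)
    b = np.asarray(coords_b, dtype=np.float64)
    if a.shape != b.shape:
        raise ValueError("selections must match atom-for-atom")
    if len(a) < 3:
        raise ValueError("need at least 3 matched atoms")
    ca, cb = a.mean(axis=0), b.mean(axis=0)
    h = (b - cb).T @ (a - ca)
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    rot = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    trans = ca - rot @ cb
    moved = b @ rot.T + trans
    rmsd = float(np.sqrt(((moved - a) ** 2).sum(axis=1).mean()))
    return Superposition(rotation=rot, translation=trans, rmsd=rmsd, n_atoms=len(a))


def rotation_angle_about_axis(rotation: np.ndarray, axis: str = "z") -> float:
    """Signed rotation angle (deg) of the component of a rotation about an axis."""
    i = "xyz".index(axis)
    j, k = (i + 1) % 3, (i + 2) % 3
    return float(np.degrees(np.arctan2(rotation[k, j] - rotation[j, k],
                                       rotation[j, j] + rotation[k, k])))


def relative_rotation(model_a: ChannelModel, model_b: ChannelModel,
                      align_sel: str, measure_sel: str, axis: str = "z",
                      atom: str | None = None) -> float:
    """Rotation (deg) about ``axis`` carrying A's measured domain onto B's.

    B is first superposed onto A using ``align_sel``. Atom displacements of
    ``measure_sel`` are then projected onto the plane normal to the axis
    (through the selection centroid) and the amplitude-weighted mean angular
    offset is returned: with in-plane positions as complex numbers p (A) and
    q (B-aligned), the angle is ``arg(sum conj(p) q)``. Positive is
    counter-clockwise viewed down the axis; swapping A and B negates the
    result. A warning is raised when the selection is nearly axial (the
    in-plane amplitude poorly conditions the angle).
    """
    a_align = model_a.select(align_sel)
    b_align = model_b.select(align_sel)
    sup = superpose(a_align, b_align)
    pa = model_a.select(measure_sel)
    pb = sup.apply(model_b.select(measure_sel))
    i = "xyz".index(axis)
    j, k = (i + 1) % 3, (i + 2) % 3
    center = pa.mean(axis=0)
    p = (pa[:, j] - center[j]) + 1j * (pa[:, k] - center[k])
    q = (pb[:, j] - center[j]) + 1j * (pb[:, k] - center[k])
    amp = np.abs(p).mean()
    spread = np.abs(pa[:, i] - pa[:, i].mean()).mean()
    if amp < 1.0 or amp < 0.1 * max(spread, 1.0):
        import warnings

        warnings.warn(f"near-axial measure selection (in-plane amplitude {amp:.2f} A): "
                      "rotation angle poorly conditioned", stacklevel=2)
    return float(np.degrees(np.angle(np.sum(np.conj(p) * q))))


def segment_displacement(model_a: ChannelModel, model_b: ChannelModel,
                         align_sel: str, segment_sel: str) -> float:
    """Distance (A) between segment Ca centroids after align_sel superposition."""
    sup = superpose(model_a.select(align_sel), model_b.select(align_sel))
    ca = model_a.select(segment_sel).mean(axis=0)
    cb = sup.apply(model_b.select(segment_sel)).mean(axis=0)
    return float(np.linalg.norm(ca - cb))
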