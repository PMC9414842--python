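"""MRC2014 and STAR file I/O (gemmi-backed) for maps, micrographs and tables.

Maps and micrographs are written as MRC2014 mode 2 (32-bit float) with the
pixel size carried in the cell header; micrographs are stored as nz = 1
volumes. Tables (picks, fits, ground truth) round-trip through single-block
STAR loops with pandas DataFrames in memory.
"""

from __future__ import annotations

import numpy as np
import pandas as pd


def write_mrc(path, data: np.ndarray, pixel_size: float) -> None:
    """Write a 2D image or 3D volume as an MRC2014 mode-2 map."""
    import gemmi

    arr = np.asarray(data, dtype=np.float32)
    if arr.ndim == 2:
        arr = arr[None, :, :]
    if arr.ndim != 3:
        raise ValueError("data must be 2D or 3D")
    nz, ny, nx = arr.shape
    grid = gemmi.FloatGrid(nx, ny, nz)
    view = np.array(grid, copy=False)
    view[:] = arr.T  # gemmi grid is (x, y, z) with x fastest
    grid.set_unit_cell(gemmi.UnitCell(nx * pixel_size, ny * pixel_size,
                                      nz * pixel_size, 90, 90, 90))
    m = gemmi.Ccp4Map()
    m.grid = grid
    m.update_ccp4_header()
    m.write_ccp4_map(str(path))


def read_mrc(path):
    """Read an MRC/CCP4 map; returns ``(data, pixel_size)``.

    3D data comes back as [z, y, x]; single-section files as a 2D image.
    Raises ``ValueError`` on unreadable or truncated files.
    """
    import gemmi

    try:
        m = gemmi.read_ccp4_map(str(path))
    except (RuntimeError, OSError) as exc:
        raise ValueError(f"cannot read MRC file {path}: {exc}") from exc
    arr = np.array(m.grid, copy=True).T.astype(np.float32)  # to [z, y, x]
    nx = m.grid.nu
    pixel = m.grid.unit_cell.a / nx if nx else 1.0
    if arr.shape[0] == 1:
        return arr[0], float(pixel)
    return arr, float(pixel)


def write_star(path, table: pd.DataFrame, block_name: str = "particles",
               prefix: str = "_lrsc") -> None:
    """Write a DataFrame as a single-block STAR loop.

    Floats are written with 6 significant digits or better; column names
    become ``{prefix}{Name}`` tags.
    """
    from gemmi import cif

    if len(table) == 0:
        # gemmi drops row-less loops; write the header explicitly
        lines = [f"data_{block_name}", "loop_"]
        lines += [f"{prefix}{c}" for c in table.columns]
        with open(path, "w") as fh:
            fh.write("\n".join(lines) + "\n")
        return
    doc = cif.Document()
    blk = doc.add_new_block(block_name)
    loop = blk.init_loop(prefix, list(table.columns))
    for _, row in table.iterrows():
        cells = []
        for v in row:
            if isinstance(v, (float, np.floating)):
                cells.append(f"{v:.8g}")
            else:
                cells.append(str(v))
        loop.add_row(cells)
    with open(path, "w") as fh:
        fh.write(doc.as_string())


def read_star(path, required: list[str] | None = None,
              prefix: str = "_lrsc") -> pd.DataFrame:
    """Read a single-block STAR loop into a DataFrame (numeric where possible)."""
    from gemmi import cif

    doc = cif.read_file(str(path))
    blk = doc.sole_block()
    cols: dict[str, list[str]] = {}
    for item in blk:
        if item.loop is not None:
            loop = item.loop
            w = loop.width()
            vals = list(loop.values)
            for i, tag in enumerate(loop.tags):
                name = tag[len(prefix):] if tag.startswith(prefix) else tag.lstrip("_")
                cols[name] = vals[i::w] if w else []
            break
    df = pd.DataFrame(cols)
    for c in df.columns:
        converted = pd.to_numeric(df[c], errors="coerce")
        if not converted.isna().any():
            df[c] = converted
    if required:
        missing = [c for c in required if c not in df.columns]
        if missing:
            raise ValueError(f"STAR file {path} missing required columns: {missing}")
    return df


# ---------------------------------------------------------------------------
# Table <-> object helpers
# ---------------------------------------------------------------------------

def fits_to_table(fits, pixel_size: float) -> pd.DataFrame:
    return pd.DataFrame({
        "CenterXPx": [f.center[0] / pixel_size for f in fits],
        "CenterYPx": [f.center[1] / pixel_size for f in fits],
        "RadiusA": [f.radius for f in fits],
        "Amplitude": [f.amplitude for f in fits],
        "Background": [f.background for f in fits],
        "ResidualRms": [f.residual_rms for f in fits],
        "Converged": [int(f.converged) for f in fits],
    })


def table_to_fits(df: pd.DataFrame, pixel_size: float):
    from .liposome_model import LiposomeFit

    return [LiposomeFit(center=(r.CenterXPx * pixel_size, r.CenterYPx * pixel_size),
                        radius=r.RadiusA, amplitude=r.Amplitude,
                        background=r.Background, residual_rms=r.ResidualRms,
                        converged=bool(r.Converged))
            for r in df.itertuples()]


def picks_to_table(picks) -> pd.DataFrame:
    return pd.DataFrame({
        "CoordinateXPx": [p.position[0] for p in picks],
        "CoordinateYPx": [p.position[1] for p in picks],
        "Score": [p.score for p in picks],
        "MicrographId": [p.micrograph_id for p in picks],
        "NearestLiposomeId": [p.nearest_liposome for p in picks],
        "MembraneDistanceA": [p.membrane_distance for p in picks],
        "Kept": [int(p.kept) for p in picks],
    })


def table_to_picks(df: pd.DataFrame):
    from .particle_ops import ParticlePick

    return [ParticlePick(position=(r.CoordinateXPx, r.CoordinateYPx), score=r.Score,
                         micrograph_id=int(r.MicrographId),
                         nearest_liposome=int(r.NearestLiposomeId),
                         membrane_distance=r.MembraneDistanceA, kept=bool(r.Kept))
            for r in df.itertuples()]


def fsc_to_table(curve) -> pd.DataFrame:
    return pd.DataFrame({"Frequency1PerA": curve.frequency, "Fsc": curve.fsc})
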