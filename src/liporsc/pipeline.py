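"""End-to-end pipeline driver: simulate -> fit -> subtract -> pick -> screen ->
extract -> priors -> reconstruct (C1/C2/C4) -> FSC -> symmetry report.

Every stage consumes the previous stage's outputs; nothing mutates its
inputs. All randomness derives from one root seed via numpy SeedSequence
spawning, so a config reproduces its run bit-for-bit. Outputs (MRC maps, STAR
tables, FSC tables, a JSON report) are written to a run directory together
with the config and its hash.

The default configuration is a desk-scale run: a handful of ~0.05 um^2
micrographs at 2.1 A/px rather than thousands of Krios micrographs, with
reconstruction at 2x binning. Sizes are configurable; the statistical
structure (liposome size distribution, occupancy, dose, defocus) follows the
simulator defaults.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from . import formats
from .liposome_model import fit_micrograph, subtract_liposomes
from .map_metrics import compare_maps, symmetry_correlation
from .particle_ops import extract_boxes, make_templates, pick_particles, \
    screen_particles, ParticleStack
from .phantoms import make_channel_phantom
from .rsc_reconstruct import DensityMap, assign_orientations, compute_fsc, \
    orientation_prior, reconstruct_halves, refine_orientations
from .sim_micrograph import CTFParams, sample_dataset
from .util import bin_image, soft_spherical_mask

DEFAULT_STRATA_NM = ((15.0, 19.0), (19.0, 25.0), (25.0, 70.0))


@dataclass
class PipelineConfig:
    """All stage parameters with desk-scale defaults; JSON round-trippable."""

    seed: int = 0
    n_micrographs: int = 16
    micrograph_shape: tuple[int, int] = (768, 768)
    pixel_size_a: float = 2.1
    mean_diameter_nm: float = 20.0
    diameter_support_nm: tuple[float, float] = (15.0, 70.0)
    liposomes_per_micrograph: int = 6
    dose_e_per_a2: float = 60.0
    defocus_um: float = 3.8
    c2_shift_a: float = 0.0             # phantom symmetry breaking
    detect_radius_range_a: tuple[float, float] = (75.0, 350.0)
    pick_threshold: float = 0.2
    pick_rotations: int = 8
    n_templates: int = 10
    screen_cutoff_a: float = 80.0
    box_nm: float = 27.0
    mask_nm: float = 17.0
    recon_bin: int = 2
    azimuth_step_deg: float = 5.0
    tilt_width_deg: float = 10.0
    inplane_width_deg: float = 10.0
    pick_sigma_a: float = 6.0       # pick-position uncertainty broadening priors
    select_fraction: float = 0.85   # keep this score quantile for reconstruction
    refine_pass: bool = False       # optional second-pass local angle polish
    symmetries: tuple[int, ...] = (1, 2, 4)
    strata_nm: tuple = DEFAULT_STRATA_NM

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "PipelineConfig":
        raw = json.loads(text)
        cfg = cls(**raw)
        # tuples round-trip as lists; normalize so equality holds
        for f in dataclasses.fields(cls):
            v = getattr(cfg, f.name)
            if isinstance(v, list):
                setattr(cfg, f.name, tuple(tuple(x) if isinstance(x, list) else x
                                           for x in v))
        return cfg

    @property
    def config_hash(self) -> str:
        return hashlib.sha256(self.to_json().encode()).hexdigest()[:16]


def run_pipeline(config: PipelineConfig, out_dir: str | Path) -> dict:
    """Execute the full pipeline; returns a results dict (also written as JSON)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "config.json").write_text(config.to_json())
    log: list[str] = []

    def stage(msg):
        log.append(f"[{time.strftime('%H:%M:%S')}] {msg}")

    px = config.pixel_size_a
    box_px = int(round(config.box_nm * 10 / px))
    box_px -= box_px % (2 * config.recon_bin)
    box_bin = box_px // config.recon_bin
    px_bin = px * config.recon_bin

    # ground-truth particle volume and the binned reference used downstream
    phantom = make_channel_phantom(box=box_px, pixel_size=px,
                                   c2_shift_a=config.c2_shift_a)
    phantom_bin = make_channel_phantom(box=box_bin, pixel_size=px_bin,
                                       c2_shift_a=config.c2_shift_a)
    reference = DensityMap(data=phantom_bin, pixel_size=px_bin)

    stage(f"simulate {config.n_micrographs} micrographs (seed {config.seed})")
    mics = sample_dataset(config.n_micrographs, seed=config.seed,
                          grid_shape=tuple(config.micrograph_shape), pixel_size=px,
                          mean_diameter_nm=config.mean_diameter_nm,
                          support_nm=tuple(config.diameter_support_nm),
                          liposomes_per_micrograph=config.liposomes_per_micrograph,
                          dose=config.dose_e_per_a2,
                          defocus_range_um=(config.defocus_um, config.defocus_um),
                          particle_volume=phantom)
    ctf = mics[0].ctf
    templates = make_templates(phantom, n_templates=config.n_templates, pixel_size=px,
                               ctf=ctf, crop_px=box_px * 3 // 8)

    all_picks, all_fits, stacks, priors = [], [], [], []
    n_true = 0
    for mid, mic in enumerate(mics):
        n_true += len(mic.particles)
        fits = fit_micrograph(mic, ctf=ctf, radius_range=config.detect_radius_range_a)
        subtracted, _ = subtract_liposomes(mic, fits, ctf=ctf)
        picks = pick_particles(subtracted, templates, threshold=config.pick_threshold,
                               n_rotations=config.pick_rotations, micrograph_id=mid)
        kept = screen_particles(picks, fits, px, cutoff=config.screen_cutoff_a) \
            if fits else []
        stack = extract_boxes(subtracted, kept, pixel_size=px,
                              box_nm=config.box_nm, mask_nm=config.mask_nm)
        for p in stack.picks:
            priors.append((orientation_prior(p, fits[p.nearest_liposome], px,
                                             tilt_width=config.tilt_width_deg,
                                             inplane_width=config.inplane_width_deg,
                                             position_sigma_a=config.pick_sigma_a),
                           fits[p.nearest_liposome].radius))
        stacks.append(stack)
        all_picks.extend(stack.picks)
        all_fits.append(fits)
        stage(f"micrograph {mid}: {len(fits)} liposomes, {len(picks)} picks, "
              f"{len(kept)} kept, {stack.images.shape[0]} extracted")

    images = np.concatenate([s.images for s in stacks if s.images.size]) \
        if any(s.images.size for s in stacks) else np.zeros((0, box_px, box_px))
    images_bin = np.array([bin_image(im, config.recon_bin) for im in images]) \
        if images.size else np.zeros((0, box_bin, box_bin))
    stack_all = ParticleStack(images=images_bin, pixel_size=px_bin,
                              box_nm=config.box_nm, mask_nm=config.mask_nm,
                              picks=all_picks)
    formats.write_star(out / "picks.star", formats.picks_to_table(all_picks))
    formats.write_star(out / "fits.star",
                       formats.fits_to_table([f for fl in all_fits for f in fl], px))

    stage(f"assign orientations for {len(all_picks)} particles")
    ctf_bin = CTFParams(defocus_um=ctf.defocus_um, voltage_kv=ctf.voltage_kv,
                        cs_mm=ctf.cs_mm, amplitude_contrast=ctf.amplitude_contrast,
                        pixel_size_a=px_bin)
    prior_list = [p for p, _ in priors]
    orientations = assign_orientations(stack_all, prior_list, reference, ctf=ctf_bin,
                                       azimuth_step=config.azimuth_step_deg,
                                       max_shift_px=8.0)
    if config.refine_pass:
        stage("local orientation refinement")
        orientations = refine_orientations(stack_all, orientations, reference,
                                           ctf=ctf_bin, max_shift_px=8.0)

    # selection: drop both the worst-matching particles and those whose
    # near/far hemisphere decision is unconfident (stands in for the
    # classification-based particle selection of a full workflow)
    scores = np.array([o.score for o in orientations])
    margins = np.array([o.side_margin for o in orientations])
    if len(scores) and config.select_fraction < 1.0:
        q = 1.0 - config.select_fraction
        keep = (scores >= np.quantile(scores, q)) \
            & (margins >= np.quantile(margins[np.isfinite(margins)], q))
        selected = np.where(keep)[0]
    else:
        selected = np.arange(len(scores))
    stack_sel = ParticleStack(images=images_bin[selected], pixel_size=px_bin,
                              box_nm=config.box_nm, mask_nm=config.mask_nm)
    ori_sel = [orientations[i] for i in selected]
    stage(f"selected {len(selected)}/{len(scores)} particles by score")

    results = {"config_hash": config.config_hash, "n_true_particles": n_true,
               "n_picked": len(all_picks), "n_selected": int(len(selected)),
               "maps": {}, "fsc": {}, "symmetry": {}, "strata": {}}
    maps = {}
    for sym in config.symmetries:
        full, h1, h2 = reconstruct_halves(stack_sel, ori_sel, ctf=ctf_bin,
                                          symmetry=sym, seed=config.seed)
        curve = compute_fsc(h1, h2)
        maps[sym] = full
        formats.write_mrc(out / f"map_c{sym}.mrc", full.data, px_bin)
        formats.write_star(out / f"fsc_c{sym}.star", formats.fsc_to_table(curve),
                           block_name="fsc")
        results["maps"][f"C{sym}"] = str(out / f"map_c{sym}.mrc")
        results["fsc"][f"C{sym}"] = {"resolution_a": curve.resolution_a,
                                     "threshold": curve.threshold}
        stage(f"C{sym}: FSC 0.143 resolution {curve.resolution_a:.2f} A")

    base_map = maps.get(1, next(iter(maps.values())))
    for order in (2, 4):
        rep = symmetry_correlation(base_map, order, mask_radius_a=60.0)
        results["symmetry"][f"C{order}"] = rep.correlation
    mask = soft_spherical_mask(box_bin, 60.0 / px_bin)
    results["phantom_correlation"] = {
        f"C{sym}": compare_maps(maps[sym],
                                DensityMap(data=phantom_bin, pixel_size=px_bin),
                                mask=mask)[0]
        for sym in maps}

    # size-stratified reconstructions share the assignment; particles are
    # split by their owning liposome's fitted diameter
    sel_set = set(int(i) for i in selected)
    strata_members = {i: [] for i in range(len(config.strata_nm))}
    for idx, (_, radius_a) in enumerate(priors):
        if idx not in sel_set:
            continue
        d_nm = 2 * radius_a / 10.0
        for si, (lo, hi) in enumerate(config.strata_nm):
            if lo <= d_nm < hi:
                strata_members[si].append(idx)
                break
    strata_maps = {}
    for si, members in strata_members.items():
        if len(members) < 8:
            continue
        sub = ParticleStack(images=images_bin[members], pixel_size=px_bin,
                            box_nm=config.box_nm, mask_nm=config.mask_nm)
        sub_ori = [orientations[i] for i in members]
        m, _, _ = reconstruct_halves(sub, sub_ori, ctf=ctf_bin, symmetry=1,
                                     seed=config.seed)
        strata_maps[si] = m
        results["strata"][f"stratum_{si}"] = {"n_particles": len(members),
                                              "range_nm": list(config.strata_nm[si])}
    pairs = sorted(strata_maps)
    for i in range(len(pairs)):
        for j in range(i + 1, len(pairs)):
            c, _, _ = compare_maps(strata_maps[pairs[i]], strata_maps[pairs[j]],
                                   mask=mask)
            results["strata"][f"corr_{pairs[i]}_{pairs[j]}"] = c

    (out / "report.json").write_text(json.dumps(results, indent=2, sort_keys=True))
    (out / "pipeline.log").write_text("\n".join(log) + "\n")
    return results
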