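# Methods

This note documents the models, algorithms, parameters and design choices
behind `liporsc`, a desk-scale implementation of random spherically
constrained (RSC) single-particle cryo-EM for membrane proteins
reconstituted into liposomes.

## The physical picture

A proteoliposome micrograph contains spherical vesicles of continuously
varying size with a small number of membrane-protein particles embedded in
each bilayer. Two facts drive the whole analysis:

1. **The membrane is a spherical shell.** Its image contribution is the
   line-of-sight projection of a radially symmetric density and can be
   fitted and subtracted per vesicle, leaving the protein signal.
2. **The protein sits in the membrane.** Its membrane-normal axis points
   along the sphere radius, so a particle picked at in-plane distance `r`
   from the center of a liposome of radius `R` has tilt
   `sin(tilt) = r/R`, up to the near/far-hemisphere ambiguity
   (`tilt` vs `180° − tilt`). The in-plane direction of the axis is the
   bearing from liposome center to particle; only the spin about the
   membrane normal is unconstrained. These sphere-derived priors replace
   the global orientation search of conventional single-particle analysis.

## Simulation (the generative model)

* **Bilayer profile.** A three-Gaussian parameterization: headgroup peaks
  at ±19 Å from the midplane (σ = 4 Å) and a broad acyl-chain trough at the
  midplane (σ = 9 Å). Amplitudes are in projected-contrast units per
  Ångström of path (defaults +0.003 / −0.0015), chosen so that vesicle rim
  contrast and particle contrast come out at the few-percent level typical
  of cryo-EM at a few microns of underfocus. The functional form is a
  package choice; it captures the double-ring projected appearance of
  vesicles with few parameters and decays to solvent level beyond
  ±(offset + 4σ).
* **Spherical projection.** The projection of a radially symmetric density
  `g(ρ)` is the Abel-type integral `P(r) = 2∫ g(√(r²+z²)) dz`, evaluated by
  the trapezoid rule (step 0.5 Å) on a fine radial table (pixel/4 spacing)
  and interpolated onto the pixel grid. A brute-force voxelized 3D
  projection oracle agrees to better than 1 % RMS across radii 75–350 Å.
* **Vesicle population.** Diameters follow a scaled Beta distribution on
  [15, 70] nm with mean exactly 20 nm (concentration 12, giving a
  right-skewed population with most vesicles near 20 nm). Occupancy is 1–2
  particles per 20-nm liposome, scaled by surface area for other sizes,
  with a 1-particle floor. Liposomes are placed by rejection sampling with
  non-overlap margins; particles are placed uniformly on each sphere with a
  50 Å minimum chord separation and uniform spin.
* **Optics and noise.** The standard phase/amplitude CTF
  `CTF(f) = −(√(1−w²)·sin χ + w·cos χ)` with
  `χ = πλΔz f² − (π/2)Cs λ³f⁴`, underfocus positive, `CTF(0) = −w`
  (the CTFFIND/RELION sign convention); defaults 300 kV, Cs 2.7 mm,
  w = 0.1, Δz = 3.8 µm. Shot noise is Poisson at
  `dose · pixel² · (1 + contrast)` counts per pixel with a total dose of
  60 e⁻/Å². The default simulated pixel is 2.1 Å (a 4× binning of the
  0.525 Å physical pixel) to keep desk-scale runtimes.
* **Particle phantom.** A tetrameric channel stand-in built from
  helix-scale Gaussian blobs (σ 5–6 Å per feature): a transmembrane bundle
  above an intracellular two-lobed gating ring with a rim shoulder helix,
  four-fold subunit placement. An optional axial displacement of two
  opposing subunits (default 5 Å where used) breaks C4 down to C2,
  emulating the high/low subunit arrangement of a C2 tetramer. A separate
  random-blob phantom with no symmetry is used wherever an orientation must
  be uniquely defined.

## Liposome fitting and subtraction

Because both the shell projection and the CTF are isotropic, the
CTF-convolved model image of a liposome is exactly circularly symmetric.
The model is therefore reduced to a 1D radial profile (rendered on a padded
patch, CTF-convolved there, then radially binned at quarter-pixel spacing),
which can be evaluated at arbitrary sub-pixel centers.

* **Detection** is multi-radius normalized cross-correlation against ring
  templates (8 radii spanning 75–350 Å), followed by per-candidate radius
  refinement over a fine ladder spanning the full radius range (the coarse
  max-over-radii map can lock onto the wrong ring when vesicles sit close
  together), peak non-maximum suppression, and greedy circle-overlap
  suppression. Default NCC threshold 0.12.
* **Fitting** is Nelder–Mead over (center x, center y, radius) with the
  amplitude and local background solved in closed form per iterate inside
  an annulus of ±60 Å around the membrane circle. The objective is the
  *unexplained variance fraction* (residual mean square over annulus data
  variance). Normalizing per annulus is essential: the raw residual of a
  wrong circle over plain background equals the noise variance — the same
  value a perfect fit attains — so raw least squares cannot rank circles
  covering different pixels. The highest-residual 15 % of annulus pixels
  are excluded and the linear subproblem re-solved (embedded particles are
  outliers against the membrane model). A radius sweep at the refined
  center restarts the simplex when a distinctly better objective exists
  elsewhere (guards against locking onto an inner CTF fringe). Fits pinned
  to the radius bounds are flagged non-converged and never subtracted.
* **Subtraction** removes the amplitude-scaled CTF-convolved membrane model
  only; the fitted local background belongs to the image and stays. The
  bilayer profile shape is shared across liposomes and only scaled, since
  nothing in the data model justifies per-vesicle profile refinement.

## Picking, screening, extraction

Picking is template matching on the subtracted micrographs: maximum over
10 reference projections (a tilt series from top to side view,
CTF-modulated, cropped to a 10-nm window so the NCC normalization hugs the
particle) and 8 in-plane rotations, with peak NMS. The membrane-distance
screen keeps picks within 80 Å of the nearest *fitted membrane circle*,
`|‖p − c‖ − R| ≤ 80 Å`. Distance to the circle, not to the center, is the
only reading under which a fixed cutoff is meaningful across 15–70 nm
vesicles. Boxes are 27 nm with a 17 nm soft circular mask; each box is
standardized to zero mean / unit variance over the pixels outside the mask
radius.

## Orientation assignment and reconstruction

Projections and back-projections use central Fourier slices with trilinear
interpolation; orientations are ZYZ triples `(tilt θ, bearing φ, spin ψ)`
with `R = Rz(φ)·Ry(θ)·Rz(ψ)`.

* **Priors.** Tilt center from `arcsin(r/R)` with the near/far pair, bearing
  from pick geometry, spin uniform. Base widths 10° (σ-like half-width).
  Widths are broadened by the angular uncertainty a given pick-position
  error induces (default 6 Å): the bearing of a pick near the projected
  liposome center is nearly unconstrained, the tilt of a rim pick likewise.
* **Search.** Stage 1 scores all angular candidates (spin exhaustive at 5°,
  tilt/bearing on local grids covering the prior widths, both hemispheres)
  by normalized Fourier-domain correlation restricted to the lowest 60 % of
  frequencies. Stage 2 rescores the best 24 candidates with an in-plane
  translation search (±5 px cross-correlation peak, parabolic sub-pixel
  refinement) — picking centers particles only to a few pixels, and
  unmodelled shifts would otherwise blur the map. The winning shift is
  removed by a phase ramp at insertion time.
* **Reconstruction.** Direct Fourier inversion: each image transform
  (times its CTF) is inserted as a central slice; the accumulated transform
  is divided by the accumulated CTF² (Wiener-style, regularized by 10⁻³ of
  the mean weight so duplicating the stack leaves the map fixed). Cn
  symmetry is imposed by real-space averaging over the n rotations about z.
  Rotations use the map-origin convention (object center on the `n//2`
  voxel); scipy's array-midpoint rotation center is half a voxel off, which
  translates rotated copies and corrupts symmetry scores.
* **Gold standard.** Halves by even/odd index after a seeded shuffle; FSC
  with one-voxel shells, resolution at the 0.143 crossing with linear
  interpolation. The combined map is per-shell filtered by
  `√(2·FSC/(1+FSC))`, the standard estimate of the signal fraction.
* **Selection.** The pipeline discards both the worst-scoring 15 % of
  particles and the 15 % with the smallest near/far score separation
  (particles whose hemisphere assignment the data do not resolve insert
  misoriented density), standing in for the classification-based particle
  selection of a full workflow.
* **Final map.** The workflow reconstructs C1, C2 and C4 maps; the map with
  the specimen's symmetry imposed is the workflow's end point (C4 for the
  default four-fold phantom), with the C1 map retained as the
  symmetry-free check that the imposed symmetry is real.

## Symmetry and map metrics

Rotational symmetry is scored as the masked Pearson correlation between a
map and its 360°/n rotation about z (trilinear resampling, soft spherical
mask, default radius 60 Å). On the C2 phantom (5 Å opposing-subunit
displacement) the C2 score is exactly 1 (a 180° rotation is grid-exact) and
exceeds the C4 score by ≈ 0.10.

## Coordinate-model geometry

Models are read with gemmi. Opposing-subunit pairing for the diagonal
measurement is the chain pairing maximizing summed pair distances (explicit
so chain naming never matters). Superposition is Kabsch with a proper
rotation. Relative domain rotation about an axis: after aligning on one
selection, in-plane atom positions (relative to the measured selection's
centroid) are treated as complex numbers `p` (model A) and `q` (aligned
model B) and the angle is `arg(Σ p̄q)` — the amplitude-weighted mean angular
offset, exactly antisymmetric under swapping the models, with a warning
when the selection is nearly axial. Segment displacement is the distance
between Cα centroids after alignment. Because the deposited accessions are
not redistributable with the package, the measurements are exercised on a
programmatically built *synthetic* tetramer whose constructed distortions
(2.7 Å diagonal difference, 5 Å segment shift, 12° domain rotation in
tests) make every expected value known exactly; the operations themselves
are additionally validated against brute-force computation.

## Problem sizes and runtime

The default pipeline configuration is 16 micrographs of 768² px at
2.1 Å/px with ~6 liposomes each, yielding roughly 150–200 particles —
enough for the phantom-recovery and symmetry properties to hold with
margin while a full run (simulation through three reconstructions, FSC and
symmetry reports) completes in roughly ten minutes on one CPU. Alignment
and reconstruction run at 2× binning (4.2 Å/px, 64³ grids); resolutions of
order 20 Å follow from the particle count and binning, not from the
method. Size-stratified reconstructions (15–19, 19–25, 25–70 nm) share the
single orientation assignment and differ only in which particles are
back-projected.

## What the simulations do and do not show

The generator reproduces the statistical structure the analysis relies on:
vesicle size dispersion, area-scaled occupancy, sphere-constrained particle
geometry with random spin and hemisphere, CTF modulation and dose-limited
shot noise. It does not model beam-induced motion, ice-thickness gradients,
astigmatism or higher-order aberrations, structural heterogeneity, or
protein-lipid boundary effects (the membrane model is particle-free, so
subtraction leaves particles untouched by construction — real membranes
deform around proteins). Passing tests therefore demonstrate the internal
consistency and geometric correctness of the method at realistic contrast
and dose, not performance on real micrographs.

## Numerical notes and degenerate inputs

* All grids are even-sized and pixel-centered (origin at the top-left pixel
  center; physical Å = index × pixel size); volumes are `[z, y, x]`.
* Fourier insertion/extraction skips samples outside the Nyquist sphere;
  empty stacks, non-cubic maps, mismatched grids, non-positive radii or
  doses, cutoffs < 0 and boxes larger than the field raise `ValueError`.
* A tilt prior at exactly 90° collapses the near/far pair to one member.
* All randomness flows through explicit seeds (numpy `SeedSequence`
  spawning per micrograph; derived sub-seeds stay below 2³¹); identical
  seeds reproduce identical datasets and maps bit-for-bit.
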