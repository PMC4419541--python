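# Methods

This note documents the models, conventions and numerical choices behind
the `ipet` package: a synthetic re-creation of individual-particle electron
tomography (IPET) of a flexible three-domain antibody, from phantom
simulation through per-particle reconstruction, quality scoring, rigid
domain fitting and ensemble flexibility statistics.

## The antibody phantom

An IgG-class particle is modelled as three rigid domains joined by flexible
hinge linkers:

* **Fab1, Fab2** — dumbbell-shaped domains, 60 Å outer diameter, 50 kDa
  each: two flattened ellipsoidal lobes along the domain's long axis.
* **Fc** — a ring-shaped domain, 70 Å outer diameter, 50 kDa, with an
  elliptical through-hole of 25 × 30 Å in the ring plane and a thickness of
  about 20 Å.

Each domain is a deterministic cloud of pseudo-atoms on a 4 Å lattice,
labelled with chains and residue ranges that match the geometry module's
domain definitions (Fab1 = chains A/B residues 1–226, Fab2 = C/D 1–226,
Fc = B/D 237–444, hinge linkers = B/D 221–236). The Fab residue range
overlaps the linker range on chains B and D; both definitions are applied
verbatim, so roughly 3 % of a Fab's pseudo-atoms are linker points. This
shifts Fab mass centers by ≈0.5 Å — inside the one-voxel agreement the
round-trip tests require — and is documented rather than "fixed".

In the local template frame the **direction** vector (minimum principal
inertia axis, the long axis) is x and the **normal** vector (maximum
principal inertia axis, the flat plane's normal) is z; a domain pose is a
center plus a proper rotation of that frame.

Rasterization splats pseudo-atoms trilinearly (mass-weighted) and blurs
with a 3 Å Gaussian. Default grid: 164³ voxels at 2.0 Å/pixel. A phantom
whose atoms (plus the raster support) would leave the box raises an error —
never silent clipping. The assembled particle measures ~150–180 Å across
for the default ensemble, consistent with the negative-stain appearance of
IgG.

## The conformational ensemble

The generator draws, per particle:

| quantity | default law | why |
|---|---|---|
| Fab–Fc center distance | Gaussian(85 Å, 8 Å), support [65, 105] | observed Fab–Fc peak ~85 Å within a 60–120 Å range |
| Fc vertex angle (Fab1–Fc–Fab2) | Gaussian(56.6°, 8°), support [35°, 85°] | observed peak ~56.6°, >90 % of particles in 40–72° |
| Fab direction vs Fc direction | Gaussian(124.7°, 12°), support [95°, 160°] | observed Fab–Fc direction-angle peak ~124.7° |
| normal (dihedral) angle | Uniform(10°, 90°) | observed near-even spread from 10° to 90° with a drop below 10° |

The triangle is over-determined if a Fab–Fab distance law is also given:
the vertex-angle law takes precedence, and the Fab–Fab law is used (via the
law of cosines, with rejection of impossible triangles) only when the
vertex law is absent. The Fab–Fab direction angle is emergent rather than
sampled. Setting `orientations="uniform"` replaces all orientation laws
with Haar-random rotations per domain — used for the folding-bound checks.
Distance and angle laws are sampled independently; the generator does not
emulate correlations between measures (or steric exclusion between the two
Fabs), so passing tests say nothing about such correlations in real data.

## Tilt-series simulation

Single tilt axis = image y axis; the beam runs along z; a stage tilt by θ
is a right-handed rotation about +y. The default schedule is −60° to +60°
in 1.5° steps — 81 views with a ±30° missing wedge. Projections are
line integrals computed by rotate-then-sum with one shared bilinear kernel;
back-projection smears each image along z and rotates back with the same
kernel, so reprojection is self-consistent with projection. Both operators
are assembled once per (grid, angle) as sparse matrices acting on all
tilt-axis rows at once.

Translational jitter is uniform, continuous, per-image in
[−jitter_max, +jitter_max] pixels per axis (default 5 px) and recorded as
ground truth. Noise is additive white Gaussian, calibrated per image so
that the mask-based SNR estimator — evaluated with the ground-truth
particle mask — returns the requested target (default 0.2, raw-micrograph
regime 0.1–0.26). No contrast-transfer function, stain, dose or detector
model is simulated; the missing wedge is the only acquisition artefact
kept. Conclusions from these phantoms therefore cover alignment, wedge and
noise behaviour, not CTF- or stain-induced errors.

## FETR refinement

Reconstruction is ab initio: direct (unweighted) back-projection of the raw
images, then three rounds of translational re-alignment:

1. **Round 1** — circular cosine-tapered masks whose radius shrinks from
   0.45 to 0.30 of the box across iterations; low-pass schedule
   60 → 40 → 30 → 20 Å.
2. **Round 2** — particle-shaped soft masks regenerated each iteration
   from the current map: low-pass to 40 Å, threshold at the level enclosing
   3× the molecular mass converted to volume at 1.21 Å³/Da
   (protein density ≈ 0.81 Da/Å³), cosine-tapered over 3 px. Filter
   schedule 40 → 30 → 20 Å.
3. **Round 3** — repeats round 2 with sub-pixel ("interpolated") shift
   application; rounds 1–2 apply integer-rounded shifts.

Each iteration reprojects a reference map at every tilt angle, aligns each
image to its reprojection by masked, band-limited cross-correlation
(FFT-based; integer peak within a 10 px search radius, ties broken toward
the smaller shift, parabolic sub-pixel refinement), and back-projects with
the updated shifts. Alignment is **incremental**: the raw image is first
translated by its current correction so the mask and the reference line up,
and only the residual is measured. A round ends early when the largest
shift update drops below 0.5 px. Divergence (many shifts pinned at the
search boundary) sets a flag on the alignment state instead of raising.

Two defaults deserve explanation:

* **Ramp-weighted alignment reference.** Aligning against reprojections of
  the plain back-projection leaves a systematic ~1.5 px feature
  displacement in the wedge-edge (±60°) views. Weighting the image spectra
  by |k_x|^0.3 (a mild ramp along the in-plane direction) before building
  the *alignment reference* removes most of that bias while keeping the
  reference quiet enough at raw SNR 0.2. The output map itself is always
  plain back-projection.
* **Achievable alignment accuracy.** At per-image SNR 0.2 on this phantom
  the Cramér–Rao localization bound is ≈0.3 px per axis; the realized
  estimator reaches a median residual of ≈0.55 px with 75–90 % of images
  within 1 px (seed-dependent), the remainder being the wedge-edge
  systematic plus the heavy tail of peak localization at this noise level.
  Even on noise-free input the fixed point is not exactly zero shift
  (≤0.8 px at the extreme tilts) for the same reference-distortion reason.

The refined map is reported alongside a 20 Å low-passed copy for display.
SNR of a reconstruction is quoted as the estimator applied to the map's
0°-reprojection with the 2-D projection of the 40 Å / 3×-mass particle
mask; three-round refinement lifts it from ~0.2 (raw) to ≳4.

## Quality metrics

* **SNR** = (I_s − I_b)/N_b with I_s the mean intensity where the soft mask
  weight ≥ 0.5, I_b and N_b mean and standard deviation over the
  complement. "Average power" is read as mean intensity, consistent with
  the difference structure of the formula.
* **FSC** on shells one Fourier voxel wide, up to Nyquist:
  Re Σ F_A F_B* / √(Σ|F_A|² Σ|F_B|²). Resolution is the first crossing
  below the threshold (0.5 matched halves, 0.143 gold standard), linearly
  interpolated in (frequency, correlation); a never-crossing curve reports
  Nyquist with a flag.
* **Half-set splitting** is by even/odd tilt order; `raw` mode zeroes the
  alignment state so each half is refined independently (gold standard),
  `aligned` mode carries the common alignment into both halves. The
  aligned split shares noise through the common reference and is therefore
  optimistic; tests assert the gold standard is never better.
* **Gold-standard FSC** additionally registers the two half maps by
  whole-voxel cross-correlation (their origins are independent gauge) and
  applies one soft solvent mask — the 40 Å / 3×-mass particle mask, 6 px
  taper, built from the half-sum — to both maps. Without the solvent mask
  the box's background noise dominates the shells and the measured
  resolution degrades from ~15 Å to ~31 Å at these conditions.
* **Map-vs-model FSC** rasterizes coordinates (trilinear splat, then a
  Gaussian low-pass at the stated resolution) and correlates against the
  map.

## Domain identification and rigid fitting

Display contours are chosen by enclosed volume: the inner level encloses
0.6× and the outer 1.6× the 150 kDa particle mass at 1.21 Å³/Da. Volume
thresholds are exact order statistics of the voxel intensities, no
bisection needed.

**Segmentation** low-passes the map to 15 Å, takes a generous support
(2.5× the particle mass by enclosed volume — wider than the 1.6× display
contour, so even the dim rim of the Fc ring is represented), keeps the
substantial connected bodies (≥15 % of the largest;
noise islands are dropped, but domains disconnected at this contour are
kept), and splits the support voxels *spatially* into three clusters by
deterministic 3-means with farthest-first seeding. A plain
three-components-at-the-inner-contour rule was tried first and fails on
real reconstructions: the spread-out Fc ring is dimmer than the compact
Fabs and vanishes from the global top-0.6×-mass voxel set while the Fab
dumbbells fragment. Within each cluster the blob is the brightest subset
enclosing 0.6× one domain's mass — a per-domain inner contour. Fewer than
three comparable clusters, or blob centers closer than 30 Å, exclude the
particle with a reason code, mirroring the practice of discarding maps with
indistinguishable domains.

**Fc identification** scores each blob's central cavity: 1 − (mean
12 Å-smoothed density within 8 Å of the blob center) / (90th-percentile
density of the blob). A ring has an empty core (score ≈ 0.9–1.0); a
dumbbell's center sits between its lobes (score ≈ 0.2). Footprint-based
hole detection (project, fill holes) was abandoned: segmentation boundaries
can break the ring into a "C" and wedge smearing fills the projected hole.
Scores within 0.05 of each other are declared ambiguous and the particle is
excluded. The two Fabs are then ordered by signed azimuth about the Fc
blob's flattest axis — a deterministic convention that is immaterial
downstream because all Fab-paired statistics are pooled or symmetric.

**Rigid fitting** maximizes normalized real-space cross-correlation of the
rasterized template over a coarse rotation grid (axis-angle offsets,
±30° in 15° steps) × coarse translations (±4 voxels in steps of 2),
followed by greedy local refinement (2° rotations, 1-voxel translations)
and per-axis parabolic sub-voxel center interpolation. The correlation
window is weighted by the blob's dilated mask so neighbouring domains do
not pull the fit. Noise-free recovery is ≤0.5 Å in center; on maps
reconstructed from SNR-0.2 series, centers are recovered to ~1–3 Å and the
vertex angle to ~1°.

**Linker feasibility** replaces the original flexible-docking step: each
16-residue hinge must span the gap between anchor points placed at 0.8× the
domain radius along the center–center line; the maximum extension is
16 × 3.8 Å = 60.8 Å. All downstream statistics depend only on the rigid
placements, so this check is the only constraint the linkers impose.

## Geometry statistics

Nine vectors per conformation: three center-to-center vectors, three
direction vectors (minimum principal inertia axis), three normals (maximum
principal inertia axis). Principal axes come from the eigendecomposition of
the mass-weighted inertia tensor about the domain mass center; signs follow
first-nonzero-component-positive, after which direction vectors are
re-oriented to point away from the Fc (the Fc's away from the Fab
midpoint) so direction angles are meaningful on [0°, 180°]. Normal angles
are folded to [0°, 90°] because the two faces of a domain plane cannot be
distinguished at this resolution.

Six measure families are reported: Fab–Fab distance, pooled Fab–Fc
distances, vertex angle, Fab–Fab direction angle, pooled Fab–Fc direction
angles, and pooled normal angles. Histograms use bin widths at the
reporting precision of the measures — 5 Å for distances, 8° for the vertex
angle, 10° for direction/normal angles — and are fitted with sixth-degree
polynomials by unweighted least squares on raw counts (falling back to
degree 4 or 2 when a distribution spans fewer than eight bins). The peak is
the fitted curve's argmax on the data range; the peak population is the
fraction of samples in the bin containing it (the fraction-in-peak-bin
reading; an under-the-curve alternative was considered and rejected as less
direct). Ensemble superposition onto the Fc uses an SVD-based Kabsch fit
(proper rotations only) of the Fc atoms onto the first structure's Fc.

## Problem sizes and determinism

The library defaults (164³ voxels, 2.0 Å/pixel, 81 views) are used for the
single-particle refinement demonstrations and the half-set resolution
analysis. The twenty-particle end-to-end batch runs at 110³ voxels and
3.0 Å/pixel — the recovery targets (5 Å distances, 8° vertex angle) are
expressed in physical units and do not depend on the grid. Every stochastic
step takes an explicit `numpy.random.Generator`; fixed seeds reproduce
bit-identical tilt series, reconstructions and ensembles.

## Known limitations

* No CTF, stain, dose or detector model; tilt angles and the tilt axis are
  assumed exact (the method's tolerance to tilt errors is not probed).
* Alignment residuals have a heavy tail at raw SNR ≤ 0.2 (see above); a
  small fraction of images lands 1–2.5 px off even after refinement.
* The generator's orientation laws are per-Fab relative to the Fc frame;
  inter-Fab angle distributions are emergent, not directly controlled.
* Excluded particles (merged or ambiguous domains) are dropped from
  ensemble statistics; at the default study conditions exclusion is rare
  (0/20 in the end-to-end batch) but rises with noise.
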