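# Methods

This note documents the measurement model implemented by `alignfit`, the
choices made where the procedure was genuinely open, and what the synthetic
phantom does and does not establish about real data.

## Problem setting

A thermoformed aligner mounted on its printed dental model is scanned twice
with micro-CT: once with the aligner (`model+aligner`) and once without
(`model`), the model remaining fixed on its holder. Both reconstructions
are treated as 8-bit gray-value grids with isotropic voxels (33 μm default).
All processing is done on the 8-bit scale because the fixed segmentation
thresholds used for gap volumetry (140, 150, 160) are 8-bit numbers; 16-bit
input is linearly windowed at load time. Grid axes are `(x, y, z)` with `z`
the occluso-gingival axis and the model base at high `z`; voxel centre `i`
sits at physical `(i + 0.5)·voxel_size`.

Model resin and aligner polymer have nearly identical x-ray absorption, so
the aligner is isolated geometrically (registration + subtraction), not by
intensity.

## Rigid registration

`register_rigid` aligns the model scan (moving) to the model+aligner scan
(fixed). Only the base — by default the bottom 20 % of z slices — enters
the metric, because the base is aligner-free in both scans and the shell
must not bias the fit. The metric is the mean squared gray-value
difference, appropriate for same-scanner, same-modality pairs; it is
minimised by Powell's derivative-free method over 6 parameters (Euler
angles in degrees about the volume centre, translations) through a
3-level factor-2 multi-resolution pyramid, starting from the identity. At
the finest level the metric is evaluated on a 2×-decimated grid (full
resolution sampling, quarter cost). Out-of-field samples are excluded from
the metric rather than compared against a fill value. A final guard
returns the identity if the optimised metric is somehow worse than the
identity's, so the metric never increases.

The model+aligner grid is never resampled: thickness and gaps are always
measured on it, and the model is brought onto that grid
(`apply_rigid`, linear or nearest interpolation, out-of-field = air 0).

On noiseless phantoms the transform is recovered to well under 0.5 voxel /
0.5° for offsets up to 3 voxels and 2°; with the default noise (sd 10 gray
values) recovery stays under 1 voxel / 1°.

## Aligner extraction

`model+aligner − registered model`, clamped below at zero (the aligner only
adds material; negative residue is noise). The clamped difference is
binarised at the Otsu threshold computed on the full 256-bin histogram
including the zero-inflated background bin — reproducible, and that
zero-mode vs shell-mode split is exactly what Otsu must separate. The
convention is: background `v < t`, foreground `v ≥ t`, ties broken toward
the lower threshold; the maximisation runs in exact integer arithmetic
because the between-class variance is constant across empty histogram gaps
and float rounding must not decide those ties. The largest 26-connected component is kept (removes
speckle), then a discrete-ball closing of radius 2 voxels heals one-voxel
noise pits without bridging true gaps (those are handled separately at the
much larger radius R). Foreground connectivity is 26, background 6 — the
standard complementary pairing.

Ball dilation and erosion are implemented exactly through the Euclidean
distance transform (offsets with norm ≤ radius); erosion treats out-of-grid
voxels as background so surfaces flush with the volume border erode like
any other.

## Centre-surface thickness

Per-slice 2D centrelines (topology-preserving thinning,
`skimage.skeletonize`) are computed for all slices along each of the three
axes; a voxel belongs to the centre surface when it is a centreline voxel
in at least two of the three directions. Local thickness at a
centre-surface voxel is

    d = 2 × (Euclidean distance to the nearest background voxel centre) × voxel_size.

Distance is measured to background voxel *centres*, not interfaces: a
one-voxel sheet then reports d = 2·voxel_size (66 μm at 33 μm), which is
the method's reporting floor, and an odd n-layer slab reports
d = (n+1)·voxel_size — a systematic one-voxel overestimate that is
documented rather than corrected. For even-thickness regions the thinning
keeps one of the two central layers; no sub-voxel symmetrisation is
attempted.

`summarize_thickness` reports full-set min/median/mean/max/sd plus the
means of `n_reps` = 100 random draws of `n_points` = 100 centre-surface
voxels (uniform, without replacement within a draw, independent across
draws, one master seed). Shrinkage is mean thickness / nominal foil
thickness × 100, rounded to one decimal.

## Gap volumetry

On the model+aligner volume: binarise at a fixed threshold (material =
`v ≥ t`); seal everything below the reference plane (set to foreground) so
hole filling cannot leak through the base; dilate by a discrete ball of
radius R, fill all background components not connected to the volume
border (6-connectivity), erode by the same ball; gaps = filled AND NOT
material, restricted to above the plane; label components (26-connectivity)
and convert counts to mm³. The construction guarantees filled ⊇ binary.

R is a free parameter. A surface slit of opening w is sealed — and hence
counted — iff w ≤ 2R, so R should exceed half the widest expected gap
mouth while staying below the scale of genuine anatomy concavities; the
default R = 10 voxels (330 μm) follows that rule for the phantom's void
sizes. On the voxel lattice this law holds exactly in the slit interior
(deeper than ~R below the mouth); within the mouth region the discrete
ball's corner voxels blur the boundary case w ≈ 2R by a few voxels. Because no single threshold is ideal when the foil thins to nothing,
the headline mode runs thresholds 140/150/160 and reports their mean with
the min–max spread as the uncertainty; 150 is the single-threshold default.
The reference plane sits 2 mm below the lowest tooth–gingiva border and is
transferred between specimens through the registration transform
(`transfer_plane`, valid for rotations < 5°, nearest-slice rounding).

`roi_gap_volume` applies the same pipeline to an axis-aligned crop (the
between-incisors ROI of the validation protocol); `projected_gap_map` sums
gap voxels along an axis × voxel size, conserving total volume exactly.

## Synthetic phantom

The generator renders a stylised arch — not anatomy; the analysis
operators, not teeth, are under test:

* substrate box with side walls, a full-footprint pedestal below the ROI
  plane, and a corrugated bottom face (amplitude 2.5 voxels) that gives the
  base the structure real printed bases have, making base-only registration
  well-posed in all 6 DOF;
* five capsule-shaped teeth along a half-arch, close enough that their
  draped shells merge (no spurious inter-tooth channels);
* a shell built between the model surface and an analytically offset outer
  surface: lateral thickness 0.85 × 12 voxels, occlusal 1.3 × 12 voxels
  (≈ 337 / 515 μm — the thick-occlusal / thin-lateral pattern of real
  foils), joined with exact circular fillets of radius 20 voxels;
* ellipsoidal voids of exactly known analytic volume (4/3·π·abc), centred
  on the model–shell interface, fully enclosed by material, pairwise
  disjoint (checked at generation, along with threshold-margin and
  enclosure invariants);
* model and shell gray values 200/195 (near-identical, as in the real
  material pair), air 30, additive Gaussian noise sd 10 clipped to
  [0, 255];
* a true rigid offset applied to the model scan by evaluating the scene's
  signed-distance fields at transformed coordinates — exact, no
  interpolation.

Every junction fillet radius exceeds the default closing radius R = 10, so
sphere-closing of a *gap-free* phantom should add nothing. Discretisation
still leaves thin (1-voxel) beads where fillets meet flat faces, ≈ 0.02 mm³
in total under default conditions — about 5 % of the implanted void total
(0.42 mm³) and the main reason recovered totals sit slightly above the
analytic truth. The gap-free regression test bounds this residual.

What the phantom does *not* emulate: partial-volume blur, beam hardening,
ring artifacts, anisotropic noise, real anatomy, or plastic deformation of
the aligner. Passing the phantom suite therefore demonstrates the
correctness of the operators and their composition under the stated image
model, not robustness to scanner physics.

Default problem sizes were chosen so the full suite runs on a laptop-class
machine: 160×140×166 voxel phantoms for arch-level checks, 10 seeded
offsets for registration recovery, 20³ masks for exhaustive distance
oracles, slabs up to 15 layers for the thickness law.

## Numerical and degenerate-input choices

* Otsu on a constant volume, empty registration regions, empty masks,
  centre surfaces outside their mask, `n_points` larger than the field,
  zero nominal thickness, mismatched grids — all raise with specific
  messages rather than returning degenerate values.
* Pearson's ρ is undefined for constant vectors; `validate_against_reference`
  reports it as missing instead of raising, since a constant reference
  column with zero mean-absolute-difference is a legitimate comparison.
* Plane transfer rounds the transformed plane centre to the nearest slice
  (half-up); rotations ≥ 5° refuse axis-aligned transfer.
* Reported tables round thickness to whole μm, volumes to 0.1 mm³, ρ to
  3 decimals; JSON outputs keep full precision.

## Known limitations

* Thickness is voxel-quantised (no sub-voxel estimation); the (n+1) slab
  bias is inherent to the centre-voxel distance convention.
* The tri-directional centreline consensus erodes the centre surface near
  mask borders (slab tests therefore assert on footprint interiors).
* The fillet-bead residual above; choosing R close to half a void's mouth
  makes recovery sensitive to discretisation.
* The validation statistics module compares against transcribed reference
  measurement vectors; it does not re-implement the interactive
  region-growing workflow those numbers came from.
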