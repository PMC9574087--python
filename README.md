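# alignfit

Quantitative 3D analysis of how well a thermoformed orthodontic aligner fits
the dental arch it was moulded on, from paired micro-CT scans.

Transparent aligners are pressure-moulded polymer foils. Two properties
govern the force they transmit to teeth: the **local thickness** `d` of the
shell after thermoforming (foils thin non-uniformly — thicker on occlusal
surfaces, thinner around incisors), and the **gaps** — voids between the
aligner's inner surface and the tooth surface, where no force can be
transmitted at all. Both can be measured non-destructively by scanning the
aligner *mounted on its model* and the *model alone* with micro-CT at
isotropic voxels (33 μm in the reference protocol).

The catch is that model resin and aligner polymer absorb x-rays almost
identically, so the aligner cannot be segmented by intensity. `alignfit`
implements the full measurement pipeline that works around this:

1. **Registration** — the aligner-free base region of the model scan is
   rigidly registered to the model+aligner scan (mean-squared-difference
   metric, multi-resolution Powell search, 6 DOF).
2. **Aligner extraction** — the registered model is subtracted voxelwise
   (clamped at zero); the difference is binarised with Otsu's method, the
   largest 26-connected component kept, and small pits closed
   morphologically.
3. **Thickness** — 2D centrelines are extracted from every slice in the
   three orthogonal directions; voxels present in ≥ 2 directions form the
   centre surface, and at each centre-surface voxel

   `d = 2 · EDT(mask) · voxel size`

   (twice the Euclidean distance to the nearest background voxel). With
   33 μm voxels the smallest reportable `d` is 66 μm. Summary statistics
   include repeated random subsampling (100 points × 100 repetitions) and
   shrinkage, the mean thickness as a percentage of the nominal foil.
4. **Gap volumetry** — the model+aligner scan is binarised at a fixed
   threshold (140/150/160 averaged), sealed below a reference plane 2 mm
   under the tooth–gingiva border, closed by *dilation with a sphere of
   radius R → hole filling → erosion by R*, and gaps are defined as
   `filled AND NOT material`, labelled into components with volumes in mm³.
5. **Validation statistics** — Pearson's ρ and the mean absolute difference
   between automatic and reference (semi-automatic) measurements.

Because the original tomograms are not redistributable, the package ships a
**synthetic phantom generator** (`alignfit.phantom`) that renders paired
8-bit volumes of a stylised dental arch — capsule teeth, a draped shell of
spatially varying thickness, ellipsoidal interface voids of exactly known
analytic volume, a known rigid offset between the two "acquisitions", and
Gaussian noise — giving exact ground truth for every pipeline stage.

## Worked example

```python
import numpy as np
from alignfit import (PhantomConfig, GapConfig, generate_arch_phantom,
                      register_rigid, apply_rigid, subtract_registered,
                      extract_aligner_mask, extract_center_surface,
                      measure_thickness, summarize_thickness,
                      total_gap_volume_multithreshold)

model, mpa, truth = generate_arch_phantom(PhantomConfig(seed=7))

t = register_rigid(mpa, model)                      # base-region rigid fit
diff = subtract_registered(mpa, apply_rigid(model, t))
mask = extract_aligner_mask(diff, closing_radius_voxels=2)
cs = extract_center_surface(mask)
fld = measure_thickness(mask, cs)
summary = summarize_thickness(fld, seed=7, nominal_foil_um=550.0)
gaps = total_gap_volume_multithreshold(mpa, GapConfig(plane=truth.base_plane))

print(f"median thickness {np.median(fld.values_um):.0f} um, "
      f"min {fld.values_um.min():.0f} um, shrinkage {summary.shrinkage_percent}%")
print(f"gap volume {gaps['mean_mm3']:.3f} mm3 "
      f"(spread {gaps['min_mm3']:.3f}-{gaps['max_mm3']:.3f}), "
      f"implanted {sum(g.analytic_volume_mm3 for g in truth.gaps):.3f} mm3")
```

prints

```
median thickness 396 um, min 66 um, shrinkage 63.2%
gap volume 0.444 mm3 (spread 0.443-0.446), implanted 0.421 mm3
```

The median equals the designed base-shell thickness (12 voxels = 396 μm),
the minimum sits at the 66 μm floor of the method, and the recovered gap
volume is within 6 % of the implanted analytic ellipsoid total, with a
threshold spread below 1 %.

A command-line interface mirrors the library
(`alignfit simulate|register|extract-aligner|thickness|gaps|validate|run`).

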