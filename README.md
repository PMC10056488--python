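# corokit

Coronary imaging analysis for researchers working with intravascular OCT
and CT coronary angiography (CTCA): lumen and adventitia border
segmentation on polar OCT pullbacks, metallic and bioresorbable (BVS)
stent-strut detection, CTCA level-set segmentation of lumen / outer wall /
plaques with stent localization, fusion of per-frame 2D results onto a 3D
centerline with tubular mesh generation, and the quantitative vessel and
stent metrics built on top (plaque burden, stent CSA, malapposition,
restenosis burden, fracture flags).  Everything is exercisable offline on
synthetic phantoms with exact ground truth, so the whole chain is testable
without clinical data.

## The algorithms in brief

* **OCT borders** — guidewire artifact removal via the Harris–Stephens
  corner response plus full-depth-shadow analysis; bilateral filtering;
  lumen as a fast-marching minimal path over speed
  `F = ε + (1−ε)·R`, where `R` is the intima ridge response (intensity ×
  positive radial gradient); adventitia from an 11×11 standard-deviation
  image followed by Frangi vesselness tuned to the dark media ring
  (thickness parameter 31 px).
* **Struts** — per-A-line percentile thresholding with shadow-length and
  slope criteria, condensed by DBSCAN (one cluster per strut); BVS struts
  by a fixed morphological rule chain (threshold 0.15 → close → fill holes
  → subtract; area ∈ [10, 40] px, aspect < 5, within a 10-px band around
  the lumen border).
* **CTCA** — multiscale Frangi vesselness; minimum-cost-path centerline
  with ridge recentering; sigmoidal HU membership functions calibrated on
  user seed voxels; 3D upwind level set with speed
  `(2·w(I) − 1) − κ·curvature`; stent extent from a sigmoid adapted to the
  luminal mean (`midpoint = μ + 3σ`) scored on the perilumenal shell per
  0.5 mm station.
* **Fusion** — rotation-minimizing frames along the centerline; rigid
  per-frame placement `c(s) + x·n(s) + y·b(s)`; lofted watertight meshes;
  model-vs-frames cross-section comparison (r², RSS, Bland–Altman) with
  landmark-based registration.

See `docs/methods.md` for assumptions, parameter defaults and limitations.

## Worked example

Segment a synthetic stenosed pullback and measure the recovered borders:

```python
import numpy as np
from corokit.phantom import OCTPhantomSpec, synth_oct_pullback
from corokit import oct_analysis as oa, metrics as mt
from corokit.types import radial_dice, contour_hausdorff_mm

spec = OCTPhantomSpec(n_frames=10, lumen_radius_mm=lambda f: 1.5 - 0.04 * f,
                      guidewire_angle_deg=46.0, noise_seed=7)
frames, truth = synth_oct_pullback(spec)

f = frames[0]
_, wire = oa.remove_guidewire(f)
lumen = oa.segment_lumen(oa.bilateral_denoise(f), wire)
adv = oa.segment_adventitia(f, lumen, wire)

poly_l = oa.contour_to_polygon(lumen, f.radial_spacing)
poly_a = oa.contour_to_polygon(adv, f.radial_spacing)
area, perim, dmin, dmax = mt.contour_metrics(poly_l)
print(f"wire sector: A-lines {wire.alines.min()}..{wire.alines.max()}")
print(f"lumen area {area:.3f} mm^2, perimeter {perim:.3f} mm")
print(f"plaque burden {mt.plaque_burden(poly_l, poly_a):.1f} %")
print(f"Dice vs truth {radial_dice(lumen.radii, truth.lumen_contours[0].radii):.4f}, "
      f"HD {contour_hausdorff_mm(lumen.radii, truth.lumen_contours[0].radii, f.radial_spacing):.4f} mm")
```

prints

```
wire sector: A-lines 40..52
lumen area 7.071 mm^2, perimeter 9.467 mm
plaque burden 53.2 %
Dice vs truth 0.9998, HD 0.0100 mm
```

The lumen area of the r = 1.5 mm phantom is recovered to within half a
percent of π·1.5² ≈ 7.07 mm², the guidewire sector [40°, 52°] is flagged
exactly, and the border agrees with the ground truth to one pixel
(0.01 mm).  The same frames flow on into strut detection, 3D fusion and the
stent metrics; the CLI ties the steps together:

```bash
corokit phantom oct --out ph --seed 7 --n-frames 10
corokit oct segment --input ph --out seg
corokit metrics --contours seg/contours.json --out met
```

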