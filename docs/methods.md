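# Methods

`corokit` reimplements, as an offline library and CLI, the computational
core of an all-in-one coronary analysis workflow: border segmentation on
intravascular OCT pullbacks, metallic and bioresorbable (BVS) stent-strut
detection, CT coronary angiography (CTCA) segmentation with a 3D level set,
fusion of 2D results onto a 3D centerline with mesh generation, and the
quantitative vessel/stent metrics derived from all of the above.  Because
clinical pullbacks cannot be shipped, every algorithm is validated against
synthetic phantoms with exact ground truth; this note records the models,
the defaults, and the choices made where the design was genuinely open.

## Conventions

Polar OCT frames are `(n_alines, n_depth)` arrays in [0, 1]; row index is
the A-line, column index is depth from the catheter center, `radial_spacing`
is mm per depth pixel.  The A-line angle is `theta = 2*pi*row/n_alines`,
zero at the image top, counter-clockwise in the cartesian view; a polar
point maps to `(x, y) = (-R sin(theta), R cos(theta))`.  All file
coordinates are 0-based, intervals half-open; distances mm, areas mm²,
angles degrees.  Every stochastic path takes an explicit integer seed and
identical seeds give bit-identical outputs.

## OCT phantom

Each frame is a piecewise-constant radial template — dark lumen interior
(0.05), a 3-px bright intima ridge (0.95) starting at the true lumen radius,
a tissue band (0.60), a dark media ring (0.12) whose outer edge is the true
adventitia radius, and a dimmer beyond-wall region (0.32) — multiplied by
exponential speckle smoothed to a ~1 px grain and renormalized to unit mean.
The smoothing reduces the raw exponential contrast to a speckle standard
deviation of roughly 28 % of the local mean, comparable to processed OCT
texture.  A guidewire draws a bright reflection near the catheter plus a
full-depth shadow (2 % transmission) over its angular sector; each metallic
strut is a saturated 3-px bloom with a full-depth shadow (5 % transmission)
behind it; each BVS strut is a bright-rimmed dark box at the lumen border.
The lumen may be elliptical (`eccentricity` = minor/major ratio) and its
mean radius may vary per frame.  Defaults: 360 A-lines x 500 depth px at
0.01 mm/px, lumen radius 1.5 mm, wall thickness 0.7 mm, media ring 0.31 mm
(31 px — matching the adventitia filter scale), guidewire width 12°, frame
spacing 0.2 mm.  The generator is not a light-transport simulation: it
reproduces the appearance cues the detectors rely on (ridges, rings,
shadows, texture), not attenuation physics, catheter reflections,
NURD or sew-up artifacts.  Passing its tests therefore demonstrates
correctness of the algorithmic chain on ideal-contrast data, not clinical
accuracy.

## OCT border segmentation

1. **Guidewire removal.** Candidate A-lines show a full-depth shadow beyond
   the catheter zone: tail mean below 0.06 *and* tail maximum below 0.4.
   The second condition separates the wire from strut shadows, where the
   strut bloom itself stays bright.  Among contiguous candidate runs
   (periodic), the run containing the strongest Harris–Stephens corner
   response near the catheter — the wire reflection — is flagged; its
   A-lines are never used as data and the border radii there are filled by
   periodic linear interpolation.
2. **Bilateral filtering** (sigma_spatial 5 px, sigma_range 0.1) suppresses
   speckle while keeping the intima edge.
3. **Lumen.** A fast-marching minimal path crosses the polar image monotone
   in A-line index through cost `1/F`, `F = eps + (1-eps)*R` with
   `eps = 0.01` and `R` the ridge response (intensity x positive radial
   gradient, rescaled to [0, 1]).  Periodicity is enforced by duplicating
   the first 12 A-lines below the frame; among the cheapest end points the
   first whose start/end radii agree within 3 px is kept and the
   doubly-visited rows are blended linearly.  A blank frame (no ridge)
   raises "no lumen detected".
4. **Adventitia.**  Bilateral filter, 11x11 neighborhood standard
   deviation, then Frangi vesselness tuned to the dark media ring with a
   thickness parameter of 31 px, interpreted as the single scale
   `sigma = 31/(2*sqrt(3))` px of a ridge detector matched to a band 31 px
   wide.  The per-A-line vesselness maximum beyond the lumen marks the
   ring center; the reported radius is center + 15.5 px (ring half
   thickness), i.e. the ring's outer edge.  A-lines with response below
   0.05 are interpolated; if more than half fail, the border is declared
   unrecoverable.  The standard-deviation step needs *texture* contrast:
   on a noiseless synthetic frame every homogeneous band is equally
   featureless and the method is intentionally undefined.

## Strut detection

**Metallic.**  Per A-line, pixels above the 99.5th intensity percentile of
the frame are kept; the brightest is a candidate when the profile drops
behind it with slope ≥ 0.05 intensity/px and the remaining tail (after a
10-px gap) is at least 150 px long with mean below 20 % of the median
beyond-lumen brightness.  Candidates are clustered with DBSCAN in cartesian
mm (eps 0.15 mm, min_pts 1 — deployed struts sit ≥ 0.6 mm apart) and each
cluster becomes one strut at its intensity-weighted centroid.  Clustering
runs per frame; cross-frame linking into stent wires (0.3 mm radius) is
done during 3D fusion.

**BVS.**  On the scan-converted frame, min-max normalized: binarize at
0.15, morphologically close with a 1-px disk, fill holes, subtract the
thresholded image; 8-connected components survive with area in [10, 40] px,
second-moments aspect ratio < 5, and centroid within 10 px of the lumen
border polygon (the "10-pixel band" is read as distance-to-border ≤ band
width).

## CTCA chain

**Vesselness.**  Multiscale Frangi response to bright tubes; the scale list
is the vessel radii (mm) to enhance and the Gaussian width per scale is
`sigma = scale/sqrt(2)`, where the second-derivative response to a ridge of
that radius peaks.  Being Hessian-based it is invariant to volume-wide HU
offsets.  Default scales 1.0/1.5/2.0 mm.

**Centerline.**  Minimum-cost path (`cost = 1/(1e-3 + vesselness)`,
26-neighborhood, metric edge lengths) between two user seeds.  Because the
response plateaus across the lumen, tie-breaking lets the raw path drift or
cut corners; each path point is therefore recentered on the
response-weighted centroid of its 5-voxel neighborhood (4 iterations) and
the path is smoothed with a moving average of window 5 before conversion to
mm.  The recentering radius must reach the plateau edge, i.e. be of the
order of the lumen radius in voxels.

**Weight calibration.**  From user-annotated seed voxels (≥ 5 per class):
lumen = product of a rising and a falling sigmoid with midpoints at the 5th
and 95th percentile of lumen-seed HU and slope `4/IQR`; wall = falling
sigmoid midway between the wall-seed mean and the lumen 5th percentile; CP
= rising sigmoid midway between the lumen 95th percentile and the CP-seed
mean (slopes `8/gap`).  Degenerate (noiseless) seed spreads get a floor of
20 HU on the band width and 5 HU on slope denominators.  Seed means not
ordered wall < lumen < CP raise "calibration inconsistent".

**Level set.**  First-order upwind evolution of a signed distance function,
speed `(2*w(I) - 1) - kappa*curvature` with kappa 0.2, time step 0.4,
mean curvature clamped to ±1/voxel, reinitialization by distance transform
every 50 iterations, at most 500 iterations, convergence when the labelled
volume changes < 1e-3 relatively over 10 iterations.  The lumen front
starts as a 1-voxel tube around the centerline.  The outer-wall front
restarts from the lumen result with speed from `max(w_wall, w_lumen, w_cp)`
— the outer surface encloses lumen, wall tissue *and* plaque, so inclusions
must not punch holes in the front.  CP = connected components of
`w_cp > 0.5` inside the wall band; NCP (which has no weight function of its
own) is defined by exclusion: wall-band voxels with `w_wall > 0.5` that are
not CP.  Labels compose with precedence stent > CP > lumen > NCP > wall;
the stent pass runs first because blooming metal on the perilumenal shell
would otherwise masquerade as calcium.

**Stent localization.**  A rising sigmoid with midpoint `mu + 3*sigma` of
the luminal HU (slope `4/max(sigma, 10 HU)`) scores the perilumenal shell —
the morphological gradient of the lumen mask dilated by one voxel.  Per
0.5 mm centerline station the score is the bright fraction of shell voxels;
the stent extent is the longest contiguous run of stations above 0.1.  An
empty extent is a valid result.  Because the midpoint adapts to the luminal
statistics, rescaling the stent contrast leaves the extent unchanged.

## 3D fusion and meshing

Frames are placed rigidly: contour point `(x, y)` goes to
`c(s) + x*n(s) + y*b(s)` at arclength `s = offset + i*frame_spacing`.  The
per-point bases are rotation-minimizing (double-reflection) frames rather
than Frenet frames, which are undefined on straight segments and flip at
inflections.  The absolute roll of the frames about the centerline is not
recoverable from a pullback; the initial normal is fixed (documented
default: the projection of +z, or +x when the path starts along z).  This
affects strut azimuth in 3D but no area or diameter.  Frame-to-arclength
registration is a linear fit through ≥ 2 user landmarks.

Rings (resampled to a uniform point count) are lofted quad-by-quad with
seam alignment by minimal twist and capped flat; optional Laplacian
smoothing (lambda 0.1, 5 iterations, *no* volume constraint) is off by
default because it shrinks cross-sections slightly.  Cross-sections for the
model-vs-frames comparison are cut every 0.5 mm perpendicular to the
centerline; a cut of a tube is star-shaped about its centroid, so the
intersection vertices are azimuth-ordered and integrated by the shoelace
formula.  Effective diameter is the area-equivalent diameter
`2*sqrt(A/pi)`.  Agreement is summarized by r², residual sum of squares
about the identity line, and Bland–Altman bias with limits of agreement
`bias ± 1.96*sd`.

## Metrics

Plaque burden uses the standard EEM-based definition
`100*(A_wall - A_lumen)/A_wall`.  Stent CSA is the area of the polygon of
struts azimuth-ordered about the lumen centroid (no vendor stent model is
fitted).  Malapposition per strut is the signed distance from the strut's
abluminal edge (center pushed one strut thickness, default 0.1 mm, toward
the wall) to the lumen border, positive when the edge still floats in the
lumen cavity; a strut is unapposed above the threshold (default 0.1 mm).
Restenosis burden is `100*(CSA - A_lumen)/CSA`, clipped at 0.  Fracture is
flagged for any run of ≥ 3 consecutive strut-free frames strictly inside
the stented extent.  Min/max diameters come from rotating calipers on the
convex hull.

## Classifier bookkeeping

The plaque-classifier data preparation is reproduced without training:
patch centers are drawn (seeded) uniformly from the ROI between the lumen
and adventitia contours; augmentation adds one 90°- and one 180°-rotated
copy per original (never a rotation of a rotation), so the augmented count
is three times the originals; the 70–30 split partitions *frames*, not
patches, so no frame leaks between training and validation.  With 300
frames x 1000 patches this yields 900,000 / 630,000 / 270,000 samples.
The architecture spec builder emits nine 3x3 conv blocks
(conv + batch-norm + ReLU; filters 32/64/128 per group of three for OCT,
16/32/128 for IVUS), max pooling after blocks 3 and 6, global average
pooling, FC 512, dropout 0.5, and a final FC sized to the number of classes
— five here (four plaque types plus background), the only head consistent
with the stated classes.  The default patch size is 25 px
for both modalities (only the IVUS size is stated explicitly).  Trained
clinical weights are out of scope: no annotated clinical frames are
shipped, so no clinical accuracy is claimed or implied.

## CT phantom

A parametric tube (straight line or helix) is rasterized on an isotropic
grid: lumen within radius r of the curve, wall within r + w, spherical CP /
NCP inclusions centred mid-wall at given (arclength, azimuth), an optional
1-voxel stent shell at the lumen surface over an arclength interval.  Class
HU defaults: background −50, NCP 30, wall 60, lumen 350, CP 900, stent
1200 — ordered as a contrast CT would show them.  Intensities may be
blurred (Gaussian, mm) and noised (Gaussian, HU, seeded).  Grid center
falls at half-integer voxel coordinates, which keeps the rasterized
cylinder volume within a fraction of a percent of pi r² L.

## Validation suite and problem sizes

The acceptance script and the heavier tests use: 50 segmented OCT frames
(360 x 500 px) for border accuracy (Dice, Hausdorff, adventitia error); a
20-frame pullback with 8 struts/frame (160 struts) for recall/precision;
64 x 64 x 160 voxel CT phantoms at 0.25 mm for the level-set, centerline
and stent checks; 300 x 1000 patches for the bookkeeping counts.  These
sizes make each suite a few minutes of single-core work while keeping the
discretization fine enough for the stated tolerances.  Clinical-grade accuracy figures would require clinical pullbacks, which
this package does not ship; the phantom suite validates the algorithmic
chain, not clinical performance.

## Known limitations

* The OCT speckle model has no depth-dependent attenuation or rotation
  artifacts; detector thresholds (percentile 99.5, shadow length 150 px,
  slope 0.05) are tuned to this contrast regime and are all exposed in the
  configuration.
* The level set is a full-grid explicit scheme; volumes much beyond
  ~10⁶ voxels would want a narrow-band implementation.
* Anisotropic CT spacing is handled by using the mean spacing in the
  level-set and vesselness voxel metrics.
* BVS detection expects per-frame min-max normalized grayscale; heavy
  catheter artifacts inside the band would produce false positives.
* The fusion step takes the centerline as input (from CTCA or any external
  source); two-view angiographic reconstruction is out of scope.
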