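# Methods

`woundkit` is a desk-scale re-creation of an AI-assisted wound assessment
stack built around a smartphone-class time-of-flight (LiDAR) sensor: a
phantom simulator standing in for the bench and clinical data such devices
are validated on, the geometric measurement engine (surface area and depth),
a two-stage U-Net tissue segmentation pipeline, and the agreement statistics
used to compare automated measurements against digital planimetry and probe
measurements.

## Sensor and camera model

The sensor is modelled as an ideal pinhole camera over a 192 x 256 grid —
the native depth-map resolution of the device class.  Each pixel stores the
*range along its ray* in millimetres (what a time-of-flight sensor measures),
with NaN marking missing returns; back-projection converts ranges to metric
3-D points.  The optics of the real sensor are not published, so the default
focal length is 210 px (about 60 degrees horizontal field of view) with the
camera at 350 mm — comfortably beyond the > 300 mm working distance the
hardware needs.  Pixels are 0-based and row-major, sampled at their centres;
the camera frame has +z along the optical axis, x along columns, y along
rows.

Depth maps can be bilinearly upsampled (align-corners mapping) to, e.g.,
512 x 683 — the "morphed" resolution used downstream of such sensors.
Upsampling never extrapolates outside the source range, and any output pixel
whose bilinear support touches a missing pixel is itself missing.  Depth is
estimated at native resolution by default: interpolation adds no
information.

## The phantom

The in-vitro phantom reproduces the adjustable-cube bench model: a skin
plane with a rectangular or elliptical aperture whose walls descend at an
edge angle alpha to a flat floor `true_depth` below skin level.  The floor
width is `aperture - 2 * depth / tan(alpha)`, clipped at zero (walls meeting
in a V); `true_depth < 0` flips the profile into a bump above the skin,
modelling hyper-granulation.  For elliptical apertures the wall profile is
driven by the normalised elliptic radius, so the wall slope equals alpha
along the minor axis and is steeper along the major axis; the maximum
reachable depth of an elliptical cavity is `min(semi-axes) * tan(alpha)`.

Rendering is analytic first-hit ray casting against the parametric
primitives (skin plane, wall planes / elliptic cone, floor plane) rather
than a mesh: the phantom is piecewise planar/quadric, exact intersections
are cheap, and an independent dense-sampling oracle can verify them to
0.05 mm.  Floor occlusion by the cavity's own walls — the failure mode of
deep, narrow, steep-edged wounds — emerges from first-hit selection.
Sensor noise is i.i.d. Gaussian on the range, default sd 1.0 mm, seeded; a
1 mm noise floor plus estimator smoothing matches the +/- 3 mm effective
depth resolution of the hardware class.  Vertical walls (alpha = 90) are
handled exactly via the cotangent form of the wall equations.

### Bench sweep protocol

The published bench validation used 51 wound configurations (depths 0-35 mm)
imaged 8-10 times each; the individual configurations are not published, so
the sweep grid here is a stand-in, not a reconstruction: depths
{5..35 step 5} x apertures {20, 35, 50} x edge angles {40, 60, 80, 90},
keeping combinations whose floor is at least 4 mm wide (the bench cubes were
always set with the floor in view), which yields 62 configurations; at 8
repeats that is 496 images, the scale of the published 487.  Noise sd is
1 mm.  These conditions are fixed; they are not tuned per run.

## Surface area

Area is the sum of per-pixel physical footprints `(z / f)^2` over the wound
mask, reported in cm^2.  When angle adjustment is on, the total is divided
by cos(theta) of the surrounding-skin plane tilt to undo projective
foreshortening of obliquely viewed wounds.  Missing depth inside the mask is
tolerated to 20% (missing pixels receive the mean footprint); beyond that
the measurement is refused.  Masks for area measurement are taken at the
photo resolution (2x the sensor grid in the bundled scenes) because mask
pixelation, not depth, limits area accuracy at 192 x 256.

## Depth

Depth follows the reference-surface construction used by the device class:

1. a boundary ring of healthy skin (mask dilated by 5 px, minus the mask) is
   back-projected and a total-least-squares plane fitted to it — the
   estimated intact-skin level prior to injury (>= 30 valid ring pixels are
   required; orthogonal regression via the scatter-matrix eigenvector);
2. every pixel's signed distance along the plane normal is computed
   (positive = below skin) — "vertical" is the plane normal, not the optical
   axis, making the estimate invariant to capture tilt;
3. the field is 3 x 3 median filtered — standard speckle control for
   time-of-flight data; it suppresses single-pixel noise excursions without
   eroding the flat floor, keeping the maximum-based estimate nearly
   unbiased at 1 mm noise;
4. the reported depth DF is the extremum of largest magnitude over the
   wound: depressions positive, elevations (hyper-granulation) negative,
   ties going to the depression;
5. magnitudes below 3 mm — the hardware's depth resolution — are reported as
   the sentinel "+/-3" (numeric value 0 with a sentinel flag, so numeric
   pipelines stay clean while reports match the published display).

Occlusion and smoothing can only *reduce* the estimate, so the depth of a
cavity is never overestimated beyond the noise margin; estimates degrade
monotonically as edge angles drop below ~40 degrees, mirroring the
hardware's documented failure regime.

## Synthetic wound photos

The clinical training corpus (3383 annotated images) is proprietary, so the
RGB renderer generates a fully specified surrogate: a wound blob (the
phantom aperture, random size/shape/offset/tilt) on skin, with slough and
necrosis patches laid out by quantile-thresholded smoothed Gaussian fields —
patch scale set by the field correlation length, target fractions hit to
pixel rounding.  Class colours are fixed in `RGB_CLASS_COLORS` (skin beige,
granulation red, slough yellow-fibrous, necrosis near-black) with per-class
texture noise, low-frequency mottle and a +/-12% linear lighting gradient.
About 10% of generated images are intact skin (negative examples).  Datasets
are split 70/20/10 (train/validation/test), disjoint and exhaustive.

What this generator does *not* emulate: specular highlights, shadows, limb
curvature, dressings/markers, camera blur, and the ambiguous tissue borders
that dominate clinical inter-rater disagreement.  Passing segmentation tests
therefore demonstrate that the pipeline architecture and training loop work
end-to-end on colour/texture-separable imagery — not clinical-grade
accuracy.

## Two-stage segmentation

Stage 1 (wound bed) and stage 2 (slough/necrosis within the stage-1 mask)
are U-Nets: a contracting path halving resolution and doubling filters per
level, an expanding path upsampling with skip connections concatenated at
matching levels, and a per-pixel class head at input resolution.  The
implementation is plain NumPy (im2col convolutions + GEMM, 2x2 max pooling,
nearest-neighbour upsampling, Adam), single-threaded and deterministic for a
fixed seed; gradients are verified against finite differences in the test
suite.

The networks are desk-scale by design: 3 levels, 8 base filters (~134 k
parameters), 128 x 128 stage-1 inputs — trainable in minutes on one CPU
core, architecturally identical to but far smaller than clinical networks.
Stage 2 receives the RGB image with out-of-wound pixels zeroed plus the
wound mask as a fourth channel, cropped to the wound's bounding box (15%
margin) and resampled to 64 x 64: tissue labelling only concerns the wound
interior, and the crop concentrates both signal and compute there.  Its
loss is likewise restricted to wound pixels, since predictions outside the
mask are discarded (forced to "other") at inference.

Training minimises pixel cross-entropy plus (1 - mean soft dice), equally
weighted — tracking all reported metrics (loss, pixel accuracy over all
classes, dice, IoU).  Optimiser: Adam, lr 1e-3, batch 8.  Early stopping:
when validation loss fails to improve by more than 1e-4 for 10 consecutive
epochs, training stops and the best-validation weights are restored.  The
epoch budgets used by the reproduction script (5 for stage 1, 12 for
stage 2) are what the synthetic corpus needs at this scale: stage 1
converges in 2-3 epochs; stage 2 takes ~10 to leave its all-granulation
plateau.  Stage-1 inference drops connected components under 16 px as
speckle.

The presence/absence call for slough and necrosis uses a 1% wound-area
threshold: published per-patient tables report trace fractions (a few
hundredths of a percent) alongside "absent" calls, so *any-pixel* presence
cannot be the operative rule; 1% treats trace fractions as segmentation
noise.  This threshold is a declared choice, not a published constant.

## Agreement statistics

The published validation tables state no formulas; the per-item columns
pin them down uniquely, and the implementations are locked by fixture tests
against every printed row and aggregate:

| statistic | per-item formula | aggregate |
|---|---|---|
| accuracy vs reference | \|device − ref\| / device | 100 (1 − mean) |
| pair reproducibility | \|m1 − m2\| / min(m1, m2) | 100 (1 − mean) |
| pair CV | (\|m1 − m2\|/√2) / mean | 100 · mean |
| depth accuracy | \|mean(m) − probe\| / mean(m), signed; sentinel → 0 | 100 (1 − mean) |
| depth spread | \|m1 − m2\| / min\|m\|; sentinel → 0 | 100 (1 − mean) |
| group spread | (max − min)/min; all-zero → 0 | 100 (1 − mean) |
| group CV | sample sd / mean; all-zero → 0 | 100 · mean |
| fraction agreement | min/max of the two percentages; (0,0) → 1 | 100 · mean |

Sample (n−1) standard deviations throughout; full precision internally,
rounding only at presentation (half away from zero to the published
decimals).  Notes: a handful of published fraction-agreement rows are
inconsistent with the min/max rule that fits all others (one prints 3.15,
which no ratio can reach), so the pixel-level headline means are validated
against the printed agreement columns rather than re-derived ratios; the
depth table's aggregate CV is not derivable from its printed per-row CVs by
any simple mean and is not fixture-tested; where a narrative value conflicts
with its table (92.26 vs 91.56), the table wins.

## Numerical choices and degenerate inputs

- Plane fits require >= 3 non-collinear points; collinearity is detected on
  the scatter spectrum.  Normals are oriented away from the camera.
- Ray casting rejects cameras inside the scene geometry and scenes outside
  the field of view; every ray must hit the (infinite) skin plane.
- Region-membership tests in the ray caster use 1e-7 mm tolerances;
  vertical-wall hits, which sit exactly on the aperture boundary, are
  classed as wound pixels via their non-zero height offset.
- Empty wound masks give zero area and empty tissue maps, not errors; the
  degenerate errors (border-clipped ring, all-missing depth) carry the
  offending quantity in their message.
- Depth-on-disk quantisation is 0.1 mm/unit (16-bit PNG + JSON sidecar),
  well under the 3 mm resolution floor; missing returns map to 65535.

## Reproduction scales

The reproduction script and acceptance tests run everything at CPU scale:
496-image bench sweep, n = 200 training corpus at 128 x 128 with three
network seeds, 30 held-out images for the fraction-recovery regression.
These sizes are the package's study conditions; the published clinical and
bench results themselves were produced with physical hardware and a
proprietary corpus, and are represented here by the fixture tables (exactly)
and by the phantom-scale properties (in direction and scale).

## Known limitations

- The reference surface is a plane; strongly curved limbs violate this and
  would need a curved sheet model.
- Undermined cavities (wound wider below the aperture) cannot be seen by
  any line-of-sight sensor and are out of scope.
- The elliptical wall profile approximates the edge angle away from the
  minor axis.
- Area from `(z/f)^2` uses the range as z; for wounds centred in the frame
  the difference is well under the 2% test tolerance, but a wound pushed to
  a frame corner would be slightly overestimated.
- The synthetic corpus makes tissue classes colour-separable; clinical
  slough/necrosis boundaries are not, and no claim about clinical accuracy
  follows from these tests.
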