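# woundkit

Desk-scale tooling for AI-assisted assessment of hard-to-heal wounds
(diabetic foot, venous leg, pressure and ischemic ulcers) with
smartphone-class LiDAR depth sensing.  Clinical wound care needs three
numbers per visit — wound surface area, wound depth, and the slough /
necrosis composition of the wound bed — and the tools that automate them
must be validated against digital planimetry and probe measurements.
`woundkit` implements that whole measurement-and-validation loop at a scale
that runs on one CPU:

- **Phantom simulator** — the adjustable-cube bench wound model (aperture,
  depth 0–35 mm, edge steepness, bumps for hyper-granulation) and a
  synthetic wound-photo generator, rendered to 192 × 256 time-of-flight
  range maps by analytic first-hit ray casting (wall occlusion included)
  and to RGB images with pixel-aligned ground truth.
- **Measurement engine** — area as summed per-pixel footprints `(z/f)²`
  with cos θ angle adjustment; depth DF as the extremum of signed distance
  to a healthy-skin reference plane fitted around the wound, with the
  ±3 mm sensor-resolution sentinel and negative values for growth above
  skin level.
- **Two-stage U-Net pipeline** — stage 1 segments the wound bed; stage 2,
  masked by stage 1, labels slough and necrosis; trained with
  cross-entropy + soft-dice loss and 10-epoch-patience early stopping.
  The networks are a compact NumPy implementation (im2col convolutions,
  Adam), ~134 k parameters, CPU-trainable in minutes.
- **Agreement statistics** — the accuracy / precision / reproducibility /
  CV conventions of clinical method-agreement tables, with the published
  measurement tables shipped as fixtures and every headline number
  reproduced exactly (see `docs/methods.md` for the formulas).

## Worked example

Simulate a 40 × 40 mm phantom wound, 10 mm deep, noise-free, and measure
it back:

```bash
woundkit simulate --out scene --depth 10 --noise-sd 0 --seed 2
woundkit report --bundle scene --out report.json
```

```json
{
  "area": {
    "area_cm2": 16.964,
    "mean_footprint_mm2": 2.945186,
    "n_pixels": 576,
    "tilt_correction_applied": true,
    "tilt_deg": 0.0
  },
  "config_hash": "8012ce841c9b",
  "depth": {
    "deepest_pixel": [85, 127],
    "depth_mm": 10.031,
    "display": "10.0",
    "reference_plane_rms_mm": 0.031,
    "reference_plane_tilt_deg": 0.0,
    "sentinel": false
  },
  "provenance": {"mask_source": "bundle"},
  "tissue": {
    "necrosis_pct": 10.0,
    "slough_pct": 30.0,
    "wound_pixels": 2500
  },
  "tool_version": "0.1.0"
}
```

The cavity depth is recovered at 10.0 mm from the reconstructed skin plane
(the 0.03 mm residue is the 0.1 mm on-disk quantisation), and the rendered
tissue layout (30% slough / 10% necrosis requested) is recovered exactly
from the ground-truth tissue map.  The area reads 16.96 cm² against the
16.00 cm² aperture: footprints are evaluated at the observed wound-surface
range, and this wound's floor sits 10 mm deeper than the skin, so its
pixels subtend slightly more area — a flat wound of the same aperture reads
within 2% of analytic.  A 2 mm cavity would instead print
`"display": "+/-3"` — below the sensor's depth resolution.

Agreement statistics from a packaged measurement table:

```bash
woundkit agree --table table3
```

```json
{
  "area_mean_cv_pct": 5.57,
  "area_precision_pct": 91.56
}
```

i.e. repeated area measurements agree to within ~8% of each other
(precision 91.56%) with a mean coefficient of variation of 5.57%.

The same operations are available as a library:

```python
from woundkit import PhantomSpec, make_cavity_scene, default_camera
from woundkit import DepthMap, estimate_wound_depth

scene = make_cavity_scene(PhantomSpec(aperture=(12, 12), true_depth=35,
                                      edge_angle_deg=80, noise_sd=0))
cam = default_camera()
ranges, mask, _ = scene.ray_cast(cam)
res = estimate_wound_depth(mask, DepthMap(ranges), cam)
print(res.depth_mm)   # 19.08 — a deep, narrow cavity is underestimated
                      # because its walls occlude the floor
```

## Package layout

| module | contents |
|---|---|
| `woundkit.geometry` | camera model, depth maps, back-projection, plane fitting, upsampling |
| `woundkit.phantom` | phantom scenes, ray-cast rendering, RGB generator, datasets, bench sweep |
| `woundkit.measure` | area, reference surface, depth DF, combined reports |
| `woundkit.segmentation` | U-Net, training loop, metrics, tissue fractions, presence calls |
| `woundkit.agreement` | agreement statistics + packaged measurement tables |
| `woundkit.io` / `woundkit.cli` | PNG/CSV/JSON dialects and the `woundkit` command |

Not in scope: real LiDAR drivers and mobile capture, undermined-cavity 3-D
reconstruction, photorealistic skin rendering, EHR export, and any claim of
clinical-grade segmentation accuracy (the synthetic corpus is
colour-separable by construction; see `docs/methods.md`).
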