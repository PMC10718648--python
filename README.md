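# lodgekit

A toolkit for preprocessing and evaluating UAV multi-spectral imagery of
wheat lodging trials.

Lodging — the permanent displacement of crop stems from vertical — is a
major yield- and quality-limiting trait in wheat breeding, conventionally
scored by walking the field and rating each plot on a 1-9 scale (1 = fully
upright, 9 = more than 75 % of plants flat). Multi-spectral UAV cameras make
that scoring automatable, but their bands are captured by physically offset
sensors and must be co-registered before any composite image, vegetation
index, or detector can use them. `lodgekit` provides the full pre- and
post-detector stack for this workflow:

- **Band registration** — rigid alignment of each band onto the green
  reference band by maximising a Gaussian-weighted mutual-information
  metric with a (1+1)-evolution strategy over a coarse-to-fine pyramid.
- **Enhancement presets** — "haze & gamma adjustment" and "contrast-limit
  stretching" for composed three-channel imagery.
- **Composites and indices** — true-colour (3-2-1) and red-edge (4-2-1)
  band stacking; NDVI, VARI, GARI and SABI rasters with denominator-safety
  masks.
- **Detection evaluation** — IoU, confidence filtering, NMS, greedy
  matching, precision/recall/F1, per-class AP (all-point interpolation),
  mAP@0.5 and mAP@0.5:0.95, and a 10x10 confusion matrix with a background
  row/column, for YOLO-format detection files from any external detector.
- **Synthetic scenes** — a seeded generator producing six-band captures of
  plot grids with exact per-band misalignment and severity ground truth, so
  every stage is testable without field data.

## The model in brief

Registration seeks the rigid transform `T*` (rotation `θ` about the image
centre plus translation `(t_x, t_y)`) maximising

    M(I_ref, I_mov, T) = MI_w(I_ref, I_mov ∘ T)

where `MI_w` is mutual information in bits of the Gaussian-weighted joint
intensity histogram (64 bins per axis; weight `w(x,y) =
exp(−((x−x_c)² + (y−y_c)²)/2σ²)` with `σ = min(H, W)/4`):

    MI = Σ_ij p_ij log2( p_ij / (p_i p_j) )

The optimiser is a (1+1)-evolution strategy: perturb the current transform
by `radius · scales · N(0, I)`, accept strict improvements, grow the search
radius by 1.002 on acceptance and shrink it symmetrically on rejection
(500 iterations per pyramid level, initial radius 2·10⁻⁴, stopping radius
1.5·10⁻⁶). Resampling is bilinear; out-of-frame pixels are excluded from
the histogram rather than filled.

Detection quality is scored with `P = TP/(TP+FP)`, `R = TP/(TP+FN)`,
`F1 = 2PR/(P+R)`, per-class average precision as the area under the
monotone precision envelope of the confidence-swept PR curve, and
`mAP = (1/|classes|) Σ_i AP_i`, optionally averaged over IoU thresholds
0.50:0.95.

## Worked example

```python
import math
from lodgekit import (OptimizerSettings, SceneConfig, generate_capture,
                      register_pair)

capture, truth = generate_capture(SceneConfig(seed=3, include_panchromatic=False))
result = register_pair(capture.bands[2], capture.bands[3],
                       optimizer_settings=OptimizerSettings(seed=1))
true_inv = truth.transforms[3].inverse()
fit = result.transform
print(f"error: {math.hypot(fit.tx - true_inv.tx, fit.ty - true_inv.ty):.3f} px, "
      f"{abs(math.degrees(fit.theta - true_inv.theta)):.3f} deg")
print(f"final mutual information: {result.metric_value:.4f} bits")
```

prints

```
error: 0.086 px, 0.014 deg
final mutual information: 1.6695 bits
```

i.e. the red band's unknown misalignment (here −0.35°, (−4.8, −9.1) px) is
recovered to better than a tenth of a pixel, and the aligned pair shares
about 1.7 bits of intensity information per pixel. The `examples/`
directory holds one short script per capability (simulation, registration,
enhancement/composition, indices, evaluation); each prints what it computes
and what the numbers mean. A thin CLI wraps the same functions:

```sh
lodgekit simulate --rows 4 --cols 5 --seed 7 --out scene/
lodgekit register scene/ --reference-band 2 --seed 1 --out aligned/
lodgekit index aligned/ --name NDVI --out ndvi.tif
lodgekit evaluate --gt gt/ --pred pred/ --iou 0.5 --out report/
```

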