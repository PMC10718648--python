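"""Score a degraded synthetic detector with the full evaluation suite.

Degrades ground truth into plausible detector output (jittered boxes,
misses, low-confidence spurious boxes) and reports per-class AP, mAP@0.5,
mAP@0.5:0.95 and the confusion matrix.
"""

import numpy as np

from lodgekit import SceneConfig, generate_capture, generate_detections
from lodgekit.detection_eval import evaluate_detections

_, truth = generate_capture(SceneConfig(rows=4, cols=5, seed=13,
                                        include_panchromatic=False))
dets = generate_detections(truth, jitter_px=3.0, miss_rate=0.1,
                           spurious_rate=0.15, seed=1)
print(f"{len(truth.boxes)} ground-truth plots, {len(dets)} detections")

report = evaluate_detections({"scene": dets}, {"scene": truth.boxes})
for c, ap in sorted(report.per_class_ap.items()):
    print(f"  class {c}: AP@0.5 = {ap:.3f}")
print(f"mAP@0.5      = {report.map50:.4f}")
print(f"mAP@0.5:0.95 = {report.map50_95:.4f}")

m = report.confusion
print(f"confusion diagonal (correct): {int(np.trace(m[:9, :9]))}")
print(f"missed truths (background column): {int(m[:9, 9].sum())}")
print(f"spurious detections (background row): {int(m[9, :9].sum())}")

# Jitter lowers IoU so mAP@0.5:0.95 falls well below mAP@0.5; misses cap
# recall, and the spurious boxes land in the background row because their
# confidences are low and they overlap no truth.
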