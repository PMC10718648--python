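"""Compute the four vegetation indices and contrast canopy against soil.

NDVI separates vigorous canopy (high NIR, low red) from soil; VARI and GARI
use only/mostly visible bands; SABI mixes NIR and the blue-green
denominator.
"""

import numpy as np

from lodgekit import MultiSpectralCapture, SceneConfig, generate_capture
from lodgekit.composition import vegetation_index

config = SceneConfig(seed=9, include_panchromatic=False,
                     band_offsets={k: (0.0, 0.0, 0.0) for k in range(1, 6)})
capture, truth = generate_capture(config)
aligned = MultiSpectralCapture("demo", capture.bands, aligned=True)

canopy = np.zeros(capture.bands[2].shape, dtype=bool)
for b in truth.boxes:
    canopy[int(b.y_min):int(b.y_max), int(b.x_min):int(b.x_max)] = True

print(f"{'index':>6} {'canopy mean':>12} {'soil mean':>10} {'valid px':>9}")
for name in ("NDVI", "VARI", "GARI", "SABI"):
    out = vegetation_index(aligned, name)
    c = out.values[canopy & out.valid_mask].mean()
    s = out.values[~canopy & out.valid_mask].mean()
    print(f"{name:>6} {c:>12.3f} {s:>10.3f} {int(out.valid_mask.sum()):>9}")

# NDVI is strongly positive over canopy and near zero over soil; the same
# ordering holds for the other indices by construction of the band
# reflectance profiles (plots are NIR-bright and red-dark).
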