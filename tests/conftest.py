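import numpy as np
import pytest

from lodgekit.io_formats import Box, BoxSet
from lodgekit.synthetic import SceneConfig, generate_capture


@pytest.fixture(scope="session")
def small_scene():
    """A compact rendered scene with truth, shared across tests (read-only)."""
    # offsets scaled with the half-size image so misalignment magnitude is
    # proportionally the same as at the 0.25-scale study conditions
    config = SceneConfig(rows=2, cols=2, plot_size_px=(40, 30), gap_px=8,
                         image_scale=0.125, max_translation_px=5.0,
                         max_rotation_deg=1.0, seed=11,
                         include_panchromatic=False)
    capture, truth = generate_capture(config)
    return config, capture, truth


def random_boxset(rng, image_id="img", width=200, height=160, n=None,
                  with_confidence=True, max_classes=9):
    """A valid random BoxSet for property and oracle tests."""
    if n is None:
        n = int(rng.integers(0, 13))
    boxes = []
    for _ in range(n):
        w = float(rng.uniform(4, width / 2))
        h = float(rng.uniform(4, height / 2))
        x0 = float(rng.uniform(0, width - w))
        y0 = float(rng.uniform(0, height - h))
        conf = float(rng.uniform(0.01, 0.99)) if with_confidence else None
        boxes.append(Box(int(rng.integers(1, max_classes + 1)),
                         x0, y0, x0 + w, y0 + h, conf))
    return BoxSet(image_id, width, height, boxes)
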