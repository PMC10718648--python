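"""Seeded synthetic six-band captures with known ground truth.

The generator emulates the imaging conditions of a UAV flight over a wheat
breeding trial: a grid of rectangular plots on a soil background, each plot
carrying a lodging-severity class on the 1-9 field scale.  Severity controls
the fraction of the plot rendered as a lodged patch — flattened canopy is
brighter in the visible bands (exposed stems and heads scatter more light)
and darker in the near-infrared than upright canopy.  Each band is the base
reflectance scene pushed through a known per-band rigid misalignment, plus
Gaussian sensor noise, so registration accuracy can be scored against an
exact truth.  The panchromatic band is rendered at its own, higher,
resolution.

Native band resolutions mirror the MicaSense RedEdge-P (1456x1088 for the
five spectral bands, 2464x2056 panchromatic); ``image_scale`` shrinks both
proportionally so the full registration suite runs quickly at desk scale.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Optional, Sequence, Union

import numpy as np
import tifffile

from .io_formats import BandImage, Box, BoxSet, MultiSpectralCapture, write_boxes
from .registration import RigidTransform2D

__all__ = [
    "SceneConfig",
    "SceneTruth",
    "BAND_PROFILES",
    "lodged_fraction_for_class",
    "generate_capture",
    "generate_detections",
    "write_fixture",
]

NATIVE_SPECTRAL = (1088, 1456)  # (H, W) bands 1-5
NATIVE_PAN = (2056, 2464)       # (H, W) band 6

#: band index -> (soil, upright canopy, lodged canopy) reflectance.
#: Plausible fixed constants: upright canopy is dark in the visible and
#: bright in the NIR; lodged patches brighten in the visible and lose NIR.
BAND_PROFILES: dict[int, tuple[float, float, float]] = {
    1: (0.12, 0.04, 0.10),   # blue
    2: (0.16, 0.10, 0.20),   # green
    3: (0.20, 0.05, 0.16),   # red
    4: (0.24, 0.30, 0.35),   # red edge
    5: (0.28, 0.50, 0.35),   # near-infrared
    6: (0.16, 0.08, 0.17),   # panchromatic (visible average)
}


def lodged_fraction_for_class(class_id: int, class9_fraction: float = 0.875) -> float:
    """Lodged-area fraction for a severity class.

    Class 1 (fully upright) has no lodged area; classes 2-8 ramp linearly as
    ``0.75 (class - 1) / 8``; class 9 means more than three quarters of the
    plot is flat, rendered at ``class9_fraction`` (default 0.875).
    """
    if not 1 <= class_id <= 9:
        raise ValueError(f"class_id must be in 1..9, got {class_id}")
    if class_id == 9:
        return class9_fraction
    return 0.75 * (class_id - 1) / 8.0


@dataclass
class SceneConfig:
    """Layout, radiometry and degradation parameters of a synthetic flight frame."""

    rows: int = 4
    cols: int = 5
    plot_size_px: tuple[int, int] = (56, 40)   # (w, h) at reference scale
    gap_px: int = 12
    image_scale: float = 0.25
    class_assignment: Union[str, Sequence[int]] = "random"
    #: per-band (theta_rad, tx, ty) or "random" to sample within max ranges
    band_offsets: Union[str, dict[int, tuple[float, float, float]]] = "random"
    max_rotation_deg: float = 2.0
    max_translation_px: float = 10.0
    noise_sd: float = 0.01
    texture_amplitude: float = 0.25
    texture_wavelength_px: tuple[float, float] = (20.0, 80.0)
    texture_components: int = 24
    include_panchromatic: bool = True
    seed: int = 0

    @property
    def spectral_shape(self) -> tuple[int, int]:
        return (round(NATIVE_SPECTRAL[0] * self.image_scale),
                round(NATIVE_SPECTRAL[1] * self.image_scale))

    @property
    def pan_shape(self) -> tuple[int, int]:
        return (round(NATIVE_PAN[0] * self.image_scale),
                round(NATIVE_PAN[1] * self.image_scale))

    def validate(self) -> None:
        h, w = self.spectral_shape
        pw, ph = self.plot_size_px
        grid_w = self.cols * pw + (self.cols - 1) * self.gap_px
        grid_h = self.rows * ph + (self.rows - 1) * self.gap_px
        if grid_w > w or grid_h > h:
            raise ValueError(
                f"plot grid {grid_w}x{grid_h} does not fit in image {w}x{h}"
            )
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")
        if self.rows < 1 or self.cols < 1:
            raise ValueError("grid must have at least one plot")


@dataclass
class SceneTruth:
    """Exact ground truth of a generated capture."""

    boxes: BoxSet
    #: per-band misalignment applied to the base scene; registration should
    #: recover each transform's inverse
    transforms: dict[int, RigidTransform2D]
    lodged_fraction: list[float]
    classes: list[int] = field(default_factory=list)


def _resolve_classes(config: SceneConfig, rng: np.random.Generator) -> list[int]:
    n = config.rows * config.cols
    if isinstance(config.class_assignment, str):
        if config.class_assignment != "random":
            raise ValueError(f"unknown class_assignment {config.class_assignment!r}")
        return [int(c) for c in rng.integers(1, 10, size=n)]
    classes = [int(c) for c in config.class_assignment]
    if len(classes) != n:
        raise ValueError(f"class_assignment must list {n} classes, got {len(classes)}")
    if any(not 1 <= c <= 9 for c in classes):
        raise ValueError("classes must lie in 1..9")
    return classes


def _resolve_offsets(config: SceneConfig, rng: np.random.Generator,
                     band_indices: Sequence[int]) -> dict[int, tuple[float, float, float]]:
    if isinstance(config.band_offsets, dict):
        out = {k: (0.0, 0.0, 0.0) for k in band_indices}
        out.update({k: tuple(v) for k, v in config.band_offsets.items()})
        out[2] = (0.0, 0.0, 0.0)  # reference band stays put
        return out
    if config.band_offsets != "random":
        raise ValueError(f"unknown band_offsets {config.band_offsets!r}")
    max_theta = math.radians(config.max_rotation_deg)
    out = {}
    for k in band_indices:
        if k == 2:
            out[k] = (0.0, 0.0, 0.0)
        else:
            theta = float(rng.uniform(-max_theta, max_theta))
            tx = float(rng.uniform(-config.max_translation_px, config.max_translation_px))
            ty = float(rng.uniform(-config.max_translation_px, config.max_translation_px))
            out[k] = (theta, tx, ty)
    return out


def _plot_rects(config: SceneConfig) -> list[tuple[int, int, int, int]]:
    """Plot rectangles (x0, y0, x1, y1) centred in the reference-scale image."""
    h, w = config.spectral_shape
    pw, ph = config.plot_size_px
    grid_w = config.cols * pw + (config.cols - 1) * config.gap_px
    grid_h = config.rows * ph + (config.rows - 1) * config.gap_px
    x_off = (w - grid_w) // 2
    y_off = (h - grid_h) // 2
    rects = []
    for r in range(config.rows):
        for c in range(config.cols):
            x0 = x_off + c * (pw + config.gap_px)
            y0 = y_off + r * (ph + config.gap_px)
            rects.append((x0, y0, x0 + pw, y0 + ph))
    return rects


class _TextureField:
    """Smooth seeded scalar field evaluable at arbitrary coordinates.

    A sum of random-direction sinusoids (unit variance) standing in for
    canopy-density and illumination variation shared by every band.  Being
    an analytic function of position, each band can point-sample it in its
    own misaligned frame with no interpolation.
    """

    def __init__(self, rng: np.random.Generator, n_components: int,
                 wavelength_range: tuple[float, float]) -> None:
        lam = rng.uniform(*wavelength_range, size=n_components)
        ang = rng.uniform(0.0, 2.0 * math.pi, size=n_components)
        k = 2.0 * math.pi / lam
        self.kx = k * np.cos(ang)
        self.ky = k * np.sin(ang)
        self.phase = rng.uniform(0.0, 2.0 * math.pi, size=n_components)
        self.norm = math.sqrt(n_components / 2.0)

    def __call__(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        out = np.zeros(x.shape, dtype=np.float64)
        for kx, ky, ph in zip(self.kx, self.ky, self.phase):
            out += np.sin(kx * x + ky * y + ph)
        return out / self.norm


def _scene_values(config: SceneConfig, band: int, fractions: Sequence[float],
                  rects: Sequence[tuple[int, int, int, int]],
                  texture: _TextureField,
                  qx: np.ndarray, qy: np.ndarray) -> np.ndarray:
    """Evaluate the continuous reflectance scene of one band.

    ``qx, qy`` are sample coordinates in reference-scale pixels; soil
    extends beyond the image bounds (the field continues past the frame).
    """
    soil, canopy, lodged = BAND_PROFILES[band]
    img = np.full(qx.shape, soil, dtype=np.float64)
    for rect, frac in zip(rects, fractions):
        x0, y0, x1, y1 = rect
        inside = (qx >= x0) & (qx < x1) & (qy >= y0) & (qy < y1)
        img[inside] = canopy
        if frac > 0:
            # lodged patch: a slab occupying `frac` of the plot from its top
            img[inside & (qy < y0 + frac * (y1 - y0))] = lodged
    if config.texture_amplitude > 0:
        img = img * (1.0 + config.texture_amplitude * texture(qx, qy))
    return np.clip(img, 0.0, 1.0)


def generate_capture(config: SceneConfig) -> tuple[MultiSpectralCapture, SceneTruth]:
    """Render a raw (misaligned, noisy) capture and its exact truth.

    Each band point-samples the continuous scene in its own frame: band k's
    pixel grid is pulled back through the inverse of that band's true rigid
    transform and the scene function is evaluated there directly, exactly as
    a physically offset sensor images the same field.  Gaussian sensor noise
    is added per band.  All randomness — class draws, misalignments, the
    shared texture and noise — derives from ``config.seed``; two calls with
    the same config are bit-identical.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    classes = _resolve_classes(config, rng)
    fractions = [lodged_fraction_for_class(c) for c in classes]
    band_indices = [1, 2, 3, 4, 5] + ([6] if config.include_panchromatic else [])
    offsets = _resolve_offsets(config, rng, band_indices)
    texture = _TextureField(rng, config.texture_components,
                            config.texture_wavelength_px)
    rects = _plot_rects(config)
    ref_shape = config.spectral_shape

    bands: dict[int, BandImage] = {}
    transforms: dict[int, RigidTransform2D] = {}
    for k in band_indices:
        shape = config.pan_shape if k == 6 else ref_shape
        h, w = shape
        center = ((w - 1) / 2.0, (h - 1) / 2.0)
        theta, tx, ty = offsets[k]
        if k == 6:
            # panchromatic misalignment specified at reference scale
            scale = shape[1] / ref_shape[1]
            tx, ty = tx * scale, ty * scale
        else:
            scale = 1.0
        t = RigidTransform2D(theta, tx, ty, center)
        transforms[k] = t
        ys, xs = np.mgrid[0:h, 0:w].astype(np.float64)
        pts = np.stack([xs.ravel(), ys.ravel()], axis=-1)
        src = t.inverse().map_points(pts)
        qx = src[:, 0].reshape(shape) / scale
        qy = src[:, 1].reshape(shape) / scale
        base = _scene_values(config, k, fractions, rects, texture, qx, qy)
        noisy = base + config.noise_sd * rng.standard_normal(shape)
        bands[k] = BandImage(np.clip(noisy, 0.0, 1.0), k)

    h, w = ref_shape
    boxes = [Box(cls, float(x0), float(y0), float(x1), float(y1))
             for (x0, y0, x1, y1), cls in zip(_plot_rects(config), classes)]
    truth = SceneTruth(
        boxes=BoxSet("synthetic", w, h, boxes),
        transforms=transforms,
        lodged_fraction=fractions,
        classes=classes,
    )
    capture = MultiSpectralCapture("synthetic", bands, aligned=False)
    return capture, truth


def _default_confidence(correct: bool, rng: np.random.Generator) -> float:
    """Correct detections score high, spurious ones low."""
    if correct:
        return float(rng.uniform(0.6, 0.99))
    return float(rng.uniform(0.05, 0.4))


def generate_detections(truth: SceneTruth, jitter_px: float = 0.0,
                        miss_rate: float = 0.0, spurious_rate: float = 0.0,
                        confidence_model: Optional[Callable[[bool, np.random.Generator], float]] = None,
                        seed: int = 0) -> BoxSet:
    """Degrade ground truth into a plausible detector output.

    Each truth box is dropped independently with probability ``miss_rate``,
    otherwise emitted with every corner coordinate jittered uniformly within
    ``±jitter_px`` and a confidence from ``confidence_model``.  For each
    truth box a spurious random-class box is also added with probability
    ``spurious_rate``.
    """
    for name, rate in (("miss_rate", miss_rate), ("spurious_rate", spurious_rate)):
        if not 0.0 <= rate <= 1.0:
            raise ValueError(f"{name} must lie in [0, 1]")
    if confidence_model is None:
        confidence_model = _default_confidence
    rng = np.random.default_rng(seed)
    gt = truth.boxes
    W, H = gt.image_width, gt.image_height
    out: list[Box] = []
    for b in gt:
        if rng.uniform() < miss_rate:
            continue
        j = rng.uniform(-jitter_px, jitter_px, size=4) if jitter_px > 0 else np.zeros(4)
        x0 = min(max(b.x_min + j[0], 0.0), W - 1.0)
        y0 = min(max(b.y_min + j[1], 0.0), H - 1.0)
        x1 = max(min(b.x_max + j[2], float(W)), x0 + 1.0)
        y1 = max(min(b.y_max + j[3], float(H)), y0 + 1.0)
        out.append(Box(b.class_id, x0, y0, x1, y1, confidence_model(True, rng)))
    for _ in gt:
        if rng.uniform() < spurious_rate:
            w = float(rng.uniform(8, max(9.0, W / 4)))
            h = float(rng.uniform(8, max(9.0, H / 4)))
            x0 = float(rng.uniform(0, W - w))
            y0 = float(rng.uniform(0, H - h))
            cls = int(rng.integers(1, 10))
            out.append(Box(cls, x0, y0, x0 + w, y0 + h,
                           confidence_model(False, rng)))
    return BoxSet(gt.image_id, W, H, out)


def write_fixture(capture: MultiSpectralCapture, truth: SceneTruth,
                  directory) -> None:
    """Write a generated scene as an on-disk fixture directory.

    Produces per-band 16-bit TIFFs under the ``<capture>_<band>.tif`` naming
    convention, the truth boxes as a YOLO-dialect text file, and the true
    per-band transforms as JSON.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for k, band in sorted(capture.bands.items()):
        codes = np.floor(np.clip(band.pixels, 0.0, 1.0) * 65535.0 + 0.5).astype(np.uint16)
        tifffile.imwrite(str(directory / f"{capture.capture_id}_{k}.tif"), codes)
    write_boxes(truth.boxes, directory / f"{capture.capture_id}_boxes.txt")
    transforms = {str(k): t.as_dict() for k, t in truth.transforms.items()}
    (directory / f"{capture.capture_id}_transforms.json").write_text(
        json.dumps(transforms, indent=2)
    )
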