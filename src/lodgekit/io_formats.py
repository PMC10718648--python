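"""File formats for multi-spectral captures and bounding-box annotations.

A capture from a six-band agricultural sensor (MicaSense RedEdge-P layout)
arrives as one single-channel 16-bit TIFF per band, named
``<capture>_<band>.tif`` with band indices 1..6: blue, green, red, red edge,
near-infrared and panchromatic.  Bands 1-5 share one resolution; the
panchromatic band 6 is captured at a higher resolution.

Annotations use the YOLO text dialect: one box per line,
``class cx cy w h [conf]`` with geometry normalised to [0, 1] and 0-based
class indices on disk.  In memory, classes are the 1-based lodging-severity
scale (1 = fully upright ... 9 = more than 75 % of plants flat) and boxes are
half-open pixel rectangles, so integer-corner areas are exact.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import TYPE_CHECKING, Optional

import numpy as np
import tifffile
from PIL import Image

if TYPE_CHECKING:  # pragma: no cover
    from .registration import RigidTransform2D

__all__ = [
    "BAND_INFO",
    "BandImage",
    "MultiSpectralCapture",
    "Box",
    "BoxSet",
    "load_band",
    "assemble_capture",
    "write_rgb",
    "read_boxes",
    "write_boxes",
]

#: band index -> (name, center wavelength nm, bandwidth nm)
BAND_INFO: dict[int, tuple[str, float, float]] = {
    1: ("blue", 475.0, 32.0),
    2: ("green", 560.0, 27.0),
    3: ("red", 668.0, 14.0),
    4: ("red_edge", 717.0, 12.0),
    5: ("nir", 842.0, 57.0),
    6: ("panchromatic", 634.5, 463.0),
}

_BAND_SUFFIX = re.compile(r"_([1-6])\.tiff?$", re.IGNORECASE)


@dataclass
class BandImage:
    """One spectral band as a float image normalised to [0, 1]."""

    pixels: np.ndarray
    band_index: int
    center_nm: Optional[float] = None
    bandwidth_nm: Optional[float] = None
    source_path: Optional[str] = None

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=np.float64)
        if self.pixels.ndim != 2:
            raise ValueError(f"band image must be 2-D, got shape {self.pixels.shape}")
        if self.band_index not in BAND_INFO:
            raise ValueError(f"band_index must be in 1..6, got {self.band_index}")
        if self.center_nm is None:
            _, self.center_nm, self.bandwidth_nm = BAND_INFO[self.band_index]

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape  # type: ignore[return-value]


@dataclass
class MultiSpectralCapture:
    """An ordered set of band rasters for one camera shot.

    ``aligned`` is False for raw sensor output; after registration every band
    shares the reference band's grid, ``transforms`` holds the fitted rigid
    transform per band (identity for the reference) and ``aligned`` is True.
    """

    capture_id: str
    bands: dict[int, BandImage]
    aligned: bool = False
    transforms: Optional[dict[int, "RigidTransform2D"]] = None
    #: per-band registration diagnostics, populated by register_capture
    registration: dict = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        if self.aligned:
            shapes = {b.shape for b in self.bands.values()}
            if len(shapes) > 1:
                raise ValueError(f"aligned capture has mixed band shapes: {shapes}")

    def band(self, index: int) -> BandImage:
        try:
            return self.bands[index]
        except KeyError:
            raise KeyError(f"capture {self.capture_id!r} has no band {index}") from None


@dataclass(frozen=True)
class Box:
    """Axis-aligned half-open box ``[x_min, x_max) x [y_min, y_max)``.

    ``class_id`` is the 1-based lodging severity (1..9); ``confidence`` is
    present for detections, None for ground truth.
    """

    class_id: int
    x_min: float
    y_min: float
    x_max: float
    y_max: float
    confidence: Optional[float] = None

    def __post_init__(self) -> None:
        if not (1 <= self.class_id <= 9):
            raise ValueError(f"class_id must be in 1..9, got {self.class_id}")
        if not (self.x_min < self.x_max and self.y_min < self.y_max):
            raise ValueError(
                f"degenerate box: ({self.x_min}, {self.y_min}, {self.x_max}, {self.y_max})"
            )
        if self.confidence is not None and not (0.0 <= self.confidence <= 1.0):
            raise ValueError(f"confidence must be in [0, 1], got {self.confidence}")

    @property
    def area(self) -> float:
        return (self.x_max - self.x_min) * (self.y_max - self.y_min)


@dataclass
class BoxSet:
    """Boxes belonging to one image, with the image geometry they refer to."""

    image_id: str
    image_width: int
    image_height: int
    boxes: list[Box] = field(default_factory=list)

    def __post_init__(self) -> None:
        for b in self.boxes:
            if b.x_min < 0 or b.y_min < 0 or b.x_max > self.image_width or b.y_max > self.image_height:
                raise ValueError(
                    f"box {b} exceeds image bounds {self.image_width}x{self.image_height}"
                )

    def __len__(self) -> int:
        return len(self.boxes)

    def __iter__(self):
        return iter(self.boxes)

    def filter_class(self, class_id: int) -> "BoxSet":
        return BoxSet(
            self.image_id,
            self.image_width,
            self.image_height,
            [b for b in self.boxes if b.class_id == class_id],
        )


def load_band(path) -> BandImage:
    """Load one single-channel 8- or 16-bit TIFF band.

    Integer codes are divided by the dtype maximum (255 or 65535) so the
    largest representable code maps exactly to 1.0.  The band index is parsed
    from the ``_<k>.tif`` filename suffix.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"band file not found: {path}")
    m = _BAND_SUFFIX.search(path.name)
    if m is None:
        raise ValueError(
            f"cannot parse band index from {path.name!r}; expected a '_<1-6>.tif' suffix"
        )
    band_index = int(m.group(1))
    raw = tifffile.imread(str(path))
    if raw.ndim != 2:
        raise ValueError(f"{path.name}: expected a single-channel TIFF, got shape {raw.shape}")
    if raw.dtype == np.uint16:
        pixels = raw.astype(np.float64) / 65535.0
    elif raw.dtype == np.uint8:
        pixels = raw.astype(np.float64) / 255.0
    else:
        raise ValueError(f"{path.name}: unsupported TIFF bit depth {raw.dtype}")
    return BandImage(pixels, band_index, source_path=str(path))


def assemble_capture(directory, capture_id: str) -> MultiSpectralCapture:
    """Collect the per-band TIFFs of one capture from a directory.

    Bands 1-5 are required; the panchromatic band 6 is included when present
    (it may have a different shape).  The result is unaligned.
    """
    directory = Path(directory)
    bands: dict[int, BandImage] = {}
    for k in range(1, 7):
        for ext in (".tif", ".tiff"):
            candidate = directory / f"{capture_id}_{k}{ext}"
            if candidate.exists():
                bands[k] = load_band(candidate)
                break
    missing = [k for k in range(1, 6) if k not in bands]
    if missing:
        raise FileNotFoundError(
            f"capture {capture_id!r} in {directory}: missing band(s) {missing}"
        )
    return MultiSpectralCapture(capture_id=capture_id, bands=bands, aligned=False)


def write_rgb(image: np.ndarray, path, bit_depth: int = 8) -> None:
    """Write a 3-channel array as a lossless 8-bit PNG or TIFF.

    Accepts either unit-range floats (max <= 1) or display-range [0, 255]
    values; both are clipped to range and rounded half-up.
    """
    image = np.asarray(image, dtype=np.float64)
    if image.ndim != 3 or image.shape[2] != 3:
        raise ValueError(f"expected an (H, W, 3) array, got shape {image.shape}")
    if not np.all(np.isfinite(image)):
        raise ValueError("image contains non-finite values")
    if bit_depth != 8:
        raise ValueError("only 8-bit output is supported")
    if image.size and image.max() <= 1.0:
        image = image * 255.0
    codes = np.floor(np.clip(image, 0.0, 255.0) + 0.5).astype(np.uint8)
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        tifffile.imwrite(str(path), codes)
    else:
        Image.fromarray(codes).save(str(path))


def _parse_box_line(parts: list[str], lineno: int, path, with_confidence: bool,
                    width: int, height: int) -> Box:
    expected = 6 if with_confidence else 5
    if len(parts) != expected:
        raise ValueError(
            f"{path}:{lineno}: expected {expected} fields, got {len(parts)}"
        )
    class_index = int(parts[0])
    if not (0 <= class_index <= 8):
        raise ValueError(f"{path}:{lineno}: on-disk class index must be 0..8, got {class_index}")
    cx, cy, w, h = (float(v) for v in parts[1:5])
    for name, v in (("cx", cx), ("cy", cy), ("w", w), ("h", h)):
        if not (0.0 <= v <= 1.0):
            raise ValueError(f"{path}:{lineno}: normalised {name}={v} outside [0, 1]")
    conf = float(parts[5]) if with_confidence else None
    x_min = (cx - w / 2.0) * width
    x_max = (cx + w / 2.0) * width
    y_min = (cy - h / 2.0) * height
    y_max = (cy + h / 2.0) * height
    # quantisation of the 6-decimal dialect may push corners a hair outside
    x_min, y_min = max(x_min, 0.0), max(y_min, 0.0)
    x_max, y_max = min(x_max, float(width)), min(y_max, float(height))
    return Box(class_index + 1, x_min, y_min, x_max, y_max, conf)


def read_boxes(path, image_width: int, image_height: int,
               with_confidence: bool = False) -> BoxSet:
    """Read a YOLO-dialect annotation file into pixel-space boxes.

    Disk geometry is normalised centre/size; disk classes are 0-based.  The
    returned boxes are half-open pixel rectangles with 1-based severity
    classes.
    """
    path = Path(path)
    boxes: list[Box] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            parts = line.split()
            if not parts:
                continue
            boxes.append(
                _parse_box_line(parts, lineno, path, with_confidence,
                                image_width, image_height)
            )
    return BoxSet(path.stem, image_width, image_height, boxes)


def write_boxes(boxset: BoxSet, path, with_confidence: bool = False) -> None:
    """Write a BoxSet in the YOLO text dialect (6-decimal precision)."""
    lines = []
    for b in boxset:
        w = (b.x_max - b.x_min) / boxset.image_width
        h = (b.y_max - b.y_min) / boxset.image_height
        cx = (b.x_min + b.x_max) / 2.0 / boxset.image_width
        cy = (b.y_min + b.y_max) / 2.0 / boxset.image_height
        fields = [str(b.class_id - 1)] + [f"{v:.6f}" for v in (cx, cy, w, h)]
        if with_confidence:
            if b.confidence is None:
                raise ValueError(f"box {b} has no confidence to write")
            fields.append(f"{b.confidence:.6f}")
        lines.append(" ".join(fields))
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))
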