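"""Band composites and vegetation indices from aligned captures.

A three-channel composite assigns spectral bands to display channels: the
(3, 2, 1) order — red, green, blue bands onto the R, G, B channels — gives
true colour; (4, 2, 1) substitutes the red-edge band for the red channel to
emphasise canopy structure invisible in true colour.

Vegetation indices are per-pixel reflectance ratios (band 1 = blue, 2 =
green, 3 = red, 5 = near-infrared):

    NDVI = (NIR - R) / (NIR + R)
    VARI = (G - R) / (G + R - B)
    GARI = (NIR - (G - (B - R))) / (NIR + (G - (B - R)))
    SABI = (NIR - R) / (B + G)

GARI is also available with the alternative denominator
``NIR - (G + (B - R))`` via ``as_printed=True``; some sources print that
variant.  Pixels whose denominator falls below a safety epsilon are masked
invalid rather than divided.
"""

from __future__ import annotations

from dataclasses import dataclass
import numpy as np

from .io_formats import MultiSpectralCapture

__all__ = ["BandOrder", "IndexMap", "INDEX_BANDS", "compose", "vegetation_index"]

BandOrder = tuple[int, int, int]

#: index name -> band indices required
INDEX_BANDS: dict[str, tuple[int, ...]] = {
    "NDVI": (3, 5),
    "VARI": (1, 2, 3),
    "GARI": (1, 2, 3, 5),
    "SABI": (1, 2, 3, 5),
}


@dataclass
class IndexMap:
    """A computed vegetation-index raster with its validity mask."""

    name: str
    values: np.ndarray
    valid_mask: np.ndarray


def _require_aligned(capture: MultiSpectralCapture, bands: tuple[int, ...]) -> None:
    if not capture.aligned:
        raise ValueError(
            f"capture {capture.capture_id!r} is not aligned; register it first"
        )
    missing = [b for b in bands if b not in capture.bands]
    if missing:
        raise KeyError(f"capture {capture.capture_id!r} missing band(s) {missing}")


def compose(capture: MultiSpectralCapture,
            order: BandOrder = (3, 2, 1)) -> np.ndarray:
    """Stack three bands of an aligned capture into an (H, W, 3) composite.

    Pure channel stacking: no value change, so extracting a channel returns
    the source band bit-exactly.
    """
    if len(order) != 3:
        raise ValueError(f"band order must name exactly 3 bands, got {order}")
    _require_aligned(capture, tuple(order))
    return np.stack([capture.bands[b].pixels for b in order], axis=-1)


def vegetation_index(capture: MultiSpectralCapture, name: str,
                     safe_epsilon: float = 1e-9,
                     as_printed: bool = False) -> IndexMap:
    """Evaluate a vegetation index over an aligned capture.

    ``as_printed`` switches GARI to the alternative denominator form; it has
    no effect on the other indices.
    """
    name = name.upper()
    if name not in INDEX_BANDS:
        raise ValueError(
            f"unknown index {name!r}; valid: {', '.join(INDEX_BANDS)}"
        )
    _require_aligned(capture, INDEX_BANDS[name])
    get = lambda b: capture.bands[b].pixels  # noqa: E731
    if name == "NDVI":
        num, den = get(5) - get(3), get(5) + get(3)
    elif name == "VARI":
        num, den = get(2) - get(3), get(2) + get(3) - get(1)
    elif name == "GARI":
        inner = get(2) - (get(1) - get(3))
        num = get(5) - inner
        den = get(5) - (get(2) + (get(1) - get(3))) if as_printed else get(5) + inner
    else:  # SABI
        num, den = get(5) - get(3), get(1) + get(2)
    valid = np.abs(den) >= safe_epsilon
    values = np.zeros_like(num)
    np.divide(num, den, out=values, where=valid)
    return IndexMap(name, values, valid)
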