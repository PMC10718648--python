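"""Radiometric enhancement presets for composed RGB imagery.

Two presets make spectral features of lodged canopy stand out in composed
three-channel images:

``haze_gamma`` — haze reduction plus gamma adjustment.  Per channel c, a
dark-level ``a_c`` (a scaled low percentile) anchors a haze-adjustment term
``t_c``, whose gamma power is scaled by a brightness term ``b_c`` (the mean
of the dark-corrected intensities weighted by that same power):

    a_c      = dark_scale * percentile(I_c, dark_percentile)
    t_c(x,y) = 1[I > a_c] * (1 + alpha_c * (I - a_c)) - beta_c   (floored)
    b_c      = mean((I - a_c) * t_c ** gamma_c)
    out      = b_c * t_c ** gamma_c                              (rescaled)

The indicator is multiplicative, ``t_c`` is clipped below at a small
positive floor before the fractional power, and the final channel is
linearly rescaled so its maximum maps to 1 — the raw product is not
naturally bounded.  Each of those resolutions is toggleable.

``stretch`` — per-channel linear contrast stretch to [0, 255] between each
channel's lower and upper intensity limits (channel min/max by default,
computed separately for every band).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

__all__ = [
    "HazeGammaParams",
    "ContrastLimits",
    "haze_gamma_adjust",
    "compute_limits",
    "stretch_contrast",
    "apply_preset",
    "PRESETS",
]


@dataclass
class HazeGammaParams:
    """Parameters of the haze & gamma preset.

    Defaults are the preset's published operating point: alpha 0.2 (haze
    intensity), beta 0.7 (curve-shape offset), gamma 0.6 (gamma exponent),
    with the dark level at one quarter of the 1st percentile.
    """

    alpha: tuple[float, float, float] = (0.2, 0.2, 0.2)
    beta: tuple[float, float, float] = (0.7, 0.7, 0.7)
    gamma: tuple[float, float, float] = (0.6, 0.6, 0.6)
    dark_percentile: float = 1.0
    dark_scale: float = 0.25
    floor: float = 1e-6
    rescale_output: bool = True

    def __post_init__(self) -> None:
        for name in ("alpha", "beta", "gamma"):
            v = getattr(self, name)
            if np.isscalar(v):
                setattr(self, name, (float(v),) * 3)
        if any(g <= 0 for g in self.gamma):
            raise ValueError(f"gamma must be positive, got {self.gamma}")
        if not 0.0 <= self.dark_percentile <= 100.0:
            raise ValueError("dark_percentile must lie in [0, 100]")
        if self.floor <= 0:
            raise ValueError("floor must be positive")


@dataclass
class ContrastLimits:
    """Per-channel (lower, upper) intensity limits for the stretch preset."""

    limits: Sequence[tuple[float, float]]

    def __post_init__(self) -> None:
        for lo, hi in self.limits:
            if lo >= hi:
                raise ValueError(f"lower limit {lo} must be below upper {hi}")


def _check_rgb(rgb: np.ndarray) -> np.ndarray:
    rgb = np.asarray(rgb, dtype=np.float64)
    if rgb.ndim != 3 or rgb.shape[2] != 3:
        raise ValueError(f"expected an (H, W, 3) array, got shape {rgb.shape}")
    return rgb


def haze_gamma_adjust(rgb: np.ndarray,
                      params: Optional[HazeGammaParams] = None) -> np.ndarray:
    """Apply the haze & gamma preset to a unit-range RGB image.

    Output is in [0, 1]; the map is monotone within each channel.
    """
    if params is None:
        params = HazeGammaParams()
    rgb = _check_rgb(rgb)
    if rgb.min() < 0.0 or rgb.max() > 1.0:
        raise ValueError("haze_gamma_adjust expects values in [0, 1]")
    out = np.empty_like(rgb)
    for c in range(3):
        chan = rgb[..., c]
        a = params.dark_scale * np.percentile(chan, params.dark_percentile)
        t = (chan > a) * (1.0 + params.alpha[c] * (chan - a)) - params.beta[c]
        t = np.maximum(t, params.floor)
        tg = t ** params.gamma[c]
        b = np.mean((chan - a) * tg)
        mapped = b * tg
        if params.rescale_output:
            peak = mapped.max()
            if peak > 0:
                mapped = mapped / peak
        out[..., c] = np.clip(mapped, 0.0, 1.0)
    return out


def compute_limits(band: np.ndarray) -> tuple[float, float]:
    """Lower and upper contrast limits of one band: its min and max."""
    band = np.asarray(band, dtype=np.float64)
    lo, hi = float(band.min()), float(band.max())
    if lo == hi:
        raise ValueError("degenerate contrast range: constant band")
    return lo, hi


def stretch_contrast(rgb: np.ndarray,
                     limits: Optional[ContrastLimits] = None) -> np.ndarray:
    """Linearly stretch each channel between its limits onto [0, 255].

    Limits default to each channel's own min/max, in which case the channel
    minimum maps exactly to 0 and the maximum exactly to 255.  Values beyond
    explicitly supplied (narrower) limits are clipped.
    """
    rgb = _check_rgb(rgb)
    if limits is None:
        limits = ContrastLimits([compute_limits(rgb[..., c]) for c in range(3)])
    out = np.empty_like(rgb)
    for c, (lo, hi) in enumerate(limits.limits):
        out[..., c] = np.clip((rgb[..., c] - lo) / (hi - lo) * 255.0, 0.0, 255.0)
    return out


PRESETS = ("haze_gamma", "stretch")


def apply_preset(rgb: np.ndarray, preset_name: str) -> np.ndarray:
    """Dispatch to a preset by name with default parameters.

    ``haze_gamma`` returns values in [0, 1]; ``stretch`` in [0, 255].
    """
    if preset_name == "haze_gamma":
        return haze_gamma_adjust(rgb)
    if preset_name == "stretch":
        return stretch_contrast(rgb)
    raise ValueError(
        f"unknown preset {preset_name!r}; valid presets: {', '.join(PRESETS)}"
    )
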