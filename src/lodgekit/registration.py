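"""Intensity-based rigid band-to-band registration.

Bands of a multi-spectral capture are taken by physically offset sensors, so
each band is misaligned against the others by a small rigid motion (rotation
plus translation).  This module aligns every band to a reference band (the
green band by default) by maximising a Gaussian-weighted mutual-information
similarity over rigid transforms with a (1+1)-evolution strategy, run
coarse-to-fine over an image pyramid.

Mutual information is computed from a joint intensity histogram of the
reference image and the warped moving image; the Gaussian weight map
emphasises the image centre, where scene overlap is guaranteed.  Pixels whose
warped source falls outside the moving image are excluded from the histogram
rather than filled, since a constant fill value would bias the metric.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Callable, Optional, Sequence

import numpy as np
from scipy import ndimage
from skimage.transform import resize

try:
    from numba import njit as _njit
    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover - numba is a normal install requirement
    _HAVE_NUMBA = False

from .io_formats import BandImage, MultiSpectralCapture

__all__ = [
    "RigidTransform2D",
    "MetricSettings",
    "OptimizerSettings",
    "JointHistogram",
    "RegistrationResult",
    "apply_transform",
    "gaussian_weights",
    "joint_histogram",
    "mutual_information",
    "evaluate_metric",
    "optimize_one_plus_one",
    "register_pair",
    "register_capture",
]


@dataclass(frozen=True)
class RigidTransform2D:
    """Rotation by ``theta`` about ``center`` followed by translation.

    A point maps as ``p' = R(theta) (p - center) + center + (tx, ty)`` with
    (x right, y down) pixel coordinates.  Applying the transform to an image
    moves its content along this map (so ``tx = 3`` shifts content 3 px to
    the right).
    """

    theta: float = 0.0
    tx: float = 0.0
    ty: float = 0.0
    center: tuple[float, float] = (0.0, 0.0)

    @classmethod
    def identity(cls, center: tuple[float, float] = (0.0, 0.0)) -> "RigidTransform2D":
        return cls(0.0, 0.0, 0.0, center)

    def map_points(self, xy: np.ndarray) -> np.ndarray:
        """Map an (N, 2) array of (x, y) points."""
        xy = np.asarray(xy, dtype=np.float64)
        c, s = math.cos(self.theta), math.sin(self.theta)
        ctr = np.asarray(self.center)
        rel = xy - ctr
        rot = np.stack([c * rel[..., 0] - s * rel[..., 1],
                        s * rel[..., 0] + c * rel[..., 1]], axis=-1)
        return rot + ctr + np.asarray([self.tx, self.ty])

    def inverse(self) -> "RigidTransform2D":
        c, s = math.cos(-self.theta), math.sin(-self.theta)
        tx, ty = -self.tx, -self.ty
        return RigidTransform2D(
            -self.theta, c * tx - s * ty, s * tx + c * ty, self.center
        )

    def compose(self, other: "RigidTransform2D") -> "RigidTransform2D":
        """Return the transform mapping ``p -> self(other(p))``."""
        if not np.allclose(self.center, other.center):
            raise ValueError("composition requires a common rotation center")
        c, s = math.cos(self.theta), math.sin(self.theta)
        tx = c * other.tx - s * other.ty + self.tx
        ty = s * other.tx + c * other.ty + self.ty
        return RigidTransform2D(self.theta + other.theta, tx, ty, self.center)

    def as_dict(self) -> dict:
        return {"theta": self.theta, "tx": self.tx, "ty": self.ty,
                "center": list(self.center)}

    @classmethod
    def from_dict(cls, d: dict) -> "RigidTransform2D":
        return cls(d["theta"], d["tx"], d["ty"], tuple(d["center"]))


@dataclass
class MetricSettings:
    """Similarity-metric configuration.

    sigma defaults to ``min(H, W) / 4`` of the image it is applied to;
    the weight-map center defaults to the image center.
    """

    bins: int = 64
    sigma: Optional[float] = None
    weighted: bool = True
    center: Optional[tuple[float, float]] = None

    def __post_init__(self) -> None:
        if self.bins < 2:
            raise ValueError(f"bins must be >= 2, got {self.bins}")
        if self.sigma is not None and self.sigma <= 0:
            raise ValueError(f"sigma must be positive, got {self.sigma}")


@dataclass
class OptimizerSettings:
    """(1+1)-evolution-strategy configuration.

    The search radius lives in a normalised parameter space (radians for
    rotation, image diagonals for translation); it grows by ``growth_factor``
    on every accepted step and shrinks by the same factor on rejection, and
    the search stops when the radius falls below ``epsilon`` or after
    ``max_iterations`` proposals.
    """

    growth_factor: float = 1.002
    max_iterations: int = 500
    initial_radius: float = 2.0e-4
    epsilon: float = 1.5e-6
    seed: int = 0
    pyramid_levels: int = 3

    def __post_init__(self) -> None:
        if self.growth_factor <= 1.0:
            raise ValueError("growth_factor must exceed 1")
        if self.epsilon >= self.initial_radius:
            raise ValueError("epsilon must be smaller than initial_radius")
        if self.pyramid_levels < 1:
            raise ValueError("pyramid_levels must be >= 1")


@dataclass
class JointHistogram:
    """Normalised joint intensity histogram with its marginals."""

    joint: np.ndarray
    marginal_ref: np.ndarray
    marginal_mov: np.ndarray
    total_weight: float


@dataclass
class RegistrationResult:
    transform: RigidTransform2D
    metric_value: float
    iterations: int
    converged: bool
    trace: list[tuple[int, float]] = field(default_factory=list)


def _pixels(image) -> np.ndarray:
    return np.asarray(image.pixels if isinstance(image, BandImage) else image,
                      dtype=np.float64)


def apply_transform(image, transform: RigidTransform2D,
                    output_shape: Optional[tuple[int, int]] = None
                    ) -> tuple[np.ndarray, np.ndarray]:
    """Warp an image by a rigid transform with bilinear resampling.

    The image content moves along the transform's point map; internally each
    output pixel is inverse-mapped into the source and sampled bilinearly.
    Returns ``(warped, valid)`` where ``valid`` marks output pixels whose
    source location lies inside the input; invalid pixels are filled with 0.
    """
    pix = _pixels(image)
    if not np.all(np.isfinite([transform.theta, transform.tx, transform.ty])):
        raise ValueError("non-finite transform parameters")
    if output_shape is None:
        output_shape = pix.shape
    h_out, w_out = output_shape
    ys, xs = np.mgrid[0:h_out, 0:w_out].astype(np.float64)
    pts = np.stack([xs.ravel(), ys.ravel()], axis=-1)
    src = transform.inverse().map_points(pts)
    sx = src[:, 0].reshape(h_out, w_out)
    sy = src[:, 1].reshape(h_out, w_out)
    h_in, w_in = pix.shape
    valid = (sx >= 0.0) & (sx <= w_in - 1.0) & (sy >= 0.0) & (sy <= h_in - 1.0)
    warped = ndimage.map_coordinates(pix, [sy, sx], order=1, mode="constant",
                                     cval=0.0, prefilter=False)
    warped[~valid] = 0.0
    return warped, valid


def gaussian_weights(shape: tuple[int, int], sigma: float,
                     center: Optional[tuple[float, float]] = None) -> np.ndarray:
    """Isotropic Gaussian weight map ``exp(-(d^2) / (2 sigma^2))``.

    ``center`` is (x_c, y_c) and defaults to the image center
    ``((W-1)/2, (H-1)/2)``, where the weight is exactly 1.
    """
    if sigma <= 0:
        raise ValueError(f"sigma must be positive, got {sigma}")
    h, w = shape
    if center is None:
        center = ((w - 1) / 2.0, (h - 1) / 2.0)
    xc, yc = center
    ys, xs = np.mgrid[0:h, 0:w].astype(np.float64)
    d2 = (xs - xc) ** 2 + (ys - yc) ** 2
    return np.exp(-d2 / (2.0 * sigma ** 2))


def joint_histogram(ref: np.ndarray, mov: np.ndarray,
                    valid: Optional[np.ndarray] = None, bins: int = 64,
                    weights: Optional[np.ndarray] = None) -> JointHistogram:
    """Accumulate the (optionally weighted) joint intensity histogram.

    Intensities in [0, 1] are split into ``bins`` equal-width bins, with the
    value 1.0 assigned to the last bin.  Each valid pixel contributes its
    weight (1 if unweighted) to one joint cell; the table is normalised by
    the total contributed weight and the marginals are its row/column sums.
    """
    ref = np.asarray(ref, dtype=np.float64)
    mov = np.asarray(mov, dtype=np.float64)
    if ref.shape != mov.shape:
        raise ValueError(f"shape mismatch: {ref.shape} vs {mov.shape}")
    if valid is None:
        valid = np.ones(ref.shape, dtype=bool)
    if weights is None:
        w = np.ones(ref.shape, dtype=np.float64)[valid]
    else:
        if weights.shape != ref.shape:
            raise ValueError("weights shape must match the images")
        w = np.asarray(weights, dtype=np.float64)[valid]
    if w.size == 0:
        raise ValueError("no valid pixels to accumulate")
    bi = np.minimum((ref[valid] * bins).astype(np.intp), bins - 1)
    bj = np.minimum((mov[valid] * bins).astype(np.intp), bins - 1)
    counts = np.bincount(bi * bins + bj, weights=w,
                         minlength=bins * bins).reshape(bins, bins)
    total = float(w.sum())
    if total <= 0:
        raise ValueError("total histogram weight is zero")
    joint = counts / total
    return JointHistogram(joint, joint.sum(axis=1), joint.sum(axis=0), total)


def mutual_information(hist: JointHistogram) -> float:
    """Mutual information in bits of a normalised joint histogram.

    ``MI = sum_ij p_ij log2(p_ij / (p_i p_j))``; empty cells contribute 0.
    """
    joint = hist.joint
    if abs(joint.sum() - 1.0) > 1e-8:
        raise ValueError("joint histogram is not normalised")
    pi = hist.marginal_ref[:, None]
    pj = hist.marginal_mov[None, :]
    nz = joint > 0.0
    mi = float(np.sum(joint[nz] * np.log2(joint[nz] / (pi * pj + 0.0)[nz])))
    return max(mi, 0.0)


def evaluate_metric(ref, mov, transform: RigidTransform2D,
                    settings: Optional[MetricSettings] = None) -> float:
    """Similarity of ``ref`` against ``mov`` warped by ``transform``.

    This is the registration objective: the moving image is warped, a joint
    histogram is accumulated over the valid overlap (Gaussian-weighted when
    enabled), and its mutual information in bits is returned.
    """
    if settings is None:
        settings = MetricSettings()
    ref_pix = _pixels(ref)
    warped, valid = apply_transform(mov, transform, output_shape=ref_pix.shape)
    if not valid.any():
        raise ValueError("empty valid region after transformation")
    weights = None
    if settings.weighted:
        sigma = settings.sigma if settings.sigma is not None else min(ref_pix.shape) / 4.0
        weights = gaussian_weights(ref_pix.shape, sigma, settings.center)
    hist = joint_histogram(ref_pix, warped, valid, settings.bins, weights)
    return mutual_information(hist)


if _HAVE_NUMBA:

    @_njit(cache=False)
    def _accumulate_joint(mov, ref_offsets, weights, c, s, cx, cy, dx, dy,
                          bins, counts):  # pragma: no cover - jitted
        """Fused inverse-map + bilinear sample + weighted joint histogram."""
        h_out, w_out = ref_offsets.shape
        hm, wm = mov.shape
        total = 0.0
        for y in range(h_out):
            ry = y - cy
            for x in range(w_out):
                rx = x - cx
                sx = c * rx - s * ry + dx
                sy = s * rx + c * ry + dy
                if sx >= 0.0 and sx <= wm - 1.0 and sy >= 0.0 and sy <= hm - 1.0:
                    x0 = int(sx)
                    y0 = int(sy)
                    fx = sx - x0
                    fy = sy - y0
                    x1 = x0 + 1 if x0 < wm - 1 else x0
                    y1 = y0 + 1 if y0 < hm - 1 else y0
                    v = (mov[y0, x0] * (1.0 - fx) * (1.0 - fy)
                         + mov[y0, x1] * fx * (1.0 - fy)
                         + mov[y1, x0] * (1.0 - fx) * fy
                         + mov[y1, x1] * fx * fy)
                    bj = int(v * bins)
                    if bj > bins - 1:
                        bj = bins - 1
                    w_ = weights[y, x]
                    counts[ref_offsets[y, x] + bj] += w_
                    total += w_
        return total


class _MetricEvaluator:
    """Registration objective caching everything that is constant per level.

    The reference image's bin indices and the weight map never change while
    optimising one pyramid level, so only the moving image is re-warped per
    proposal.  With numba available the warp and histogram accumulation run
    as one fused pass; otherwise a vectorised numpy path is used.
    """

    def __init__(self, ref: np.ndarray, mov: np.ndarray,
                 settings: MetricSettings) -> None:
        self.mov = np.ascontiguousarray(mov)
        self.bins = settings.bins
        self.shape = ref.shape
        ref_bins = np.minimum((ref * settings.bins).astype(np.int64),
                              settings.bins - 1)
        self.ref_offsets = np.ascontiguousarray(ref_bins * settings.bins)
        if settings.weighted:
            sigma = settings.sigma if settings.sigma is not None else min(ref.shape) / 4.0
            self.weights = gaussian_weights(ref.shape, sigma, settings.center)
        else:
            self.weights = np.ones(ref.shape, dtype=np.float64)
        h, w = ref.shape
        if not _HAVE_NUMBA:
            ys, xs = np.mgrid[0:h, 0:w]
            self.xs = xs.astype(np.float64)
            self.ys = ys.astype(np.float64)

    def _joint_counts(self, transform: RigidTransform2D) -> tuple[np.ndarray, float]:
        inv = transform.inverse()
        c, s = math.cos(inv.theta), math.sin(inv.theta)
        cx, cy = inv.center
        dx, dy = inv.tx + cx, inv.ty + cy
        if _HAVE_NUMBA:
            counts = np.zeros(self.bins * self.bins, dtype=np.float64)
            total = _accumulate_joint(self.mov, self.ref_offsets, self.weights,
                                      c, s, cx, cy, dx, dy, self.bins, counts)
            return counts, total
        rx = self.xs - cx
        ry = self.ys - cy
        sx = c * rx - s * ry + dx
        sy = s * rx + c * ry + dy
        h, w = self.mov.shape
        valid = (sx >= 0.0) & (sx <= w - 1.0) & (sy >= 0.0) & (sy <= h - 1.0)
        warped = ndimage.map_coordinates(self.mov, [sy, sx], order=1,
                                         mode="constant", cval=0.0,
                                         prefilter=False)
        # invalid pixels keep index 0 but contribute zero weight
        wts = self.weights * valid
        bj = np.minimum((warped * self.bins).astype(np.int64), self.bins - 1)
        counts = np.bincount((self.ref_offsets + bj).ravel(),
                             weights=wts.ravel(),
                             minlength=self.bins * self.bins)
        return counts, float(wts.sum())

    def __call__(self, transform: RigidTransform2D) -> float:
        counts, total = self._joint_counts(transform)
        if total <= 0.0:
            return -np.inf
        joint = counts.reshape(self.bins, self.bins) / total
        pi = joint.sum(axis=1)[:, None]
        pj = joint.sum(axis=0)[None, :]
        nz = joint > 0.0
        return float(np.sum(joint[nz] * np.log2(joint[nz] / (pi * pj)[nz])))


def optimize_one_plus_one(objective: Callable[[RigidTransform2D], float],
                          settings: OptimizerSettings,
                          initial: RigidTransform2D,
                          scales: Sequence[float]) -> RegistrationResult:
    """Maximise an objective over rigid transforms with a (1+1)-ES.

    Each iteration perturbs the parent parameters (theta, tx, ty) by
    ``radius * scales * N(0, I)``; strictly improving proposals are accepted
    and grow the radius by the growth factor, rejections shrink it by the
    same factor.  The search stops when the radius drops below epsilon
    (converged) or at the iteration cap.
    """
    rng = np.random.default_rng(settings.seed)
    scales = np.asarray(scales, dtype=np.float64)
    params = np.array([initial.theta, initial.tx, initial.ty])
    center = initial.center

    def to_transform(p: np.ndarray) -> RigidTransform2D:
        return RigidTransform2D(p[0], p[1], p[2], center)

    f_parent = objective(to_transform(params))
    if not np.isfinite(f_parent):
        raise RuntimeError("objective is non-finite at the initial transform")
    radius = settings.initial_radius
    trace: list[tuple[int, float]] = [(0, f_parent)]
    iterations = 0
    converged = False
    for i in range(1, settings.max_iterations + 1):
        iterations = i
        candidate = params + radius * scales * rng.standard_normal(3)
        f_cand = objective(to_transform(candidate))
        if f_cand == -np.inf:
            # proposal warped the image fully out of frame: reject it
            f_cand = -np.inf
        elif not np.isfinite(f_cand):
            raise RuntimeError(
                f"objective became non-finite at iteration {i}: {candidate}"
            )
        if f_cand > f_parent:
            params, f_parent = candidate, f_cand
            radius *= settings.growth_factor
            trace.append((i, f_parent))
        else:
            radius /= settings.growth_factor
        if radius < settings.epsilon:
            converged = True
            break
    return RegistrationResult(to_transform(params), f_parent, iterations,
                              converged, trace)


def _downscale(image: np.ndarray, factor: int) -> np.ndarray:
    if factor == 1:
        return image
    h, w = image.shape
    out_shape = (max(1, round(h / factor)), max(1, round(w / factor)))
    return resize(image, out_shape, order=1, anti_aliasing=True,
                  preserve_range=True).astype(np.float64)


def register_pair(ref, mov, metric_settings: Optional[MetricSettings] = None,
                  optimizer_settings: Optional[OptimizerSettings] = None,
                  presmooth_sigma: float = 0.75) -> RegistrationResult:
    """Register a moving band onto a reference band.

    Runs the (1+1)-ES over a coarse-to-fine pyramid (factor 2 per level);
    each finer level starts from the previous estimate with translations
    doubled.  The returned transform maps the moving image onto the
    reference grid (i.e. warping ``mov`` by it aligns it with ``ref``).

    Both images are pre-smoothed with a small Gaussian (``presmooth_sigma``
    pixels, 0 disables it) before metric evaluation.  Bilinear resampling
    averages away independent sensor noise at off-grid offsets, which lifts
    mutual information at half-pixel misalignments; correlating the noise
    over neighbouring pixels suppresses that artifact without displacing
    the metric's peak.
    """
    if metric_settings is None:
        metric_settings = MetricSettings()
    if optimizer_settings is None:
        optimizer_settings = OptimizerSettings()
    ref_pix = _pixels(ref)
    mov_pix = _pixels(mov)
    if np.ptp(ref_pix) == 0.0 or np.ptp(mov_pix) == 0.0:
        raise ValueError("no intensity structure: constant image")
    if mov_pix.shape != ref_pix.shape:
        mov_pix = resize(mov_pix, ref_pix.shape, order=1, anti_aliasing=True,
                         preserve_range=True).astype(np.float64)
    if presmooth_sigma > 0:
        ref_pix = ndimage.gaussian_filter(ref_pix, presmooth_sigma)
        mov_pix = ndimage.gaussian_filter(mov_pix, presmooth_sigma)
    mov_pix = np.clip(mov_pix, 0.0, 1.0)
    ref_pix = np.clip(ref_pix, 0.0, 1.0)

    levels = optimizer_settings.pyramid_levels
    estimate: Optional[RigidTransform2D] = None
    result: Optional[RegistrationResult] = None
    for level in range(levels - 1, -1, -1):
        factor = 2 ** level
        ref_l = _downscale(ref_pix, factor)
        mov_l = _downscale(mov_pix, factor)
        h, w = ref_l.shape
        center = ((w - 1) / 2.0, (h - 1) / 2.0)
        if estimate is None:
            initial = RigidTransform2D.identity(center)
        else:
            initial = RigidTransform2D(estimate.theta, estimate.tx * 2.0,
                                       estimate.ty * 2.0, center)
        diag = math.hypot(h, w)
        evaluator = _MetricEvaluator(ref_l, mov_l, metric_settings)
        level_settings = replace(optimizer_settings,
                                 seed=optimizer_settings.seed + level)
        result = optimize_one_plus_one(evaluator, level_settings, initial,
                                       scales=(1.0, diag, diag))
        estimate = result.transform
    assert result is not None
    return result


def register_capture(capture: MultiSpectralCapture, reference_band: int = 2,
                     metric_settings: Optional[MetricSettings] = None,
                     optimizer_settings: Optional[OptimizerSettings] = None
                     ) -> MultiSpectralCapture:
    """Align every band of a capture onto the reference band's grid.

    The panchromatic band, captured at a different resolution, is first
    bilinearly resampled to the reference shape and then registered like any
    other band.  Per-band fitted transforms and diagnostics are recorded on
    the returned capture; a band that fails to converge is still resampled
    with its best-seen transform and flagged.
    """
    if reference_band not in capture.bands:
        raise KeyError(f"reference band {reference_band} missing from capture")
    ref = capture.bands[reference_band]
    ref_shape = ref.shape
    h, w = ref_shape
    center = ((w - 1) / 2.0, (h - 1) / 2.0)
    aligned_bands: dict[int, BandImage] = {}
    transforms: dict[int, RigidTransform2D] = {}
    results: dict[int, RegistrationResult] = {}
    for idx, band in sorted(capture.bands.items()):
        if idx == reference_band:
            aligned_bands[idx] = BandImage(ref.pixels.copy(), idx,
                                           source_path=band.source_path)
            transforms[idx] = RigidTransform2D.identity(center)
            continue
        pix = band.pixels
        if pix.shape != ref_shape:
            pix = np.clip(resize(pix, ref_shape, order=1, anti_aliasing=True,
                                 preserve_range=True), 0.0, 1.0)
        res = register_pair(ref.pixels, pix, metric_settings, optimizer_settings)
        warped, _ = apply_transform(pix, res.transform, output_shape=ref_shape)
        aligned_bands[idx] = BandImage(warped, idx, source_path=band.source_path)
        transforms[idx] = res.transform
        results[idx] = res
    out = MultiSpectralCapture(capture.capture_id, aligned_bands, aligned=True,
                               transforms=transforms)
    out.registration = results
    return out
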