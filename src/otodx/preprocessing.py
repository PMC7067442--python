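"""Frame quality filtering and ROI extraction.

Raw otoscope frames are screened for defocus with the variance-of-Laplacian
focus measure; frames below a configurable threshold are discarded.  The
bright circular aperture of the speculum tip is then located with a circular
Hough transform over an edge map, and a fixed-size crop (420x380 by default)
centered on the detected circle becomes the region of interest for feature
extraction.

Coordinate convention: arrays are indexed 0-based ``(row, col)`` internally;
circle centers are reported as ``(x, y)`` image coordinates.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage import filters
from skimage.transform import hough_circle

#: 3x3 four-neighbor Laplacian kernel applied to the luminance channel.
LAPLACIAN_KERNEL = np.array([[0.0, 1.0, 0.0], [1.0, -4.0, 1.0], [0.0, 1.0, 0.0]])

#: Default Hough radius search range for 640x480 frames, pixels.
DEFAULT_RADIUS_RANGE = (100, 220)

#: Default crop size (width, height).
DEFAULT_CROP_SIZE = (420, 380)


class NoCircleError(RuntimeError):
    """The Hough accumulator produced no peak above the score floor."""


@dataclass(frozen=True)
class FrameQualityReport:
    blur_score: float
    passes: bool
    threshold_used: float


@dataclass(frozen=True)
class DetectedCircle:
    """Aperture circle: ``center`` is (x, y) in pixels, ``score`` the
    normalized Hough accumulator strength (fraction of perimeter supported
    by edge pixels)."""

    center: tuple[float, float]
    radius: float
    score: float


@dataclass
class ROIImage:
    pixels: np.ndarray  # uint8 (crop_h, crop_w, 3)
    source_circle: DetectedCircle


def luminance(image: np.ndarray) -> np.ndarray:
    """Rec. 601 luminance of an RGB raster (pass-through for grayscale)."""
    arr = np.asarray(image, dtype=float)
    if arr.ndim == 2:
        return arr
    if arr.ndim == 3 and arr.shape[2] == 3:
        return arr[..., 0] * 0.299 + arr[..., 1] * 0.587 + arr[..., 2] * 0.114
    raise ValueError(f"expected 2-D grayscale or (H, W, 3) RGB, got shape {arr.shape}")


def laplacian_variance(image: np.ndarray) -> float:
    """Variance of the 3x3 Laplacian response of the luminance channel.

    Symmetric (reflect) boundary handling.  Invariant to adding a constant
    to every pixel; scales as alpha^2 under multiplicative contrast alpha.
    Zero for a constant image.
    """
    lum = luminance(image)
    if lum.size == 0:
        raise ValueError("empty image")
    response = ndimage.convolve(lum, LAPLACIAN_KERNEL, mode="reflect")
    return float(np.var(response))


def select_sharp_frames(
    frames: list[np.ndarray], threshold: float
) -> tuple[list[np.ndarray], list[FrameQualityReport]]:
    """Keep frames whose blur score is at or above ``threshold`` (order preserved)."""
    if threshold < 0:
        raise ValueError("threshold must be nonnegative")
    kept, reports = [], []
    for frame in frames:
        score = laplacian_variance(frame)
        ok = score >= threshold
        reports.append(FrameQualityReport(blur_score=score, passes=ok, threshold_used=threshold))
        if ok:
            kept.append(frame)
    return kept, reports


def calibrate_blur_threshold(scores: list[float] | np.ndarray) -> float:
    """Otsu split of a set of blur scores, for choosing the sharpness cut.

    The focus threshold is application-defined; this helper picks the value
    separating the two score clusters of a mixed sharp/blurred frame set.
    """
    scores = np.asarray(scores, dtype=float)
    if scores.size < 2 or np.ptp(scores) == 0:
        raise ValueError("need at least two distinct scores to calibrate")
    return float(filters.threshold_otsu(scores, nbins=256))


def detect_aperture_circle(
    frame: np.ndarray,
    radius_range: tuple[int, int] = DEFAULT_RADIUS_RANGE,
    score_floor: float = 0.25,
    radius_step: int = 1,
) -> DetectedCircle:
    """Locate the otoscope aperture with a circular Hough transform.

    A Sobel gradient-magnitude edge map (Otsu-binarized) feeds a circular
    Hough accumulator over ``radius_range`` with ``radius_step`` px bins.  The
    highest-scoring circle wins; exact ties break toward the larger radius,
    then the smaller center row, then the smaller center column.  Raises
    :class:`NoCircleError` when no accumulator peak reaches ``score_floor``
    (e.g. an edge-free uniform frame).
    """
    lum = luminance(frame)
    h, w = lum.shape
    r_lo, r_hi = int(radius_range[0]), int(radius_range[1])
    if not (0 < r_lo <= r_hi) or r_hi > max(h, w):
        raise ValueError(f"radius_range {radius_range} invalid for frame {w}x{h}")

    grad = filters.sobel(lum)
    if grad.max() <= 1e-9:
        raise NoCircleError("frame contains no edges")
    edges = grad > filters.threshold_otsu(grad)
    if not edges.any():
        raise NoCircleError("frame contains no edges")

    radii = np.arange(r_lo, r_hi + 1, max(1, int(radius_step)))
    accum = hough_circle(edges, radii, normalize=True)
    best = float(accum.max())
    if best < score_floor:
        raise NoCircleError(f"best accumulator score {best:.3f} below floor {score_floor}")

    # tie-break: larger radius, then smaller row, then smaller column
    cand = np.argwhere(accum >= best - 1e-12)
    cand = sorted(cand, key=lambda rc: (-radii[rc[0]], rc[1], rc[2]))
    ri, row, col = cand[0]
    return DetectedCircle(center=(float(col), float(row)), radius=float(radii[ri]), score=best)


def crop_roi(
    frame: np.ndarray,
    circle: DetectedCircle,
    crop_size: tuple[int, int] = DEFAULT_CROP_SIZE,
) -> ROIImage:
    """Axis-aligned ``crop_size`` (width, height) window centered on the circle.

    Regions falling outside the frame are zero-padded so the output shape is
    always exact.
    """
    arr = np.asarray(frame)
    if arr.ndim == 2:
        arr = np.stack([arr] * 3, axis=-1)
    h, w = arr.shape[:2]
    cw, ch = int(crop_size[0]), int(crop_size[1])
    cx, cy = int(round(circle.center[0])), int(round(circle.center[1]))
    top, left = cy - ch // 2, cx - cw // 2

    out = np.zeros((ch, cw, 3), dtype=arr.dtype)
    src_t, src_l = max(0, top), max(0, left)
    src_b, src_r = min(h, top + ch), min(w, left + cw)
    if src_t < src_b and src_l < src_r:
        out[src_t - top : src_b - top, src_l - left : src_r - left] = arr[src_t:src_b, src_l:src_r]
    return ROIImage(pixels=out, source_circle=circle)


def preprocess_frame(
    frame: np.ndarray,
    blur_threshold: float | None = None,
    radius_range: tuple[int, int] = DEFAULT_RADIUS_RANGE,
    crop_size: tuple[int, int] = DEFAULT_CROP_SIZE,
) -> ROIImage:
    """Full preprocessing of a raw frame: blur gate, aperture detection, crop.

    Raises ``ValueError`` when the frame fails the blur gate, and
    :class:`NoCircleError` when no aperture is found.
    """
    if blur_threshold is not None:
        score = laplacian_variance(frame)
        if score < blur_threshold:
            raise ValueError(f"frame rejected: blur score {score:.2f} below threshold {blur_threshold:.2f}")
    circle = detect_aperture_circle(frame, radius_range=radius_range)
    return crop_roi(frame, circle, crop_size=crop_size)
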