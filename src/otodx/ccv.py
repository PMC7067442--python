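"""Color coherence vector (CCV) features.

A CCV splits each quantized color's pixels into *coherent* ones (members of
a large same-color 8-connected component) and *incoherent* ones (members of
small components), capturing the spatial distribution of color rather than
just its histogram.  The pipeline: 3x3 local-mean smoothing, uniform
quantization of RGB to N = 27 colors (3 levels per channel), connected
component labeling, and per-color coherent/incoherent counting.  The
default feature is the 27-dimensional coherent fraction per color; the
classic 54-dimensional (alpha, beta) concatenation is also available.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage import measure


class CCVError(ValueError):
    pass


@dataclass
class CoherenceVector:
    """Per-color coherent (alpha) and incoherent (beta) pixel counts."""

    alpha: np.ndarray  # (n_colors,) int
    beta: np.ndarray  # (n_colors,) int
    n_colors: int
    tau: int

    @property
    def total_pixels(self) -> int:
        return int(self.alpha.sum() + self.beta.sum())


def smooth_local_average(image: np.ndarray) -> np.ndarray:
    """Replace each pixel by its 3x3 neighborhood mean, per channel.

    Reflect borders; results are rounded to the nearest integer
    (numpy round-half-to-even) and returned as uint8.
    """
    arr = np.asarray(image, dtype=float)
    smoothed = ndimage.uniform_filter(arr, size=(3, 3, 1) if arr.ndim == 3 else 3, mode="reflect")
    return np.clip(np.rint(smoothed), 0, 255).astype(np.uint8)


def quantize_colors(image: np.ndarray, n_colors: int = 27) -> np.ndarray:
    """Uniformly bin each RGB channel into cbrt(n_colors) levels.

    For the default 27 colors each channel has 3 levels with bin edges at
    1/3 and 2/3 of the 0-255 range (85 and 170); intervals are half-open
    with the top edge closed.  Color index = r_bin*9 + g_bin*3 + b_bin.
    """
    levels = round(n_colors ** (1.0 / 3.0))
    if levels**3 != n_colors:
        raise CCVError(f"n_colors must be a perfect cube for uniform binning, got {n_colors}")
    arr = np.asarray(image)
    if arr.ndim != 3 or arr.shape[2] != 3:
        raise CCVError("expected an (H, W, 3) RGB raster")
    edges = np.array([255.0 * (i + 1) / levels for i in range(levels - 1)])
    bins = np.searchsorted(edges, arr.astype(float), side="right")
    return (bins[..., 0] * levels**2 + bins[..., 1] * levels + bins[..., 2]).astype(np.int32)


def connected_components(indices: np.ndarray, connectivity: int = 8) -> tuple[np.ndarray, np.ndarray]:
    """Label maximal same-color connected regions.

    Returns (labels, sizes): labels start at 1, ``sizes[l-1]`` is the pixel
    count of component l.  8-connectivity by default (diagonal neighbors of
    the same color join).
    """
    if connectivity not in (4, 8):
        raise CCVError("connectivity must be 4 or 8")
    labels = measure.label(indices, background=-1, connectivity=2 if connectivity == 8 else 1)
    sizes = np.bincount(labels.ravel())[1:]
    return labels, sizes


def coherence_vector(
    indices: np.ndarray,
    components: tuple[np.ndarray, np.ndarray],
    tau: int,
    n_colors: int = 27,
) -> CoherenceVector:
    """Count coherent/incoherent pixels per color.

    A pixel is coherent when its component holds at least ``tau`` pixels.
    Conservation: sum(alpha) + sum(beta) equals the raster's pixel count.
    """
    if tau < 1:
        raise CCVError("tau must be >= 1")
    labels, sizes = components
    coherent = sizes[labels - 1] >= tau
    idx = indices.ravel()
    coh = coherent.ravel()
    alpha = np.bincount(idx[coh], minlength=n_colors)
    beta = np.bincount(idx[~coh], minlength=n_colors)
    return CoherenceVector(alpha=alpha, beta=beta, n_colors=n_colors, tau=tau)


def to_feature(ccv: CoherenceVector, mode: str = "paper_27") -> np.ndarray:
    """Collapse a CCV into a feature vector.

    ``paper_27``: per-color coherent fraction alpha_i / max(1, alpha_i+beta_i),
    matching the reported 27-dimensional feature space.  ``classic_54``:
    concatenated (alpha, beta) normalized by total pixels.
    """
    if mode == "paper_27":
        denom = np.maximum(1, ccv.alpha + ccv.beta)
        return ccv.alpha / denom
    if mode == "classic_54":
        total = max(1, ccv.total_pixels)
        return np.concatenate([ccv.alpha, ccv.beta]) / total
    raise CCVError(f"unknown CCV feature mode {mode!r}")


def ccv_features(
    image: np.ndarray,
    n_colors: int = 27,
    tau: int | None = None,
    mode: str = "paper_27",
) -> np.ndarray:
    """End-to-end CCV feature vector: smooth, quantize, label, count, collapse.

    ``tau`` defaults to 1% of the raster's pixel count (at least 1).
    """
    arr = np.asarray(image)
    if tau is None:
        tau = max(1, round(0.01 * arr.shape[0] * arr.shape[1]))
    smoothed = smooth_local_average(arr)
    indices = quantize_colors(smoothed, n_colors=n_colors)
    comps = connected_components(indices)
    ccv = coherence_vector(indices, comps, tau=tau, n_colors=n_colors)
    return to_feature(ccv, mode=mode)
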