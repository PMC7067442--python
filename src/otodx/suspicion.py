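"""Class-conditional suspicion-area segmentation and overlay rendering.

Given an ROI and its predicted ear condition, the region that motivates the
diagnosis is segmented with class-specific HSV thresholds — yellow-brown
high-saturation pixels for earwax, bright desaturated pixels for
myringosclerosis, and a dark perforation core united with its adjacent
red rim for chronic otitis media — cleaned up with 3x3 morphological
opening and closing, and small components dropped.  ``highlight`` renders
the mask contour (and a translucent fill) on a copy of the image; a normal
prediction passes the image through untouched.

Hue is measured in degrees [0, 360); saturation and value in [0, 1].
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage import color

from .synthetic import CLASSES

#: Default per-class segmentation thresholds.
HIGHLIGHT_DEFAULTS = {
    "earwax": {"hue_band": (18.0, 52.0), "sat_min": 0.40, "val_min": 0.15, "min_area_fraction": 0.002},
    "myringosclerosis": {"val_min": 0.85, "sat_max": 0.15, "min_area_fraction": 0.002},
    "otitis_media": {
        "core_val_max": 0.25,
        "rim_hue_max": 15.0,
        "rim_hue_min_wrap": 345.0,
        "rim_sat_min": 0.45,
        "rim_reach_px": 14,
        "min_area_fraction": 0.01,
    },
    "fill_alpha": 0.25,
    "contour_rgb": (0, 255, 0),
}


@dataclass
class SuspicionMask:
    mask: np.ndarray  # bool, ROI shape
    predicted_class: str
    method_params: dict = field(default_factory=dict)

    @property
    def empty(self) -> bool:
        return not bool(self.mask.any())


@dataclass
class HighlightResult:
    image: np.ndarray
    mask: SuspicionMask | None
    annotation: str
    no_region_found: bool = False


def _hsv(pixels: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    hsv = color.rgb2hsv(np.asarray(pixels, dtype=np.uint8))
    return hsv[..., 0] * 360.0, hsv[..., 1], hsv[..., 2]


def _cleanup(mask: np.ndarray, min_area: int) -> np.ndarray:
    footprint = np.ones((3, 3), dtype=bool)
    # edge-pad so opening/closing see no artificial background at the border
    padded = np.pad(mask, 2, mode="edge")
    padded = ndimage.binary_opening(padded, structure=footprint)
    padded = ndimage.binary_closing(padded, structure=footprint)
    mask = padded[2:-2, 2:-2]
    if min_area > 1:
        labels, n = ndimage.label(mask, structure=np.ones((3, 3)))
        if n:
            sizes = np.bincount(labels.ravel())
            mask &= sizes[labels] >= min_area
    return mask


def _min_area(shape: tuple[int, ...], params: dict) -> int:
    return max(1, int(round(params["min_area_fraction"] * shape[0] * shape[1])))


def segment_earwax(roi: np.ndarray, params: dict | None = None) -> SuspicionMask:
    """Yellow-brown, saturated pixels — cerumen against the pink membrane."""
    p = {**HIGHLIGHT_DEFAULTS["earwax"], **(params or {})}
    hue, sat, val = _hsv(roi)
    lo, hi = p["hue_band"]
    mask = (hue >= lo) & (hue <= hi) & (sat >= p["sat_min"]) & (val >= p["val_min"])
    mask = _cleanup(mask, _min_area(mask.shape, p))
    return SuspicionMask(mask=mask, predicted_class="earwax", method_params=p)


def segment_myringosclerosis(roi: np.ndarray, params: dict | None = None) -> SuspicionMask:
    """Bright, desaturated pixels — calcified white plaques."""
    p = {**HIGHLIGHT_DEFAULTS["myringosclerosis"], **(params or {})}
    _, sat, val = _hsv(roi)
    mask = (val >= p["val_min"]) & (sat <= p["sat_max"])
    mask = _cleanup(mask, _min_area(mask.shape, p))
    return SuspicionMask(mask=mask, predicted_class="myringosclerosis", method_params=p)


def segment_perforation(roi: np.ndarray, params: dict | None = None) -> SuspicionMask:
    """Dark perforation core united with its adjacent red-hued rim."""
    p = {**HIGHLIGHT_DEFAULTS["otitis_media"], **(params or {})}
    hue, sat, val = _hsv(roi)
    core = val <= p["core_val_max"]
    red = ((hue <= p["rim_hue_max"]) | (hue >= p["rim_hue_min_wrap"])) & (sat >= p["rim_sat_min"])
    near_core = ndimage.binary_dilation(core, iterations=int(p["rim_reach_px"]))
    mask = _cleanup(core | (red & near_core), _min_area(core.shape, p))
    return SuspicionMask(mask=mask, predicted_class="otitis_media", method_params=p)


_SEGMENTERS = {
    "earwax": segment_earwax,
    "myringosclerosis": segment_myringosclerosis,
    "otitis_media": segment_perforation,
}


def segment(roi: np.ndarray, predicted_class: str, params: dict | None = None) -> SuspicionMask | None:
    """Dispatch to the class segmenter; ``None`` for a normal prediction."""
    if predicted_class == "normal":
        return None
    if predicted_class not in _SEGMENTERS:
        raise ValueError(f"unknown class {predicted_class!r}; expected one of {CLASSES}")
    return _SEGMENTERS[predicted_class](roi, params)


def mask_contour(mask: np.ndarray) -> np.ndarray:
    """Boundary pixels of a binary mask (mask minus its erosion)."""
    eroded = ndimage.binary_erosion(mask, structure=np.ones((3, 3), dtype=bool), border_value=0)
    return mask & ~eroded


def highlight(roi: np.ndarray, predicted_class: str, params: dict | None = None) -> HighlightResult:
    """Render the suspicion overlay for a predicted class.

    Normal predictions return an unmodified copy (the label lives in the
    annotation only).  Otherwise the class mask is drawn as a solid contour
    plus a translucent fill on a copy of the ROI; the input is never
    modified.  An empty mask leaves the image unchanged and sets the
    ``no_region_found`` flag.
    """
    pixels = np.asarray(roi)
    out = pixels.copy()
    if predicted_class == "normal":
        return HighlightResult(image=out, mask=None, annotation="normal")

    sm = segment(pixels, predicted_class, params)
    if sm.empty:
        return HighlightResult(image=out, mask=sm, annotation=f"{predicted_class}: no region found", no_region_found=True)

    cfg = {**HIGHLIGHT_DEFAULTS, **(params or {})}
    alpha = float(cfg["fill_alpha"])
    contour_rgb = np.array(cfg["contour_rgb"], dtype=float)
    fill = sm.mask & ~mask_contour(sm.mask)
    out_f = out.astype(float)
    out_f[fill] = (1 - alpha) * out_f[fill] + alpha * contour_rgb
    out_f[mask_contour(sm.mask)] = contour_rgb
    return HighlightResult(
        image=np.clip(np.rint(out_f), 0, 255).astype(np.uint8),
        mask=sm,
        annotation=predicted_class,
    )


def dice(mask_a: np.ndarray, mask_b: np.ndarray) -> float:
    """Dice overlap 2|A∩B| / (|A|+|B|); 1.0 when both masks are empty."""
    a = np.asarray(mask_a, dtype=bool)
    b = np.asarray(mask_b, dtype=bool)
    denom = a.sum() + b.sum()
    if denom == 0:
        return 1.0
    return 2.0 * np.logical_and(a, b).sum() / denom
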