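"""Synthetic otoscopy phantom generator.

Clinical otoscope recordings of the tympanic membrane are not publicly
deposited, so every downstream stage of the pipeline is exercised on
phantoms: a pinkish-gray textured "membrane" disc on which class-specific
lesions are painted.  Four classes are modeled:

* ``normal`` — membrane only, no lesion;
* ``earwax`` — yellow-brown soft-edged occluding blobs (cerumen);
* ``myringosclerosis`` — bright, desaturated calcified patches;
* ``otitis_media`` — one dark perforation with a reddened rim.

Each lesion class also emits a binary ground-truth mask so that
segmentation stages can be scored against a known answer.  Every generator
output is a pure function of its :class:`PhantomSpec` (including the seed):
identical specs give bit-identical images.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field, replace
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
from scipy import ndimage

#: Canonical class order used throughout the pipeline.
CLASSES: tuple[str, ...] = ("normal", "earwax", "myringosclerosis", "otitis_media")

#: Default number of lesions drawn per class (otitis is always a single
#: perforation; the count is ignored for normal ears).
_DEFAULT_LESION_COUNT = {"earwax": 3, "myringosclerosis": 4, "otitis_media": 1}

# Reference lesion colors (RGB).  Chosen so each class sits in a distinct
# HSV band: earwax hue ~20-40 deg at high saturation, myringosclerosis
# value >= 0.85 with saturation <= 0.15, otitis core value <= 0.25 with a
# rim hue near 0 deg.  The membrane base is pinkish-gray (hue ~0-15 deg,
# moderate saturation), so color-driven features have real signal.
_MEMBRANE_RGB = np.array([192.0, 148.0, 138.0])
_CANAL_RGB = np.array([112.0, 84.0, 76.0])
_EARWAX_RGB = np.array([180.0, 115.0, 38.0])
_MYRINGO_RGB = np.array([242.0, 238.0, 233.0])
_OTITIS_CORE_RGB = np.array([45.0, 18.0, 18.0])
_OTITIS_RIM_RGB = np.array([175.0, 35.0, 35.0])

_MIN_SIDE = 64  # smallest ROI side supporting 8x8 DCT blocks and the filter bank


class PhantomError(ValueError):
    """Invalid phantom specification."""


@dataclass(frozen=True)
class PhantomSpec:
    """Parameters of a single phantom image.

    ``roi_size`` is ``(width, height)`` in pixels, matching the pipeline's
    420x380 crop convention.  ``lesion_scale`` is the total lesion area as
    a fraction of the ROI area; ``texture_grain`` is the correlation length
    (pixels) of the background texture; ``blur_sigma`` applies a final
    Gaussian defocus.
    """

    class_label: str
    roi_size: tuple[int, int] = (420, 380)
    seed: int = 0
    lesion_count: int | None = None
    lesion_scale: float = 0.12
    texture_grain: float = 6.0
    blur_sigma: float = 0.0

    def __post_init__(self) -> None:
        if self.class_label not in CLASSES:
            raise PhantomError(f"unknown class {self.class_label!r}; expected one of {CLASSES}")
        w, h = self.roi_size
        if w < _MIN_SIDE or h < _MIN_SIDE:
            raise PhantomError(f"roi_size {self.roi_size} below minimum {_MIN_SIDE}x{_MIN_SIDE}")
        if not (0.0 < self.lesion_scale <= 0.5):
            raise PhantomError("lesion_scale must lie in (0, 0.5]")
        if self.texture_grain <= 0:
            raise PhantomError("texture_grain must be positive")
        if self.blur_sigma < 0:
            raise PhantomError("blur_sigma must be nonnegative")
        if self.lesion_count is not None and self.lesion_count < 0:
            raise PhantomError("lesion_count must be >= 0")


@dataclass
class LabeledImage:
    """An RGB raster with a ground-truth class label.

    ``mask`` is the binary ground-truth lesion mask (``None`` for lesion-free
    images).  ``circle`` records the true aperture circle ``(cx, cy, r)``
    when the image was embedded into a full otoscope frame.
    """

    pixels: np.ndarray  # uint8, (H, W, 3)
    label: str
    provenance: PhantomSpec | str | None = None
    mask: np.ndarray | None = None
    circle: tuple[float, float, float] | None = None

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 3 or px.shape[2] != 3:
            raise PhantomError("pixels must be an (H, W, 3) RGB array")
        if px.shape[0] < _MIN_SIDE or px.shape[1] < _MIN_SIDE:
            raise PhantomError(f"image sides must be >= {_MIN_SIDE}")


def _correlated_noise(rng: np.random.Generator, shape: tuple[int, int], grain: float) -> np.ndarray:
    """Zero-mean unit-variance Gaussian field with correlation length ``grain``."""
    noise = rng.standard_normal(shape)
    smooth = ndimage.gaussian_filter(noise, sigma=grain, mode="reflect")
    sd = smooth.std()
    return smooth / sd if sd > 0 else smooth


def _random_blob_mask(
    rng: np.random.Generator,
    shape: tuple[int, int],
    n_blobs: int,
    total_area: float,
    inner_margin: float = 0.18,
) -> np.ndarray:
    """Union of ``n_blobs`` random ellipses totalling roughly ``total_area`` px."""
    h, w = shape
    yy, xx = np.mgrid[0:h, 0:w]
    mask = np.zeros(shape, dtype=bool)
    area_each = total_area / max(1, n_blobs)
    for _ in range(n_blobs):
        # semi-axes with random 1:1..1:2.5 aspect, area pi*a*b = area_each
        aspect = rng.uniform(1.0, 2.5)
        b_ax = np.sqrt(area_each / (np.pi * aspect))
        a_ax = aspect * b_ax
        theta = rng.uniform(0, np.pi)
        cy = rng.uniform(inner_margin * h, (1 - inner_margin) * h)
        cx = rng.uniform(inner_margin * w, (1 - inner_margin) * w)
        ct, st = np.cos(theta), np.sin(theta)
        u = (xx - cx) * ct + (yy - cy) * st
        v = -(xx - cx) * st + (yy - cy) * ct
        mask |= (u / a_ax) ** 2 + (v / b_ax) ** 2 <= 1.0
    return mask


def _soft_composite(canvas: np.ndarray, mask: np.ndarray, color: np.ndarray, softness: float = 2.5) -> None:
    """Alpha-composite ``color`` into ``canvas`` with a softened mask edge (in place)."""
    alpha = ndimage.gaussian_filter(mask.astype(float), sigma=softness, mode="constant")
    alpha = np.clip(alpha, 0.0, 1.0)[..., None]
    canvas *= 1.0 - alpha
    canvas += alpha * color


def generate_phantom(spec: PhantomSpec) -> LabeledImage:
    """Render one phantom otoscopy ROI from its spec.

    The base layer is a pinkish-gray elliptical membrane over a darker
    canal surround, with smooth low-frequency shading and correlated
    texture noise.  Class-specific lesions are then composited, the
    ground-truth lesion mask recorded, and an optional defocus blur
    applied.
    """
    w, h = spec.roi_size
    rng = np.random.default_rng(spec.seed)
    yy, xx = np.mgrid[0:h, 0:w]

    # membrane disc over canal background
    cy, cx = h / 2.0, w / 2.0
    ell = ((xx - cx) / (0.48 * w)) ** 2 + ((yy - cy) / (0.48 * h)) ** 2 <= 1.0
    canvas = np.empty((h, w, 3), dtype=float)
    canvas[:] = _CANAL_RGB + rng.normal(0, 4, 3)
    membrane_color = _MEMBRANE_RGB + rng.normal(0, 6, 3)
    _soft_composite(canvas, ell, membrane_color, softness=4.0)

    # multiplicative low-frequency shading and fine correlated texture:
    # illumination varies as a gain, so dark regions fluctuate less in
    # absolute terms than bright ones
    shading = _correlated_noise(rng, (h, w), grain=min(h, w) / 4.0) * 0.055
    texture = _correlated_noise(rng, (h, w), grain=spec.texture_grain) * 0.045
    canvas *= (1.0 + shading + texture)[..., None]
    # mild independent per-channel grain so color features see local variation
    canvas += rng.normal(0, 2.0, size=canvas.shape)

    mask: np.ndarray | None = None
    if spec.class_label != "normal":
        n_lesions = spec.lesion_count
        if n_lesions is None:
            n_lesions = _DEFAULT_LESION_COUNT[spec.class_label]
        if spec.class_label == "otitis_media":
            n_lesions = 1  # a single perforation, by construction
        total_area = spec.lesion_scale * h * w
        if n_lesions > 0:
            blob = _random_blob_mask(rng, (h, w), n_lesions, total_area)
            if spec.class_label == "earwax":
                _soft_composite(canvas, blob, _EARWAX_RGB + rng.normal(0, 3, 3))
                mask = blob
            elif spec.class_label == "myringosclerosis":
                _soft_composite(canvas, blob, _MYRINGO_RGB + rng.normal(0, 3, 3))
                mask = blob
            else:  # otitis_media: dark core plus red rim
                rim_width = max(4, int(round(0.04 * min(h, w))))
                rim = ndimage.binary_dilation(blob, iterations=rim_width) & ~blob
                _soft_composite(canvas, rim, _OTITIS_RIM_RGB + rng.normal(0, 4, 3))
                _soft_composite(canvas, blob, _OTITIS_CORE_RGB + rng.normal(0, 3, 3))
                mask = blob | rim
        else:
            mask = np.zeros((h, w), dtype=bool)

    if spec.blur_sigma > 0:
        canvas = ndimage.gaussian_filter(canvas, sigma=(spec.blur_sigma, spec.blur_sigma, 0))

    pixels = np.clip(np.rint(canvas), 0, 255).astype(np.uint8)
    return LabeledImage(pixels=pixels, label=spec.class_label, provenance=spec, mask=mask)


def phantom_seed(dataset_seed: int, class_label: str, index: int) -> int:
    """Deterministic per-image seed from (dataset seed, class, index).

    Hash-derived so each image's seed is independent of generation order.
    """
    ss = np.random.SeedSequence([int(dataset_seed), CLASSES.index(class_label), int(index)])
    return int(ss.generate_state(1)[0] % (2**31))


def generate_dataset(
    n_per_class: int,
    seed: int,
    roi_size: tuple[int, int] = (420, 380),
    **spec_overrides,
) -> list[LabeledImage]:
    """Generate ``4 * n_per_class`` phantoms, ``n_per_class`` per class."""
    if n_per_class < 1:
        raise PhantomError("n_per_class must be >= 1")
    images: list[LabeledImage] = []
    for label in CLASSES:
        for i in range(n_per_class):
            spec = PhantomSpec(
                class_label=label,
                roi_size=roi_size,
                seed=phantom_seed(seed, label, i),
                **spec_overrides,
            )
            images.append(generate_phantom(spec))
    return images


def embed_in_frame(
    roi: LabeledImage,
    frame_size: tuple[int, int] = (640, 480),
    center: tuple[int, int] = (320, 240),
    radius: int = 150,
    seed: int = 0,
) -> LabeledImage:
    """Composite an ROI inside a bright circle on a dark otoscope frame.

    Emulates a raw otoscope frame: near-black surround with mild sensor
    noise, and the membrane visible only through the circular aperture of
    the speculum tip.  The true circle is recorded on the output for
    round-trip checks against the Hough detector.
    """
    fw, fh = frame_size
    cx, cy = center
    if not (radius > 0 and cx - radius >= 0 and cx + radius < fw and cy - radius >= 0 and cy + radius < fh):
        raise PhantomError(f"circle (center={center}, r={radius}) does not fit in frame {frame_size}")

    rng = np.random.default_rng(seed)
    frame = np.clip(rng.normal(8.0, 3.0, size=(fh, fw, 3)), 0, 255)

    h, w = roi.pixels.shape[:2]
    yy, xx = np.mgrid[0:fh, 0:fw]
    inside = (xx - cx) ** 2 + (yy - cy) ** 2 <= radius**2
    # sample the ROI centered on the circle center, edge-replicating beyond it
    src_r = np.clip(yy - cy + h // 2, 0, h - 1)
    src_c = np.clip(xx - cx + w // 2, 0, w - 1)
    frame[inside] = roi.pixels[src_r[inside], src_c[inside]]

    return LabeledImage(
        pixels=np.clip(np.rint(frame), 0, 255).astype(np.uint8),
        label=roi.label,
        provenance=roi.provenance,
        mask=None,
        circle=(float(cx), float(cy), float(radius)),
    )


def degrade_sharpness(image: LabeledImage, sigma: float) -> LabeledImage:
    """Gaussian low-pass of a labeled image; label and provenance preserved."""
    if sigma < 0:
        raise PhantomError("sigma must be nonnegative")
    if sigma == 0:
        return replace_pixels(image, image.pixels.copy())
    blurred = ndimage.gaussian_filter(image.pixels.astype(float), sigma=(sigma, sigma, 0))
    return replace_pixels(image, np.clip(np.rint(blurred), 0, 255).astype(np.uint8))


def replace_pixels(image: LabeledImage, pixels: np.ndarray) -> LabeledImage:
    return LabeledImage(
        pixels=pixels,
        label=image.label,
        provenance=image.provenance,
        mask=None if image.mask is None else image.mask.copy(),
        circle=image.circle,
    )


def write_dataset(images: list[LabeledImage], root: str | Path) -> Path:
    """Write a directory-per-class PNG tree plus a manifest CSV.

    Layout: ``<root>/<class>/<index>.png`` with ground-truth masks written
    alongside as ``<index>_mask.png`` for lesion classes.  The manifest
    records path, label and generator seed for every image.
    """
    root = Path(root)
    rows = []
    counters = {c: 0 for c in CLASSES}
    for img in images:
        cls_dir = root / img.label
        cls_dir.mkdir(parents=True, exist_ok=True)
        idx = counters[img.label]
        counters[img.label] += 1
        path = cls_dir / f"{idx:04d}.png"
        iio.imwrite(path, img.pixels)
        if img.mask is not None:
            iio.imwrite(cls_dir / f"{idx:04d}_mask.png", (img.mask.astype(np.uint8) * 255))
        seed = img.provenance.seed if isinstance(img.provenance, PhantomSpec) else ""
        rows.append({"path": str(path.relative_to(root)), "label": img.label, "seed": seed})
    manifest = root / "manifest.csv"
    pd.DataFrame(rows).to_csv(manifest, index=False)
    return manifest


def load_dataset(root: str | Path) -> list[LabeledImage]:
    """Read a dataset written by :func:`write_dataset` (or any manifest tree)."""
    root = Path(root)
    manifest = pd.read_csv(root / "manifest.csv")
    images = []
    for _, row in manifest.iterrows():
        path = root / row["path"]
        pixels = np.asarray(iio.imread(path))
        if pixels.ndim == 2:
            pixels = np.stack([pixels] * 3, axis=-1)
        mask_path = path.with_name(path.stem + "_mask.png")
        mask = np.asarray(iio.imread(mask_path)) > 127 if mask_path.exists() else None
        images.append(LabeledImage(pixels=pixels[..., :3], label=row["label"], provenance=str(path), mask=mask))
    return images


def dataset_fingerprint(images: list[LabeledImage]) -> str:
    """SHA-256 over all pixel buffers and labels, for determinism checks."""
    digest = hashlib.sha256()
    for img in images:
        digest.update(img.label.encode())
        digest.update(np.ascontiguousarray(img.pixels).tobytes())
    return digest.hexdigest()
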