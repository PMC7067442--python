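"""Block-DCT texture descriptor with Laplace-model quantization.

Following the JPEG block transform, the luminance image is split into
non-overlapping 8x8 blocks and each block mapped to 64 orthonormal DCT-II
coefficients.  Eight low-frequency channels are retained (high frequencies
are dominated by noise); AC coefficients, which are well modeled by a
zero-mean Laplace distribution, are quantized with a Lloyd-Max optimal
scalar quantizer fitted to each channel's scale.  Each block then becomes an
8-vector of reconstruction codes, and the same texton-dictionary +
frequency-histogram machinery as the filter-bank method turns the block
vectors into a fixed-length feature.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.fft

from .filterbank import TextonDictionary, assign_vectors, kmeans_dictionary, texton_histogram
from .preprocessing import luminance

BLOCK = 8

#: Default channel selection: the 8 lowest-frequency coefficients in JPEG
#: zigzag order starting at DC, as (u, v) row-major indices u*8+v.
DEFAULT_CHANNELS: tuple[int, ...] = (0, 1, 8, 16, 9, 2, 3, 10)

DEFAULT_LEVELS_AC = 5
DEFAULT_LEVELS_DC = 3


class DCTError(ValueError):
    pass


class DegenerateChannelError(DCTError):
    """All coefficients in a channel are zero; no Laplace scale exists."""


@dataclass
class DCTBlockPlanes:
    """Per-block DCT coefficients, shape (block_rows, block_cols, 64).

    Coefficient index is row-major over frequency (u, v) in 0..7, so index 0
    is the DC coefficient (proportional to the block mean).
    """

    coefficients: np.ndarray
    block_grid: tuple[int, int]


@dataclass(frozen=True)
class ChannelSelection:
    indices: tuple[int, ...] = DEFAULT_CHANNELS

    def __post_init__(self) -> None:
        idx = tuple(int(i) for i in self.indices)
        if len(set(idx)) != len(idx):
            raise DCTError("channel indices must be distinct")
        if any(i < 0 or i > 63 for i in idx):
            raise DCTError("channel indices must lie in 0..63")
        if 63 in idx:
            raise DCTError("the highest-frequency corner channel (7,7) is excluded")
        object.__setattr__(self, "indices", idx)

    @classmethod
    def from_uv(cls, pairs) -> "ChannelSelection":
        return cls(tuple(u * BLOCK + v for u, v in pairs))


def block_dct(image: np.ndarray) -> DCTBlockPlanes:
    """Orthonormal 2-D DCT-II over non-overlapping 8x8 blocks.

    Right/bottom remainders smaller than a block are discarded.  For a
    constant block of value m the DC coefficient is 8*m and every AC
    coefficient vanishes; Parseval's identity holds per block.
    """
    img = luminance(image)
    h, w = img.shape
    if h < BLOCK or w < BLOCK:
        raise DCTError(f"image {img.shape} smaller than one {BLOCK}x{BLOCK} block")
    br, bc = h // BLOCK, w // BLOCK
    blocks = img[: br * BLOCK, : bc * BLOCK].reshape(br, BLOCK, bc, BLOCK).transpose(0, 2, 1, 3)
    coeff = scipy.fft.dctn(blocks, axes=(-2, -1), norm="ortho")
    return DCTBlockPlanes(coefficients=coeff.reshape(br, bc, BLOCK * BLOCK), block_grid=(br, bc))


def inverse_block_dct(planes: DCTBlockPlanes) -> np.ndarray:
    """Reconstruct the (cropped) image from its block coefficients."""
    br, bc = planes.block_grid
    coeff = planes.coefficients.reshape(br, bc, BLOCK, BLOCK)
    blocks = scipy.fft.idctn(coeff, axes=(-2, -1), norm="ortho")
    return blocks.transpose(0, 2, 1, 3).reshape(br * BLOCK, bc * BLOCK)


def fit_laplace_scale(sample: np.ndarray, center: float = 0.0) -> float:
    """Maximum-likelihood Laplace scale of a coefficient sample.

    For AC channels the location is fixed at 0, so b is the mean absolute
    coefficient.  Raises :class:`DegenerateChannelError` for an all-zero
    sample.
    """
    sample = np.asarray(sample, dtype=float).ravel()
    if sample.size < 16:
        raise DCTError(f"need >= 16 samples per channel, got {sample.size}")
    b = float(np.abs(sample - center).mean())
    if b <= 0.0:
        raise DegenerateChannelError("all coefficients equal the center; Laplace scale undefined")
    return b


def _laplace_cdf(x: np.ndarray, b: float) -> np.ndarray:
    return np.where(x < 0, 0.5 * np.exp(x / b), 1.0 - 0.5 * np.exp(-x / b))


def _laplace_partial_mean(x: np.ndarray, b: float) -> np.ndarray:
    """M(x) = integral_{-inf}^{x} t f(t) dt for the Laplace(0, b) density.

    M(-inf) = 0 and M(+inf) = 0 (the distribution has zero mean); computed
    piecewise to avoid 0 * inf at the open cell edges.
    """
    x = np.asarray(x, dtype=float)
    out = np.zeros_like(x)
    finite = np.isfinite(x)
    neg = (x < 0) & finite
    pos = (x >= 0) & finite
    out[neg] = 0.5 * np.exp(x[neg] / b) * (x[neg] - b)
    out[pos] = -0.5 * np.exp(-x[pos] / b) * (x[pos] + b)
    return out


def _conditional_mean(lo: np.ndarray, hi: np.ndarray, b: float) -> np.ndarray:
    lo = np.asarray(lo, dtype=float)
    hi = np.asarray(hi, dtype=float)
    mass = _laplace_cdf(hi, b) - _laplace_cdf(lo, b)
    num = _laplace_partial_mean(hi, b) - _laplace_partial_mean(lo, b)
    return num / np.maximum(mass, 1e-300)


@dataclass
class QuantizerChannel:
    b: float
    thresholds: np.ndarray  # strictly increasing, length levels-1
    codes: np.ndarray  # length levels

    def quantize(self, values: np.ndarray) -> np.ndarray:
        return self.codes[np.searchsorted(self.thresholds, values, side="right")]


@dataclass
class LaplaceQuantizer:
    """Per-channel Lloyd-Max scalar quantizers for Laplace-distributed data."""

    channels: dict[int, QuantizerChannel]


def lloyd_max_laplace(b: float, levels: int, tol: float = 1e-8, max_iter: int = 10_000) -> QuantizerChannel:
    """Lloyd-Max optimal scalar quantizer for the Laplace(0, b) density.

    Fixed-point iteration: thresholds are midpoints of adjacent codes, codes
    are the conditional means of their cells, until the relative change in
    every code falls below ``tol``.  The quantizer is symmetric about 0 for
    even level counts; scale equivariant in b.
    """
    if b <= 0:
        raise DCTError("scale b must be positive")
    if levels < 2:
        raise DCTError("need at least 2 levels")
    # initialize codes at Laplace quantiles
    probs = (np.arange(levels) + 0.5) / levels
    codes = np.where(probs < 0.5, b * np.log(2 * probs), -b * np.log(2 * (1 - probs)))
    for _ in range(max_iter):
        thresholds = 0.5 * (codes[:-1] + codes[1:])
        lo = np.concatenate([[-np.inf], thresholds])
        hi = np.concatenate([thresholds, [np.inf]])
        new_codes = _conditional_mean(lo, hi, b)
        if np.all(np.abs(new_codes - codes) <= tol * np.maximum(np.abs(codes), b)):
            codes = new_codes
            break
        codes = new_codes
    else:
        raise DCTError(f"Lloyd-Max did not converge in {max_iter} iterations")
    thresholds = 0.5 * (codes[:-1] + codes[1:])
    return QuantizerChannel(b=b, thresholds=thresholds, codes=codes)


def build_quantizer(b_per_channel: dict[int, float], levels: int | dict[int, int]) -> LaplaceQuantizer:
    """Build per-channel Lloyd-Max quantizers.

    ``levels`` may be one count for all channels or a per-channel mapping.
    """
    channels = {}
    for ch, b in b_per_channel.items():
        lv = levels[ch] if isinstance(levels, dict) else levels
        channels[ch] = lloyd_max_laplace(b, lv)
    return LaplaceQuantizer(channels=channels)


def quantize_blocks(
    planes: DCTBlockPlanes,
    sel: ChannelSelection,
    q: LaplaceQuantizer,
) -> np.ndarray:
    """Map each block to the reconstruction codes of its selected channels.

    The DC channel (index 0), when selected, is first standardized across
    the image's blocks (subtract the mean DC, divide by the DC standard
    deviation) so its quantizer operates on a zero-centered variable like
    the AC channels.  Output shape: (block_rows, block_cols, n_channels).
    """
    missing = [ch for ch in sel.indices if ch not in q.channels]
    if missing:
        raise DCTError(f"quantizer lacks channels {missing}")
    br, bc = planes.block_grid
    out = np.empty((br, bc, len(sel.indices)))
    for j, ch in enumerate(sel.indices):
        vals = planes.coefficients[:, :, ch]
        if ch == 0:
            sd = vals.std()
            vals = (vals - vals.mean()) / (sd if sd > 1e-12 else 1.0)
        out[:, :, j] = q.channels[ch].quantize(vals)
    return out


def standardized_channel_samples(images: list[np.ndarray], sel: ChannelSelection) -> dict[int, np.ndarray]:
    """Pool per-channel coefficient samples over images (DC standardized per image)."""
    pools: dict[int, list[np.ndarray]] = {ch: [] for ch in sel.indices}
    for image in images:
        planes = block_dct(image)
        for ch in sel.indices:
            vals = planes.coefficients[:, :, ch].ravel()
            if ch == 0:
                sd = vals.std()
                vals = (vals - vals.mean()) / (sd if sd > 1e-12 else 1.0)
            pools[ch].append(vals)
    return {ch: np.concatenate(v) for ch, v in pools.items()}


def fit_dct_quantizer(
    images: list[np.ndarray],
    sel: ChannelSelection | None = None,
    levels_ac: int = DEFAULT_LEVELS_AC,
    levels_dc: int = DEFAULT_LEVELS_DC,
) -> tuple[ChannelSelection, LaplaceQuantizer]:
    """Fit the Laplace scales and Lloyd-Max quantizers from a training set."""
    if sel is None:
        sel = ChannelSelection()
    samples = standardized_channel_samples(images, sel)
    b_per_channel = {ch: fit_laplace_scale(vals) for ch, vals in samples.items()}
    levels = {ch: (levels_dc if ch == 0 else levels_ac) for ch in sel.indices}
    return sel, build_quantizer(b_per_channel, levels)


def quantized_block_vectors(image: np.ndarray, sel: ChannelSelection, q: LaplaceQuantizer) -> np.ndarray:
    """Flattened (n_blocks, n_channels) quantized vectors for one image."""
    grid = quantize_blocks(block_dct(image), sel, q)
    return grid.reshape(-1, grid.shape[2])


def build_dct_texton_dictionary(
    images_by_class: dict[str, list[np.ndarray]],
    sel: ChannelSelection,
    q: LaplaceQuantizer,
    k: int = 10,
    seed: int = 0,
    max_samples_per_class: int = 10_000,
) -> TextonDictionary:
    """Per-class k-means dictionary over quantized block vectors."""
    vectors_by_class = {
        cls: np.vstack([quantized_block_vectors(im, sel, q) for im in images])
        for cls, images in images_by_class.items()
    }
    return kmeans_dictionary(vectors_by_class, k=k, seed=seed, max_samples_per_class=max_samples_per_class)


def dct_texton_features(
    image: np.ndarray,
    dictionary: TextonDictionary,
    sel: ChannelSelection,
    q: LaplaceQuantizer,
) -> np.ndarray:
    """Texton frequency histogram over quantized DCT block vectors."""
    vectors = quantized_block_vectors(image, sel, q)
    labels = assign_vectors(vectors, dictionary)
    return texton_histogram(labels, n_bins=dictionary.n_textons).vector
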