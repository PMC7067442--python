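"""MR8 filter-bank texture features via texton histograms.

The texture descriptor works in three stages.  First, a bank of 38
Gaussian-derivative kernels is built: edge (first-derivative) and bar
(second-derivative) filters at 3 scales x 6 orientations, plus an isotropic
Gaussian and a Laplacian of Gaussian.  Convolving an image with the bank and
taking the maximum response over the 6 orientations within each
(scale, type) group collapses the 38 responses to 8 rotationally-robust
planes — the "maximum response 8" (MR8) representation.  Second, pixel
response 8-vectors pooled per class are clustered with k-means; the
centroids (*textons*) from all classes are concatenated into one ordered
dictionary (default 10 per class x 4 classes = 40 bins).  Third, each pixel
of a new image is labeled with its nearest texton and the normalized
frequency histogram of labels is the 40-dimensional feature vector.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import scipy.fft
from scipy.spatial.distance import cdist
from sklearn.cluster import KMeans

from .preprocessing import luminance

#: Default (sigma_deriv, sigma_elong) scale pairs of the oriented filters.
DEFAULT_SCALES: tuple[tuple[float, float], ...] = ((1.0, 3.0), (2.0, 6.0), (4.0, 12.0))

DEFAULT_SUPPORT = 49  # kernel side, pixels
DEFAULT_ISO_SIGMA = 10.0  # Gaussian / LoG scale

#: Weber-law constant used in contrast normalization of response vectors.
WEBER_L = 0.03


class FilterBankError(ValueError):
    pass


@dataclass
class FilterBank:
    """Ordered kernel list plus the grouping of kernels into response slots.

    ``grouping[s]`` lists the kernel indices whose responses slot ``s``
    maximizes over (a single index for the two isotropic slots).
    """

    kernels: list[np.ndarray]
    grouping: list[list[int]]
    slot_kinds: list[str]  # per slot: "edge" | "bar" | "gaussian" | "log"
    scales: tuple[tuple[float, float], ...] = DEFAULT_SCALES
    orientations: int = 6
    _fft_cache: dict = field(default_factory=dict, repr=False)

    @property
    def n_slots(self) -> int:
        return len(self.grouping)


def _oriented_kernel(support: int, sigma_deriv: float, sigma_elong: float, theta: float, order: int) -> np.ndarray:
    """Anisotropic Gaussian-derivative kernel.

    The Gaussian is elongated (std ``sigma_elong``) along the filter axis at
    angle ``theta`` and differentiated (``order`` 1 = edge, 2 = bar) across
    it (std ``sigma_deriv``).  Zero-mean, L1-normalized.
    """
    half = support // 2
    y, x = np.mgrid[-half : half + 1, -half : half + 1]
    u = x * np.cos(theta) + y * np.sin(theta)  # along the filter
    v = -x * np.sin(theta) + y * np.cos(theta)  # across (derivative direction)
    g = np.exp(-0.5 * ((u / sigma_elong) ** 2 + (v / sigma_deriv) ** 2))
    if order == 1:
        k = -(v / sigma_deriv**2) * g
    elif order == 2:
        k = (v**2 / sigma_deriv**4 - 1.0 / sigma_deriv**2) * g
    else:
        raise FilterBankError(f"derivative order must be 1 or 2, got {order}")
    k -= k.mean()
    return k / np.abs(k).sum()


def _gaussian_kernel(support: int, sigma: float) -> np.ndarray:
    half = support // 2
    y, x = np.mgrid[-half : half + 1, -half : half + 1]
    g = np.exp(-0.5 * (x**2 + y**2) / sigma**2)
    return g / np.abs(g).sum()


def _log_kernel(support: int, sigma: float) -> np.ndarray:
    half = support // 2
    y, x = np.mgrid[-half : half + 1, -half : half + 1]
    r2 = x**2 + y**2
    k = (r2 / sigma**4 - 2.0 / sigma**2) * np.exp(-0.5 * r2 / sigma**2)
    k -= k.mean()
    return k / np.abs(k).sum()


def build_mr8_bank(
    scales: tuple[tuple[float, float], ...] = DEFAULT_SCALES,
    orientations: int = 6,
    support: int = DEFAULT_SUPPORT,
    iso_sigma: float = DEFAULT_ISO_SIGMA,
) -> FilterBank:
    """Construct the 38-kernel bank with its 8-slot grouping.

    Kernel order: edge filters (scale-major, orientation-minor), then bar
    filters, then the Gaussian and the Laplacian of Gaussian.
    """
    if orientations < 2:
        raise FilterBankError("need at least 2 orientations")
    for pair in scales:
        if len(pair) != 2 or pair[0] <= 0 or pair[1] <= 0:
            raise FilterBankError(f"invalid scale pair {pair}")

    kernels: list[np.ndarray] = []
    grouping: list[list[int]] = []
    slot_kinds: list[str] = []
    for order, kind in ((1, "edge"), (2, "bar")):
        for sd, se in scales:
            group = []
            for o in range(orientations):
                theta = np.pi * o / orientations
                group.append(len(kernels))
                kernels.append(_oriented_kernel(support, sd, se, theta, order))
            grouping.append(group)
            slot_kinds.append(kind)
    grouping.append([len(kernels)])
    kernels.append(_gaussian_kernel(support, iso_sigma))
    slot_kinds.append("gaussian")
    grouping.append([len(kernels)])
    kernels.append(_log_kernel(support, iso_sigma))
    slot_kinds.append("log")
    return FilterBank(
        kernels=kernels,
        grouping=grouping,
        slot_kinds=slot_kinds,
        scales=tuple(scales),
        orientations=orientations,
    )


def _convolve_bank(img: np.ndarray, bank: FilterBank) -> np.ndarray:
    """Convolve with every kernel (reflect padding) via a shared FFT.

    Returns an array of shape (n_kernels, H, W).  Kernel FFTs are cached on
    the bank per padded shape.
    """
    support = bank.kernels[0].shape[0]
    half = support // 2
    padded = np.pad(img, half, mode="reflect")
    ph, pw = padded.shape
    fh = scipy.fft.next_fast_len(ph + support - 1)
    fw = scipy.fft.next_fast_len(pw + support - 1)

    key = (fh, fw)
    if key not in bank._fft_cache:
        stack = np.zeros((len(bank.kernels), fh, fw))
        for i, k in enumerate(bank.kernels):
            stack[i, :support, :support] = k
        bank._fft_cache[key] = scipy.fft.rfft2(stack, axes=(-2, -1))
    kf = bank._fft_cache[key]

    imf = scipy.fft.rfft2(padded, s=(fh, fw))
    full = scipy.fft.irfft2(imf[None] * kf, s=(fh, fw), axes=(-2, -1))
    h, w = img.shape
    return full[:, 2 * half : 2 * half + h, 2 * half : 2 * half + w]


@dataclass
class MR8Response:
    planes: np.ndarray  # (8, H, W)

    @property
    def vectors(self) -> np.ndarray:
        """Per-pixel response vectors, shape (H*W, 8)."""
        return self.planes.reshape(self.planes.shape[0], -1).T


def mr8_responses(
    image: np.ndarray,
    bank: FilterBank,
    contrast_normalize: bool = True,
) -> MR8Response:
    """Compute the 8 maximum-response planes of an image.

    The luminance channel is standardized to zero mean / unit variance, then
    convolved with all 38 kernels.  Each edge slot takes the maximum of
    |response| over its 6 orientations (the edge kernels are odd, so the
    polarity-free maximum is what stays invariant under image rotation);
    each bar slot takes the signed maximum (bar kernels are even, making
    the sign — bright vs dark line — rotation-consistent); the isotropic
    responses pass through.  When ``contrast_normalize`` is set, each
    pixel's 8-vector r is rescaled by the Weber-law factor
    log(1 + L/0.03)/L with L = ||r||_2.
    """
    img = luminance(image)
    support = bank.kernels[0].shape[0]
    if min(img.shape) < support:
        raise FilterBankError(f"image {img.shape} smaller than kernel support {support}")
    sd = img.std()
    img = (img - img.mean()) / (sd if sd > 1e-12 else 1.0)

    responses = _convolve_bank(img, bank)
    planes = np.stack(
        [
            np.abs(responses[idx]).max(axis=0) if kind == "edge" else responses[idx].max(axis=0)
            for idx, kind in zip(bank.grouping, bank.slot_kinds)
        ]
    )

    if contrast_normalize:
        norm = np.sqrt((planes**2).sum(axis=0))
        scale = np.where(norm > 1e-12, np.log1p(norm / WEBER_L) / np.maximum(norm, 1e-12), 1.0)
        planes = planes * scale
    return MR8Response(planes=planes)


@dataclass
class TextonDictionary:
    """Ordered texton centroids; centroid order defines histogram bin order."""

    centroids: np.ndarray  # (n_textons, dim)
    class_of: list[str]
    k_per_class: int

    def __post_init__(self) -> None:
        if len(self.class_of) != self.centroids.shape[0]:
            raise FilterBankError("class_of length must match centroid count")

    @property
    def n_textons(self) -> int:
        return self.centroids.shape[0]

    def save(self, path: str | Path) -> None:
        """Persist as plain text: '#'-prefixed header lines, then the matrix."""
        path = Path(path)
        with open(path, "w") as fh:
            fh.write(f"# otodx texton dictionary v1\n")
            fh.write(f"# k_per_class: {self.k_per_class}\n")
            fh.write(f"# class_of: {','.join(self.class_of)}\n")
            np.savetxt(fh, self.centroids, fmt="%.17g")

    @classmethod
    def load(cls, path: str | Path) -> "TextonDictionary":
        header: dict[str, str] = {}
        with open(path) as fh:
            lines = fh.readlines()
        for line in lines:
            if line.startswith("#") and ":" in line:
                key, _, value = line[1:].partition(":")
                header[key.strip()] = value.strip()
        matrix = np.loadtxt([ln for ln in lines if not ln.startswith("#")], ndmin=2)
        return cls(
            centroids=matrix,
            class_of=header["class_of"].split(","),
            k_per_class=int(header["k_per_class"]),
        )


def kmeans_dictionary(
    vectors_by_class: dict[str, np.ndarray],
    k: int,
    seed: int,
    max_samples_per_class: int = 10_000,
) -> TextonDictionary:
    """Per-class k-means over pooled vectors; centroids concatenated in the
    mapping's class order.

    k-means++ initialization, relative tolerance 1e-4, at most 300
    iterations, seeded for determinism.  Vectors are subsampled to at most
    ``max_samples_per_class`` per class before clustering.
    """
    centroids, class_of = [], []
    for ci, (cls, vecs) in enumerate(vectors_by_class.items()):
        vecs = np.asarray(vecs, dtype=float)
        if vecs.ndim != 2:
            raise FilterBankError("per-class vectors must be 2-D (n, dim)")
        if vecs.shape[0] < k:
            raise FilterBankError(f"class {cls!r}: {vecs.shape[0]} vectors < k={k}")
        if vecs.shape[0] > max_samples_per_class:
            rng = np.random.default_rng(np.random.SeedSequence([seed, ci]).generate_state(1)[0])
            idx = rng.choice(vecs.shape[0], size=max_samples_per_class, replace=False)
            vecs = vecs[idx]
        km = KMeans(n_clusters=k, init="k-means++", n_init=4, tol=1e-4, max_iter=300, random_state=seed)
        km.fit(vecs)
        centroids.append(km.cluster_centers_)
        class_of.extend([cls] * k)
    return TextonDictionary(centroids=np.vstack(centroids), class_of=class_of, k_per_class=k)


def build_texton_dictionary(
    images_by_class: dict[str, list[np.ndarray]],
    k: int = 10,
    seed: int = 0,
    bank: FilterBank | None = None,
    max_samples_per_class: int = 10_000,
) -> TextonDictionary:
    """Learn the MR8 texton dictionary from per-class image sets.

    Each class's images are filtered with the bank and their pixel response
    8-vectors pooled; per-class k-means centroids are concatenated class by
    class (the reference configuration uses 40 images per class and k=10,
    yielding 40 textons).
    """
    if bank is None:
        bank = build_mr8_bank()
    vectors_by_class = {}
    for cls, images in images_by_class.items():
        if len(images) < 1:
            raise FilterBankError(f"class {cls!r} has no images")
        vectors_by_class[cls] = np.vstack([mr8_responses(im, bank).vectors for im in images])
    return kmeans_dictionary(vectors_by_class, k=k, seed=seed, max_samples_per_class=max_samples_per_class)


def assign_vectors(vectors: np.ndarray, dictionary: TextonDictionary) -> np.ndarray:
    """Nearest-centroid (Euclidean) label per vector; ties take the lowest index."""
    if vectors.shape[1] != dictionary.centroids.shape[1]:
        raise FilterBankError(
            f"vector dim {vectors.shape[1]} != centroid dim {dictionary.centroids.shape[1]}"
        )
    d = cdist(vectors, dictionary.centroids, metric="sqeuclidean")
    return np.argmin(d, axis=1)


def assign_textons(resp: MR8Response, dictionary: TextonDictionary) -> np.ndarray:
    """Per-pixel texton label raster for an MR8 response."""
    _, h, w = resp.planes.shape
    return assign_vectors(resp.vectors, dictionary).reshape(h, w)


@dataclass
class TextonHistogram:
    counts: np.ndarray
    normalized: bool

    @property
    def vector(self) -> np.ndarray:
        return self.counts


def texton_histogram(labels: np.ndarray, n_bins: int, normalize: bool = True) -> TextonHistogram:
    """Frequency histogram of texton labels over all pixels (or blocks)."""
    labels = np.asarray(labels).ravel()
    if labels.size and (labels.min() < 0 or labels.max() >= n_bins):
        raise FilterBankError(f"labels outside [0, {n_bins})")
    counts = np.bincount(labels, minlength=n_bins).astype(float)
    if normalize:
        total = counts.sum()
        if total > 0:
            counts = counts / total
    return TextonHistogram(counts=counts, normalized=normalize)


def filterbank_features(
    image: np.ndarray,
    dictionary: TextonDictionary,
    bank: FilterBank | None = None,
) -> np.ndarray:
    """End-to-end MR8 texton histogram feature vector for one image."""
    if bank is None:
        bank = build_mr8_bank()
    resp = mr8_responses(image, bank)
    labels = assign_textons(resp, dictionary)
    return texton_histogram(labels, n_bins=dictionary.n_textons).vector
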