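"""Image datasets and Poisson rate encoding.

Pixel intensities are turned into spikes by rate coding: a pixel of
intensity ``I`` (0-255) drives an independent Poisson train at
``I / gain_divisor`` Hz for the duration of the presentation.  With the
default divisor of 4 the maximum intensity 255 maps to 63.75 Hz.

The synthetic generator produces small MNIST-like labeled sets — sparse
bright strokes on a dark background, several mutually distinguishable
classes, per-sample intensity jitter, randomized presentation order — so
the full training pipeline can run at desk scale without external data.
Real MNIST / Fashion-MNIST files in IDX format are supported for
full-scale runs.
"""

from __future__ import annotations

import gzip
import struct
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "LabeledImageSet",
    "RateCode",
    "image_rates",
    "encode_poisson",
    "generate_synthetic_patterns",
    "read_idx",
    "write_idx",
    "read_idx_dataset",
    "train_test_split",
    "partition_iterations",
    "normalize_intensity_sum",
]

DEFAULT_GAIN_DIVISOR = 4.0


@dataclass
class LabeledImageSet:
    """Labeled 8-bit grayscale images with a presentation order."""

    images: np.ndarray  # (n, h, w) uint8
    labels: np.ndarray  # (n,) int
    order: np.ndarray = field(default=None)  # presentation permutation

    def __post_init__(self) -> None:
        self.images = np.asarray(self.images)
        self.labels = np.asarray(self.labels, dtype=int)
        if self.images.ndim != 3:
            raise ValueError("images must have shape (n, height, width)")
        if len(self.labels) != len(self.images):
            raise ValueError("labels and images length mismatch")
        if self.order is None:
            self.order = np.arange(len(self.images))
        self.order = np.asarray(self.order, dtype=int)

    def __len__(self) -> int:
        return len(self.images)

    @property
    def n_classes(self) -> int:
        return int(self.labels.max()) + 1 if len(self.labels) else 0

    @property
    def n_pixels(self) -> int:
        return int(self.images.shape[1] * self.images.shape[2])

    def in_order(self) -> "LabeledImageSet":
        """Return a copy with images physically arranged in presentation order."""
        return LabeledImageSet(self.images[self.order], self.labels[self.order])

    def subset(self, idx) -> "LabeledImageSet":
        idx = np.asarray(idx)
        return LabeledImageSet(self.images[idx], self.labels[idx])


@dataclass
class RateCode:
    """Per-pixel firing rates (Hz) for one presentation."""

    rates: np.ndarray
    duration: float
    gain_divisor: float = DEFAULT_GAIN_DIVISOR


def image_rates(image, gain_divisor: float = DEFAULT_GAIN_DIVISOR) -> np.ndarray:
    """Flattened per-pixel rates in Hz: intensity / gain_divisor."""
    if gain_divisor <= 0:
        raise ValueError("gain_divisor must be > 0")
    return np.asarray(image, dtype=float).ravel() / gain_divisor


def encode_poisson(
    image,
    gain_divisor: float = DEFAULT_GAIN_DIVISOR,
    duration: float = 350.0,
    dt: float = 0.5,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Bernoulli-thinned Poisson spike trains for each pixel.

    Returns a boolean array of shape (n_steps, n_pixels); a pixel at rate
    r Hz spikes in each bin of width dt ms with probability r*dt/1000
    (exact in the dt -> 0 limit, bias O(r*dt) otherwise).
    """
    if rng is None:
        rng = np.random.default_rng()
    rates = image_rates(image, gain_divisor)
    n_steps = int(round(duration / dt))
    p = rates * dt / 1000.0
    return rng.random((n_steps, rates.size)) < p[None, :]


def _stroke_prototype(
    h: int, w: int, n_strokes: int, rng: np.random.Generator, blur_sigma: float = 1.0
) -> np.ndarray:
    """Random line strokes rasterized on an h x w canvas.

    A Gaussian blur widens the strokes into graded intensities so the
    per-pixel activity overlaps between classes, as it does for
    anti-aliased handwritten digits; without it every class would drive a
    disjoint pixel set, which real digit data does not do.
    """
    from scipy import ndimage

    img = np.zeros((h, w))
    for _ in range(n_strokes):
        x0, y0 = rng.uniform(0, w - 1), rng.uniform(0, h - 1)
        angle = rng.uniform(0, np.pi)
        length = rng.uniform(0.5, 0.95) * min(h, w)
        n_pts = max(int(length * 2), 4)
        ts = np.linspace(0, length, n_pts)
        xs = np.clip(np.round(x0 + ts * np.cos(angle)).astype(int), 0, w - 1)
        ys = np.clip(np.round(y0 + ts * np.sin(angle)).astype(int), 0, h - 1)
        img[ys, xs] = 255.0
    if blur_sigma > 0:
        img = ndimage.gaussian_filter(img, blur_sigma)
        if img.max() > 0:
            img *= 255.0 / img.max()
    return img


def _prototype_correlation(a: np.ndarray, b: np.ndarray) -> float:
    fa, fb = a.ravel(), b.ravel()
    if fa.std() == 0 or fb.std() == 0:
        return 1.0
    return float(np.corrcoef(fa, fb)[0, 1])


def generate_synthetic_patterns(
    n_classes: int = 3,
    image_size: tuple[int, int] = (12, 12),
    samples_per_class: int = 200,
    stroke_density: int = 3,
    noise_sd: float = 40.0,
    dropout: float = 0.25,
    blur_sigma: float = 1.0,
    seed: int | None = None,
    max_corr: float = 0.5,
) -> LabeledImageSet:
    """Synthetic MNIST-like pattern set.

    Each class is a prototype of ``stroke_density`` random bright strokes;
    prototypes are resampled until every pairwise correlation is below
    ``max_corr`` so the classes stay mutually distinguishable.  Each
    sample degrades its prototype with per-pixel Gaussian intensity
    jitter of ``noise_sd`` (background pixels get a quarter of that
    amplitude) and random occlusion of a ``dropout`` fraction of the
    stroke pixels — the analogue of the stroke variability that makes
    handwritten digits non-identical.  The presentation order is a seeded
    random permutation of all samples so class features are reinforced in
    interleaved order.
    """
    if n_classes < 2:
        raise ValueError("need at least 2 classes")
    h, w = image_size
    rng = np.random.default_rng(seed)
    prototypes: list[np.ndarray] = []
    attempts = 0
    while len(prototypes) < n_classes:
        cand = _stroke_prototype(h, w, stroke_density, rng, blur_sigma)
        attempts += 1
        if attempts > 200 * n_classes:
            raise RuntimeError("failed to generate distinguishable prototypes")
        if cand.max() == 0:
            continue
        if all(_prototype_correlation(cand, p) < max_corr for p in prototypes):
            prototypes.append(cand)
    n = n_classes * samples_per_class
    images = np.empty((n, h, w), dtype=np.uint8)
    labels = np.repeat(np.arange(n_classes), samples_per_class)
    for k, proto in enumerate(prototypes):
        block = np.repeat(proto[None, :, :], samples_per_class, axis=0)
        if dropout > 0:
            occluded = (block > 0) & (rng.random(block.shape) < dropout)
            block = np.where(occluded, 0.0, block)
        if noise_sd > 0:
            jitter = rng.normal(0.0, noise_sd, size=block.shape)
            background = rng.normal(0.0, noise_sd / 4.0, size=block.shape)
            block = np.where(block > 0, block + jitter, np.abs(background))
        images[k * samples_per_class : (k + 1) * samples_per_class] = np.clip(
            block, 0, 255
        ).astype(np.uint8)
    order = rng.permutation(n)
    return LabeledImageSet(images=images, labels=labels, order=order)


# ---------------------------------------------------------------------------
# IDX container (the MNIST distribution format)

_IDX_DTYPES = {0x08: np.uint8, 0x09: np.int8, 0x0B: np.int16, 0x0C: np.int32, 0x0D: np.float32, 0x0E: np.float64}


def _open_maybe_gzip(path, mode):
    data = open(path, "rb").read(2)
    if data == b"\x1f\x8b":
        return gzip.open(path, mode)
    return open(path, mode)


def read_idx(path) -> np.ndarray:
    """Read a single IDX array (gzip-transparent)."""
    with _open_maybe_gzip(path, "rb") as fh:
        header = fh.read(4)
        if len(header) < 4 or header[0] != 0 or header[1] != 0:
            raise ValueError(f"{path}: bad IDX magic at byte 0: {header[:4]!r}")
        type_code, n_dims = header[2], header[3]
        if type_code not in _IDX_DTYPES:
            raise ValueError(f"{path}: unknown IDX type code 0x{type_code:02x} at byte 2")
        dims = []
        for d in range(n_dims):
            raw = fh.read(4)
            if len(raw) < 4:
                raise ValueError(f"{path}: truncated dimension header at byte {4 + 4*d}")
            dims.append(struct.unpack(">i", raw)[0])
        dtype = np.dtype(_IDX_DTYPES[type_code]).newbyteorder(">")
        count = int(np.prod(dims)) if dims else 0
        payload = fh.read(count * dtype.itemsize)
        if len(payload) < count * dtype.itemsize:
            raise ValueError(
                f"{path}: truncated payload at byte {4 + 4*n_dims + len(payload)}"
            )
        return np.frombuffer(payload, dtype=dtype).reshape(dims).astype(_IDX_DTYPES[type_code])


def write_idx(path, array: np.ndarray) -> None:
    """Write an array in IDX format (uint8 payloads for image/label data)."""
    array = np.asarray(array)
    codes = {v: k for k, v in _IDX_DTYPES.items()}
    if array.dtype.type not in {np.dtype(d).type for d in _IDX_DTYPES.values()}:
        array = array.astype(np.uint8)
    code = codes[array.dtype.type]
    with open(path, "wb") as fh:
        fh.write(bytes([0, 0, code, array.ndim]))
        for d in array.shape:
            fh.write(struct.pack(">i", d))
        fh.write(array.astype(np.dtype(array.dtype).newbyteorder(">")).tobytes())


def read_idx_dataset(images_path, labels_path, seed: int | None = None) -> LabeledImageSet:
    """Load an (images, labels) IDX pair, with a seeded presentation order."""
    images = read_idx(images_path)
    labels = read_idx(labels_path)
    if images.ndim != 3:
        raise ValueError(f"{images_path}: expected 3-D image array, got {images.ndim}-D")
    if labels.ndim != 1 or len(labels) != len(images):
        raise ValueError(
            f"{labels_path}: label count {labels.shape} does not match {len(images)} images"
        )
    order = np.random.default_rng(seed).permutation(len(images))
    return LabeledImageSet(images=images, labels=labels.astype(int), order=order)


def normalize_intensity_sum(dataset: LabeledImageSet) -> LabeledImageSet:
    """Scale each image so its intensity sum equals the dataset median sum.

    Used for Fashion-MNIST-like data whose per-sample gray-value sums vary
    strongly.
    """
    sums = dataset.images.reshape(len(dataset), -1).sum(axis=1).astype(float)
    target = np.median(sums[sums > 0])
    scale = np.where(sums > 0, target / np.maximum(sums, 1.0), 1.0)
    images = np.clip(
        dataset.images.astype(float) * scale[:, None, None], 0, 255
    ).astype(np.uint8)
    return LabeledImageSet(images=images, labels=dataset.labels, order=dataset.order)


def train_test_split(
    dataset: LabeledImageSet, test_fraction: float = 0.25, seed: int | None = None
):
    """Stratified split into (train, test) with fresh presentation orders."""
    if not 0.0 < test_fraction < 1.0:
        raise ValueError("test_fraction must be in (0, 1)")
    rng = np.random.default_rng(seed)
    test_idx = []
    for c in np.unique(dataset.labels):
        idx = np.flatnonzero(dataset.labels == c)
        n_test = max(1, int(round(len(idx) * test_fraction)))
        test_idx.append(rng.permutation(idx)[:n_test])
    test_idx = np.sort(np.concatenate(test_idx))
    train_mask = np.ones(len(dataset), dtype=bool)
    train_mask[test_idx] = False
    train = dataset.subset(np.flatnonzero(train_mask))
    test = dataset.subset(test_idx)
    train.order = rng.permutation(len(train))
    test.order = rng.permutation(len(test))
    return train, test


def partition_iterations(dataset: LabeledImageSet, images_per_iteration: int):
    """Contiguous presentation-order slices, one per training iteration.

    Returns a list of ``(subset, is_short)`` pairs; the final slice is
    flagged short when the dataset size is not a multiple of the slice
    length.
    """
    if images_per_iteration < 1:
        raise ValueError("images_per_iteration must be >= 1")
    ordered = dataset.in_order()
    n = len(ordered)
    slices = []
    for start in range(0, n, images_per_iteration):
        stop = min(start + images_per_iteration, n)
        slices.append((ordered.subset(np.arange(start, stop)), stop - start < images_per_iteration))
    return slices
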