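"""Handcrafted image descriptors used to separate real from generated images.

Three filters, each mapping a raw (uint8, [0, 255]) grayscale image to a
fixed-length real vector whose length depends only on the filter parameters:

* ``jpeg_coefficient`` — histograms of block-DCT coefficients, the frequency
  content a JPEG codec would encode: pad 28x28 to 32x32, take the orthonormal
  type-II DCT of each non-overlapping 8x8 block, zigzag-order the
  coefficients, and histogram each of the first ``n_coeffs`` positions across
  blocks (default 9 positions x 16 bins = 144 values).
* ``auto_color_correlogram`` — for each quantized intensity c and distance d,
  the probability that a pixel at Chebyshev (L-inf) distance exactly d from a
  pixel of colour c also has colour c (default 64 levels x 4 distances = 256
  values).
* ``colour_layout`` — MPEG-7 style colour layout: partition the image into an
  8x8 grid, take the mean colour of each block in YCbCr (for grayscale,
  Y = intensity and Cb = Cr = 128), DCT the 8x8 block-mean matrix per
  channel and keep the first zigzag coefficients (default 6 + 3 + 3 = 12
  values, kept real-valued).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.fft import dctn

logger = logging.getLogger("synthdetect")

#: fixed histogram ranges for the jpeg_coefficient filter, chosen to cover
#: the attainable orthonormal-DCT range of uint8 blocks (DC max = 8*255)
JPEG_DC_RANGE = (0.0, 2048.0)
JPEG_AC_RANGE = (-1024.0, 1024.0)

FILTER_IDS = ("jpeg_coefficient", "auto_color_correlogram", "colour_layout")


@dataclass(frozen=True)
class DescriptorVector:
    filter_id: str
    values: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "values", np.asarray(self.values, dtype=np.float64))
        if not np.all(np.isfinite(self.values)):
            raise ValueError("descriptor values must be finite")

    def __len__(self) -> int:
        return self.values.size


@dataclass(frozen=True)
class QuantizedImage:
    levels: int
    labels: np.ndarray  # integer bin indices, same shape as the image


def _as_raw_gray(image, require_28: bool = True) -> np.ndarray:
    a = np.asarray(image)
    if a.ndim == 3 and a.shape[-1] == 1:
        a = a[..., 0]
    if a.ndim != 2:
        raise ValueError(f"expected a single 2-D grayscale image, got {a.shape}")
    if require_28 and a.shape != (28, 28):
        raise ValueError(f"expected a 28x28 image, got {a.shape}")
    if a.min() < 0 or a.max() > 255:
        raise ValueError("raw image values must lie in [0, 255]")
    return a.astype(np.float64)


def zigzag_indices(n: int = 8) -> list[tuple[int, int]]:
    """(row, col) pairs of an n x n grid in JPEG zigzag order."""
    order = []
    for s in range(2 * n - 1):
        diag = [(i, s - i) for i in range(max(0, s - n + 1), min(s, n - 1) + 1)]
        if s % 2 == 0:
            diag.reverse()  # even anti-diagonals run bottom-left -> top-right
        order.extend(diag)
    return order


_ZIGZAG8 = zigzag_indices(8)


# ---------------------------------------------------------------------------
# JPEG block-DCT coefficient histograms
# ---------------------------------------------------------------------------


def block_dct_coefficients(image) -> np.ndarray:
    """Orthonormal 2-D DCT-II of the 16 8x8 blocks of the edge-padded image.

    Returns an array of shape (16, 8, 8), blocks in row-major order.
    """
    a = _as_raw_gray(image)
    padded = np.pad(a, ((0, 4), (0, 4)), mode="edge")
    blocks = padded.reshape(4, 8, 4, 8).transpose(0, 2, 1, 3).reshape(16, 8, 8)
    return dctn(blocks, axes=(1, 2), norm="ortho")


def jpeg_coefficient_features(image, n_coeffs: int = 9,
                              n_bins: int = 16) -> DescriptorVector:
    """Histogram, over the 16 blocks, of each of the first ``n_coeffs``
    zigzag-ordered DCT coefficients; vector length n_coeffs * n_bins.

    Values falling outside the fixed histogram range are counted in the
    nearest edge bin so every block contributes to every histogram.
    """
    if n_coeffs < 1 or n_coeffs > 64:
        raise ValueError("n_coeffs must be in [1, 64]")
    if n_bins < 1:
        raise ValueError("n_bins must be >= 1")
    coeffs = block_dct_coefficients(image)
    out = np.empty(n_coeffs * n_bins, dtype=np.float64)
    for idx in range(n_coeffs):
        r, c = _ZIGZAG8[idx]
        vals = coeffs[:, r, c]
        lo, hi = JPEG_DC_RANGE if idx == 0 else JPEG_AC_RANGE
        width = (hi - lo) / n_bins
        bins = np.floor((vals - lo) / width).astype(int)
        bins = np.clip(bins, 0, n_bins - 1)
        out[idx * n_bins:(idx + 1) * n_bins] = np.bincount(bins, minlength=n_bins)
    return DescriptorVector("jpeg_coefficient", out)


# ---------------------------------------------------------------------------
# auto colour correlogram
# ---------------------------------------------------------------------------


def quantize(image, levels: int) -> QuantizedImage:
    """Uniform intensity quantization: bin = floor(v * levels / 256)."""
    if levels < 2:
        raise ValueError("levels must be >= 2")
    a = _as_raw_gray(image, require_28=False)
    labels = np.clip((a.astype(np.int64) * levels) // 256, 0, levels - 1)
    return QuantizedImage(levels, labels.astype(np.int64))


def _chebyshev_ring(d: int) -> list[tuple[int, int]]:
    """All integer offsets at L-inf distance exactly d (8d of them)."""
    ring = []
    for dy in range(-d, d + 1):
        for dx in range(-d, d + 1):
            if max(abs(dy), abs(dx)) == d:
                ring.append((dy, dx))
    return ring


def auto_color_correlogram(image, levels: int = 64,
                           distances=(1, 3, 5, 7)) -> DescriptorVector:
    """Auto-correlogram over Chebyshev rings; colour-major layout.

    entry[c, d] = P(pixel at L-inf distance d from a colour-c pixel is also
    colour c), over all ordered in-bounds pixel pairs; colours absent from
    the image (or distances with no in-bounds pairs) contribute 0.
    """
    distances = list(distances)
    if not distances or any(d < 1 for d in distances):
        raise ValueError("distances must be non-empty, each >= 1")
    q = quantize(image, levels)
    labels = q.labels
    H, W = labels.shape
    values = np.zeros((levels, len(distances)), dtype=np.float64)
    for di, d in enumerate(distances):
        if d >= min(H, W):
            logger.warning(
                "correlogram distance %d >= image side %d; entries set to 0",
                d, min(H, W))
            continue
        numer = np.zeros(levels, dtype=np.int64)
        denom = np.zeros(levels, dtype=np.int64)
        for dy, dx in _chebyshev_ring(d):
            ys = slice(max(0, -dy), min(H, H - dy))
            xs = slice(max(0, -dx), min(W, W - dx))
            p = labels[ys, xs].ravel()
            qn = labels[ys.start + dy:ys.stop + dy, xs.start + dx:xs.stop + dx].ravel()
            denom += np.bincount(p, minlength=levels)
            numer += np.bincount(p[p == qn], minlength=levels)
        present = denom > 0
        values[present, di] = numer[present] / denom[present]
    return DescriptorVector("auto_color_correlogram", values.ravel())


# ---------------------------------------------------------------------------
# colour layout (MPEG-7 style)
# ---------------------------------------------------------------------------


def _block_means(a: np.ndarray, grid: int = 8) -> np.ndarray:
    """Mean of each cell of an even-index grid x grid partition of the image."""
    H, W = a.shape
    rb = [(i * H) // grid for i in range(grid + 1)]
    cb = [(j * W) // grid for j in range(grid + 1)]
    sums = np.add.reduceat(np.add.reduceat(a, rb[:-1], axis=0), cb[:-1], axis=1)
    counts = np.outer(np.diff(rb), np.diff(cb))
    return sums / counts


def colour_layout(image, n_y: int = 6, n_c: int = 3) -> DescriptorVector:
    """Colour layout descriptor of a grayscale image.

    The image is mapped to YCbCr with Y = intensity and constant chroma
    Cb = Cr = 128, partitioned into an 8x8 grid of blocks (3 or 4 pixels per
    side for a 28x28 image), each block reduced to its mean, and the 8x8
    block-mean matrix of each channel transformed by the orthonormal 2-D DCT.
    The first ``n_y`` Y and ``n_c`` per-chroma zigzag coefficients are kept,
    real-valued.  Default length 6 + 3 + 3 = 12.
    """
    if n_y < 1 or n_c < 0 or n_y > 64 or n_c > 64:
        raise ValueError("invalid coefficient counts")
    a = _as_raw_gray(image)
    y_means = _block_means(a)
    chroma_means = np.full((8, 8), 128.0)
    vec = []
    for means, count in ((y_means, n_y), (chroma_means, n_c), (chroma_means, n_c)):
        coeffs = dctn(means, norm="ortho")
        vec.extend(coeffs[r, c] for r, c in _ZIGZAG8[:count])
    return DescriptorVector("colour_layout", np.array(vec))


# ---------------------------------------------------------------------------
# batch extraction
# ---------------------------------------------------------------------------

_EXTRACTORS = {
    "jpeg_coefficient": jpeg_coefficient_features,
    "auto_color_correlogram": auto_color_correlogram,
    "colour_layout": colour_layout,
}

#: CLI short names
FILTER_ALIASES = {"jpeg": "jpeg_coefficient", "acc": "auto_color_correlogram",
                  "cld": "colour_layout"}


def resolve_filter_id(name: str) -> str:
    fid = FILTER_ALIASES.get(name, name)
    if fid not in _EXTRACTORS:
        raise ValueError(f"unknown filter {name!r}; choose from {FILTER_IDS}")
    return fid


def extract_features(images, filter_id: str, **params) -> np.ndarray:
    """Apply one filter to a batch of raw images; returns an (n, L) array."""
    fid = resolve_filter_id(filter_id)
    fn = _EXTRACTORS[fid]
    images = np.asarray(images)
    if images.ndim == 2:
        images = images[None]
    rows = [fn(img, **params).values for img in images]
    return np.stack(rows, axis=0)
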