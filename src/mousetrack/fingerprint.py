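"""Correlogram appearance fingerprints.

Identity across frames rests on an appearance signature in the idTracker
lineage: for every unordered pair of pixels inside a buffered crop of the
animal, take the Euclidean distance ``d`` between the pixels and the sum
``s`` of their grayscale intensities, and accumulate the pairs into a 2-D
histogram over (d, s). The histogram is invariant to translation and robust
to rotation (pair distances are preserved), yet discriminates animals whose
coat texture or brightness differ.

The buffering step dilates the detected mask (10 iterations of a 3x3 kernel
by default), blurs it with a 7x7 Gaussian, and thresholds above zero, so the
crop includes a soft margin around the animal. Crops are downscaled by an
integer factor (4 by default) before pair enumeration to bound the O(k^2)
pair count.

Histograms are normalized to unit mass so that crops of different sizes are
comparable; two fingerprints are compared by the mean absolute difference of
their bins (lower = more similar).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from scipy.spatial.distance import pdist

from .config import FingerprintParams
from .segmentation import MaskRegion, to_grayscale

#: intensity sums of 8-bit pixel pairs live in [0, 510]
_SUM_RANGE = 511.0

from functools import lru_cache


@lru_cache(maxsize=64)
def _pair_indices(k: int) -> tuple[np.ndarray, np.ndarray]:
    """Upper-triangle pair indices in pdist's condensed ordering."""
    return np.triu_indices(k, 1)


@dataclass(frozen=True)
class Correlogram:
    """Normalized 2-D histogram over (pixel-pair distance, intensity sum)."""

    hist: np.ndarray  # (n_dist_bins, n_sum_bins), sums to 1 when total_pairs > 0
    total_pairs: int

    def __post_init__(self) -> None:
        if np.any(self.hist < 0):
            raise ValueError("histogram masses must be non-negative")


def _gaussian_kernel1d(ksize: int) -> np.ndarray:
    """Odd-sized 1-D Gaussian kernel with the conventional sigma for its size."""
    if ksize == 1:
        return np.ones(1)
    sigma = 0.3 * ((ksize - 1) * 0.5 - 1) + 0.8
    x = np.arange(ksize) - (ksize - 1) / 2
    k = np.exp(-(x**2) / (2 * sigma**2))
    return k / k.sum()


def buffered_mask(mask: np.ndarray, params: FingerprintParams) -> np.ndarray:
    """Dilate + blur + threshold a binary mask into its buffered support."""
    m = mask.astype(bool)
    if params.dilation_iters > 0:
        kernel = np.ones((params.dilation_kernel, params.dilation_kernel), dtype=bool)
        m = ndimage.binary_dilation(m, structure=kernel, iterations=params.dilation_iters)
    if params.blur_kernel > 1:
        k1 = _gaussian_kernel1d(params.blur_kernel)
        blurred = ndimage.convolve1d(m.astype(np.float64), k1, axis=0, mode="constant")
        blurred = ndimage.convolve1d(blurred, k1, axis=1, mode="constant")
        m = blurred > 0
    return m


def _downscale_block(arr: np.ndarray, f: int) -> np.ndarray:
    """Block-average downscale by integer factor ``f`` (zero-padded to fit)."""
    if f == 1:
        return arr.astype(np.float64)
    h, w = arr.shape
    H, W = -(-h // f) * f, -(-w // f) * f
    padded = np.zeros((H, W), dtype=np.float64)
    padded[:h, :w] = arr
    return padded.reshape(H // f, f, W // f, f).mean(axis=(1, 3))


def buffer_and_crop(
    frame: np.ndarray, region: MaskRegion, params: FingerprintParams
) -> tuple[np.ndarray, np.ndarray]:
    """Extract the masked grayscale patch that feeds the correlogram.

    Returns ``(patch, mask)`` at the downscaled resolution: ``patch`` is the
    grayscale crop with pixels outside the buffered mask zeroed, ``mask``
    marks which downscaled pixels take part in pair enumeration.
    """
    if region.area_px == 0:
        raise ValueError("cannot fingerprint an empty mask")
    H, W = region.frame_shape
    # grow the bbox by the maximum buffering reach before dilating
    reach = params.dilation_iters * (params.dilation_kernel // 2) + params.blur_kernel // 2
    r0, c0 = region.offset
    h, w = region.mask.shape
    R0, C0 = max(0, r0 - reach), max(0, c0 - reach)
    R1, C1 = min(H, r0 + h + reach), min(W, c0 + w + reach)
    local = np.zeros((R1 - R0, C1 - C0), dtype=bool)
    local[r0 - R0 : r0 - R0 + h, c0 - C0 : c0 - C0 + w] = region.mask
    buf = buffered_mask(local, params)
    rows, cols = np.nonzero(buf)
    rr0, rr1 = rows.min(), rows.max() + 1
    cc0, cc1 = cols.min(), cols.max() + 1
    gray = to_grayscale(frame)
    crop = gray[R0 + rr0 : R0 + rr1, C0 + cc0 : C0 + cc1].copy()
    bufc = buf[rr0:rr1, cc0:cc1]
    crop[~bufc] = 0.0
    f = params.downscale
    patch = _downscale_block(crop, f)
    mask_small = _downscale_block(bufc.astype(np.float64), f) > 0
    return patch, mask_small


def compute_correlogram(
    patch: np.ndarray, mask: np.ndarray, params: FingerprintParams
) -> Correlogram:
    """Histogram all unordered included-pixel pairs of a masked patch.

    Bin indices follow ``floor(d / max_dist_px * n_dist_bins)`` (clamped to
    the last, overflow bin) and ``floor(s / 511 * n_sum_bins)`` with
    ``s = I(p) + I(q)``. Self-pairs are excluded. With fewer than two included
    pixels the zero correlogram (``total_pairs = 0``) is returned. If
    ``max_pairs`` is set and exceeded, a seeded uniform subsample is used.
    """
    rows, cols = np.nonzero(mask)
    k = rows.size
    hist = np.zeros((params.n_dist_bins, params.n_sum_bins))
    if k < 2:
        return Correlogram(hist=hist, total_pairs=0)
    coords = np.column_stack([rows, cols]).astype(np.float64)
    intensities = np.asarray(patch, dtype=np.float64)[rows, cols]
    d = pdist(coords)
    # condensed-form pair sums, same ordering as pdist
    iu, ju = _pair_indices(k)
    s = intensities[iu] + intensities[ju]
    if params.max_pairs is not None and d.size > params.max_pairs:
        rng = np.random.default_rng(params.pair_seed)
        sel = rng.choice(d.size, size=params.max_pairs, replace=False)
        d, s = d[sel], s[sel]
    di = np.minimum(
        (d * (params.n_dist_bins / params.max_dist_px)).astype(np.int64),
        params.n_dist_bins - 1,
    )
    si = np.minimum(
        (s * (params.n_sum_bins / _SUM_RANGE)).astype(np.int64), params.n_sum_bins - 1
    )
    flat = np.bincount(
        di * params.n_sum_bins + si, minlength=params.n_dist_bins * params.n_sum_bins
    )
    hist = flat.reshape(params.n_dist_bins, params.n_sum_bins).astype(np.float64)
    total = int(d.size)
    return Correlogram(hist=hist / total, total_pairs=total)


def fingerprint_region(
    frame: np.ndarray, region: MaskRegion, params: FingerprintParams
) -> Correlogram:
    """Full fingerprint pipeline for one detection: buffer, crop, histogram."""
    patch, mask = buffer_and_crop(frame, region, params)
    return compute_correlogram(patch, mask, params)


def dissimilarity(a: Correlogram, b: Correlogram) -> float:
    """Mean absolute bin difference between two correlograms.

    Symmetric; zero for identical histograms; at most
    ``2 / (n_dist_bins * n_sum_bins)`` for normalized inputs.
    """
    if a.hist.shape != b.hist.shape:
        raise ValueError(f"correlogram shapes differ: {a.hist.shape} vs {b.hist.shape}")
    return float(np.abs(a.hist - b.hist).mean())
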