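"""Per-frame instance detection and contour post-processing.

The bundled detector is a classical threshold/connected-component segmenter
for dark animals on a bright arena. Any callable mapping a frame to a sequence
of :class:`MaskRegion` can stand in for it (for example, masks precomputed by
an external neural detector and loaded from VIA annotations), so the tracking
and correction stages are detector-agnostic.

Contour post-processing follows the raster conventions used throughout the
package: 0-based coordinates, origin top-left, x rightward, y downward.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage import measure
from skimage.filters import threshold_otsu
from skimage.morphology import disk

from .config import SegmentationParams

#: luma weights used for RGB -> grayscale conversion
_LUMA = np.array([0.299, 0.587, 0.114])


def to_grayscale(image: np.ndarray) -> np.ndarray:
    """Convert an RGB(A) frame to float grayscale; grayscale passes through."""
    img = np.asarray(image)
    if img.ndim == 2:
        return img.astype(np.float64)
    return img[..., :3].astype(np.float64) @ _LUMA


@dataclass
class MaskRegion:
    """A detected animal instance in one frame.

    The mask is stored bbox-local with an (row, col) offset; ``centroid`` is
    the geometric center (mean of set-pixel coordinates) in full-frame float
    pixels, ordered (x, y).
    """

    frame_index: int
    mask: np.ndarray  # bool, bbox-local
    offset: tuple[int, int]  # (row0, col0) of the bbox in the frame
    frame_shape: tuple[int, int]
    _contour: np.ndarray | None = field(default=None, repr=False)

    @property
    def area_px(self) -> int:
        return int(self.mask.sum())

    @property
    def centroid(self) -> tuple[float, float]:
        rows, cols = np.nonzero(self.mask)
        r0, c0 = self.offset
        return (float(cols.mean()) + c0, float(rows.mean()) + r0)

    def full_mask(self) -> np.ndarray:
        """Frame-sized boolean mask."""
        out = np.zeros(self.frame_shape, dtype=bool)
        r0, c0 = self.offset
        h, w = self.mask.shape
        out[r0 : r0 + h, c0 : c0 + w] = self.mask
        return out

    @property
    def contour(self) -> np.ndarray:
        """Outer boundary polygon, (n, 2) float array of (x, y) vertices."""
        if self._contour is None:
            self._contour = mask_contour(self.mask, self.offset)
        return self._contour


def mask_contour(mask: np.ndarray, offset: tuple[int, int] = (0, 0)) -> np.ndarray:
    """Trace the outer boundary of a binary mask as an (x, y) polygon."""
    padded = np.pad(mask.astype(float), 1)
    contours = measure.find_contours(padded, 0.5)
    if not contours:
        return np.empty((0, 2))
    # outer boundary = longest contour
    rc = max(contours, key=len)
    r0, c0 = offset
    xy = np.column_stack([rc[:, 1] - 1 + c0, rc[:, 0] - 1 + r0])
    if len(xy) > 1 and np.allclose(xy[0], xy[-1]):
        xy = xy[:-1]
    return xy


@dataclass(frozen=True)
class RegionFromMask:
    """Build a MaskRegion from a frame-sized boolean mask."""

    @staticmethod
    def build(frame_index: int, full_mask: np.ndarray) -> MaskRegion:
        rows, cols = np.nonzero(full_mask)
        if rows.size == 0:
            raise ValueError("empty mask")
        r0, r1 = rows.min(), rows.max() + 1
        c0, c1 = cols.min(), cols.max() + 1
        return MaskRegion(
            frame_index=frame_index,
            mask=full_mask[r0:r1, c0:c1].copy(),
            offset=(int(r0), int(c0)),
            frame_shape=full_mask.shape,
        )


def segment_frame(
    image: np.ndarray,
    params: SegmentationParams,
    frame_index: int = 0,
) -> list[MaskRegion]:
    """Detect dark blobs in one frame.

    Thresholds the grayscale frame (fixed level or Otsu), labels connected
    components with 8-connectivity, filters by area, and returns regions in
    descending area order. Deterministic given (image, params).
    """
    gray = to_grayscale(image)
    if params.threshold == "otsu":
        level = threshold_otsu(gray)
    else:
        level = float(params.threshold)
    fg = gray < level
    labels, n = ndimage.label(fg, structure=np.ones((3, 3), dtype=int))
    if n == 0:
        return []
    areas = ndimage.sum_labels(fg, labels, index=np.arange(1, n + 1))
    keep = [
        (int(a), lab)
        for lab, a in zip(range(1, n + 1), areas)
        if params.min_area_px <= a <= params.max_area_px
    ]
    keep.sort(key=lambda t: (-t[0], t[1]))  # area desc, label asc for ties
    slices = ndimage.find_objects(labels)
    regions = []
    for _, lab in keep:
        sl = slices[lab - 1]
        regions.append(
            MaskRegion(
                frame_index=frame_index,
                mask=labels[sl] == lab,
                offset=(sl[0].start, sl[1].start),
                frame_shape=gray.shape,
            )
        )
    return regions


def expand_contour(region: MaskRegion, expand_px: int) -> MaskRegion:
    """Expand a detected region by ``expand_px`` pixels (disk dilation).

    The mask is dilated with a disk structuring element of radius
    ``expand_px`` and the contour re-extracted; the result is clipped to the
    frame bounds. ``expand_px = 0`` returns an identical region.
    """
    if expand_px < 0:
        raise ValueError("expand_px must be >= 0")
    if expand_px == 0:
        return MaskRegion(
            frame_index=region.frame_index,
            mask=region.mask.copy(),
            offset=region.offset,
            frame_shape=region.frame_shape,
        )
    r0, c0 = region.offset
    h, w = region.mask.shape
    H, W = region.frame_shape
    # pad the local mask by the dilation radius, clipped to frame bounds
    pt = min(expand_px, r0)
    pl = min(expand_px, c0)
    pb = min(expand_px, H - (r0 + h))
    pr = min(expand_px, W - (c0 + w))
    padded = np.pad(region.mask, ((pt, pb), (pl, pr)))
    dilated = ndimage.binary_dilation(padded, structure=disk(expand_px))
    return MaskRegion(
        frame_index=region.frame_index,
        mask=dilated,
        offset=(r0 - pt, c0 - pl),
        frame_shape=region.frame_shape,
    )


def _perpendicular_distances(points: np.ndarray, a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Distance from each point to the segment-supporting line a-b (or to a if a==b)."""
    ab = b - a
    norm = np.hypot(*ab)
    if norm == 0.0:
        return np.hypot(points[:, 0] - a[0], points[:, 1] - a[1])
    rel = points - a
    return np.abs(ab[0] * rel[:, 1] - ab[1] * rel[:, 0]) / norm


def _rdp_open(points: np.ndarray, epsilon: float) -> np.ndarray:
    """Iterative Ramer-Douglas-Peucker on an open polyline; keeps endpoints."""
    n = len(points)
    keep = np.zeros(n, dtype=bool)
    keep[0] = keep[-1] = True
    stack = [(0, n - 1)]
    while stack:
        i, j = stack.pop()
        if j <= i + 1:
            continue
        d = _perpendicular_distances(points[i + 1 : j], points[i], points[j])
        k = int(np.argmax(d))
        if d[k] > epsilon:
            k += i + 1
            keep[k] = True
            stack.append((i, k))
            stack.append((k, j))
    return points[keep]


def simplify_rdp(poly: np.ndarray, epsilon: float) -> np.ndarray:
    """Simplify a closed polygon with the Ramer-Douglas-Peucker algorithm.

    The closed contour is split at its two mutually farthest vertices and each
    open chain simplified independently; every discarded vertex lies within
    ``epsilon`` of the simplified chain. Vertex order is preserved, starting
    from the first split vertex. A fully collinear polygon degenerates to its
    two extreme vertices.
    """
    pts = np.asarray(poly, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2 or len(pts) < 3:
        raise ValueError("polygon must be an (n >= 3, 2) array")
    if epsilon < 0:
        raise ValueError("epsilon must be >= 0")
    if epsilon == 0:
        return pts.copy()
    # split at the two mutually farthest vertices (O(n^2), vectorized)
    d2 = ((pts[:, None, :] - pts[None, :, :]) ** 2).sum(-1)
    i, j = np.unravel_index(int(np.argmax(d2)), d2.shape)
    i, j = min(i, j), max(i, j)
    chain1 = pts[i : j + 1]
    chain2 = np.concatenate([pts[j:], pts[: i + 1]])
    out1 = _rdp_open(chain1, epsilon)
    out2 = _rdp_open(chain2, epsilon)
    # drop shared endpoints when joining the two simplified chains
    out = np.concatenate([out1[:-1], out2[:-1]])
    return out
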