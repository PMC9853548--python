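"""Independent brute-force reference implementations used only by tests.

These are deliberately naive (textbook recursion, exhaustive double loops)
and share no code with the package's implementations.
"""

from __future__ import annotations

import math

import numpy as np


def rdp_naive(points: np.ndarray, epsilon: float) -> np.ndarray:
    """Textbook recursive Ramer-Douglas-Peucker on an open polyline."""

    def point_line_dist(p, a, b):
        if a[0] == b[0] and a[1] == b[1]:
            return math.hypot(p[0] - a[0], p[1] - a[1])
        num = abs(
            (b[0] - a[0]) * (a[1] - p[1]) - (a[0] - p[0]) * (b[1] - a[1])
        )
        return num / math.hypot(b[0] - a[0], b[1] - a[1])

    def recurse(pts):
        if len(pts) <= 2:
            return list(pts)
        dmax, idx = -1.0, 0
        for k in range(1, len(pts) - 1):
            d = point_line_dist(pts[k], pts[0], pts[-1])
            if d > dmax:
                dmax, idx = d, k
        if dmax > epsilon:
            left = recurse(pts[: idx + 1])
            right = recurse(pts[idx:])
            return left[:-1] + right
        return [pts[0], pts[-1]]

    return np.array(recurse(list(map(tuple, points))))


def rdp_closed_naive(points: np.ndarray, epsilon: float) -> np.ndarray:
    """Closed-contour RDP: split at the two mutually farthest vertices."""
    pts = np.asarray(points, dtype=float)
    if epsilon == 0:
        return pts.copy()
    best, bi, bj = -1.0, 0, 0
    for i in range(len(pts)):
        for j in range(i + 1, len(pts)):
            d = math.hypot(*(pts[i] - pts[j]))
            if d > best:
                best, bi, bj = d, i, j
    chain1 = pts[bi : bj + 1]
    chain2 = np.concatenate([pts[bj:], pts[: bi + 1]])
    out1 = rdp_naive(chain1, epsilon)
    out2 = rdp_naive(chain2, epsilon)
    return np.concatenate([out1[:-1], out2[:-1]])


def correlogram_naive(
    patch: np.ndarray,
    mask: np.ndarray,
    n_dist_bins: int,
    n_sum_bins: int,
    max_dist_px: float,
) -> tuple[np.ndarray, int]:
    """Exhaustive double-loop pair histogram (integer counts)."""
    coords = [(r, c) for r in range(mask.shape[0]) for c in range(mask.shape[1]) if mask[r, c]]
    hist = np.zeros((n_dist_bins, n_sum_bins), dtype=np.int64)
    total = 0
    for a in range(len(coords)):
        for b in range(a + 1, len(coords)):
            (r1, c1), (r2, c2) = coords[a], coords[b]
            d = math.hypot(r1 - r2, c1 - c2)
            s = float(patch[r1, c1]) + float(patch[r2, c2])
            di = min(int(d / max_dist_px * n_dist_bins), n_dist_bins - 1)
            si = min(int(s / 511.0 * n_sum_bins), n_sum_bins - 1)
            hist[di, si] += 1
            total += 1
    return hist, total


def dilate_disk_naive(mask: np.ndarray, radius: int) -> np.ndarray:
    """Brute-force disk dilation: a pixel is set iff any set pixel of the
    input lies within ``radius`` (Euclidean)."""
    out = np.zeros_like(mask, dtype=bool)
    rows, cols = np.nonzero(mask)
    H, W = mask.shape
    for r in range(H):
        for c in range(W):
            if np.any((rows - r) ** 2 + (cols - c) ** 2 <= radius**2):
                out[r, c] = True
    return out


def buffered_mask_naive(mask: np.ndarray, iters: int, ksize: int, blur: int) -> np.ndarray:
    """Naive dilation (square kernel, repeated) + full-kernel Gaussian support."""
    m = mask.astype(bool).copy()
    half = ksize // 2
    H, W = m.shape
    for _ in range(iters):
        nxt = np.zeros_like(m)
        for r in range(H):
            for c in range(W):
                r0, r1 = max(0, r - half), min(H, r + half + 1)
                c0, c1 = max(0, c - half), min(W, c + half + 1)
                nxt[r, c] = m[r0:r1, c0:c1].any()
        m = nxt
    if blur > 1:
        bh = blur // 2
        nxt = np.zeros_like(m)
        for r in range(H):
            for c in range(W):
                r0, r1 = max(0, r - bh), min(H, r + bh + 1)
                c0, c1 = max(0, c - bh), min(W, c + bh + 1)
                nxt[r, c] = m[r0:r1, c0:c1].any()
        m = nxt
    return m
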