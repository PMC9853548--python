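"""Frame-to-frame identity assignment.

Animals detected in the first usable frame receive IDs 0..n-1; in every later
frame, the dissimilarity between each ID's last real fingerprint and each new
detection is computed, all (ID, detection) pairs are sorted by ascending
dissimilarity, and pairs are accepted greedily — a pair is taken iff neither
its ID nor its detection is already used. Surplus detections simply lose the
competition and are ignored; IDs with no detection left are misses for that
frame and keep their previous fingerprint.

Greedy ascending matching is deliberately not optimal bipartite assignment:
the first and second lowest values win in order, which can differ from the
minimum-total-cost matching.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .config import RunConfig
from .fingerprint import Correlogram, dissimilarity, fingerprint_region
from .io import make_track_table
from .segmentation import MaskRegion, segment_frame

logger = logging.getLogger(__name__)


class InitializationError(RuntimeError):
    """No frame in the stream contained enough detections to assign IDs."""


@dataclass
class IdentityState:
    """Last real observation per animal ID."""

    fingerprints: dict[int, Correlogram]
    centroids: dict[int, tuple[float, float]]
    last_real_frame: dict[int, int]

    @property
    def ids(self) -> list[int]:
        return sorted(self.fingerprints)


@dataclass
class Assignment:
    """Result of matching one frame's detections against the identity state."""

    matches: dict[int, int]  # detection_index -> animal_id
    ignored: set[int] = field(default_factory=set)
    unmatched_ids: set[int] = field(default_factory=set)


def initialize_ids(detections: list[MaskRegion], n_mice: int) -> list[tuple[int, MaskRegion]]:
    """Assign IDs 0..n-1 to the n largest detections of the first usable frame.

    The ``n_mice`` largest-area detections are kept (the rest ignored) and
    ordered by (centroid_y, centroid_x) ascending; deterministic.
    """
    if len(detections) < n_mice:
        raise ValueError(
            f"need >= {n_mice} detections to initialize, got {len(detections)}"
        )
    by_area = sorted(
        range(len(detections)), key=lambda i: (-detections[i].area_px, i)
    )[:n_mice]
    kept = [detections[i] for i in by_area]
    kept.sort(key=lambda r: (r.centroid[1], r.centroid[0]))
    return list(enumerate(kept))


def greedy_match(ids: list[int], matrix) -> Assignment:
    """Greedy ascending matching given a dissimilarity matrix.

    ``matrix[row, col]`` is the dissimilarity between ``ids[row]`` and
    detection ``col``. All pairs are sorted ascending, ties broken by
    (ID, detection index); a pair is accepted iff neither member is already
    used, until min(n_ids, n_detections) pairs are accepted. This is the
    first-and-second-lowest-wins rule, which can differ from the
    minimum-total-cost bipartite assignment.
    """
    matrix = np.asarray(matrix, dtype=float)
    n_det = matrix.shape[1] if matrix.ndim == 2 else 0
    pairs = [
        (matrix[r, j], i, j) for r, i in enumerate(ids) for j in range(n_det)
    ]
    pairs.sort()
    matches: dict[int, int] = {}
    used_ids: set[int] = set()
    target = min(len(ids), n_det)
    for _, i, j in pairs:
        if len(matches) == target:
            break
        if i in used_ids or j in matches:
            continue
        matches[j] = i
        used_ids.add(i)
    return Assignment(
        matches=matches,
        ignored=set(range(n_det)) - set(matches),
        unmatched_ids=set(ids) - used_ids,
    )


def match_frame(
    state: IdentityState, fingerprints: list[Correlogram]
) -> Assignment:
    """Greedy ascending-dissimilarity matching of detections to IDs.

    Builds the full dissimilarity matrix between each ID's last real
    fingerprint and each detection and applies :func:`greedy_match`.
    """
    ids = state.ids
    if fingerprints:
        matrix = np.array(
            [[dissimilarity(state.fingerprints[i], fp) for fp in fingerprints] for i in ids]
        )
    else:
        matrix = np.empty((len(ids), 0))
    return greedy_match(ids, matrix)


def track_video(stream, config: RunConfig, detector=None):
    """Track a frame stream end to end.

    ``detector`` is any callable ``(frame, frame_index) -> list[MaskRegion]``;
    by default the bundled threshold segmenter with ``config.segmentation``.
    Returns ``(table, state)`` where ``table`` is the uncorrected track table
    (one row per matched ID per frame; missed IDs have no row) and ``state``
    the final :class:`IdentityState`.

    Frames before the first one with >= n_mice detections are skipped (and
    logged); if no such frame exists an :class:`InitializationError` is
    raised naming the maximum simultaneous detection count seen.
    """
    n = config.n_mice
    if detector is None:
        det_params = config.segmentation

        def detector(frame, frame_index):
            return segment_frame(frame, det_params, frame_index=frame_index)

    fp_params = config.fingerprint
    rows: list[dict] = []
    state: IdentityState | None = None
    max_seen = 0
    for frame_index, frame in enumerate(stream):
        detections = detector(frame, frame_index)
        max_seen = max(max_seen, len(detections))
        if state is None:
            if len(detections) < n:
                logger.debug(
                    "frame %d: %d detections, waiting for %d to initialize",
                    frame_index, len(detections), n,
                )
                continue
            state = IdentityState({}, {}, {})
            for animal_id, region in initialize_ids(detections, n):
                fp = fingerprint_region(frame, region, fp_params)
                state.fingerprints[animal_id] = fp
                cx, cy = region.centroid
                state.centroids[animal_id] = (cx, cy)
                state.last_real_frame[animal_id] = frame_index
                rows.append(
                    {"frame": frame_index, "id": animal_id, "cx_px": cx,
                     "cy_px": cy, "area_px": float(region.area_px)}
                )
            logger.info("initialized %d IDs at frame %d", n, frame_index)
            continue
        fingerprints = [fingerprint_region(frame, r, fp_params) for r in detections]
        assignment = match_frame(state, fingerprints)
        for j, animal_id in sorted(assignment.matches.items(), key=lambda t: t[1]):
            region = detections[j]
            cx, cy = region.centroid
            state.fingerprints[animal_id] = fingerprints[j]
            state.centroids[animal_id] = (cx, cy)
            state.last_real_frame[animal_id] = frame_index
            rows.append(
                {"frame": frame_index, "id": animal_id, "cx_px": cx,
                 "cy_px": cy, "area_px": float(region.area_px)}
            )
        if assignment.unmatched_ids:
            logger.debug(
                "frame %d: missed IDs %s", frame_index, sorted(assignment.unmatched_ids)
            )
    if state is None:
        raise InitializationError(
            f"no frame had >= {n} detections (max simultaneous count seen: {max_seen})"
        )
    return make_track_table(rows), state
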