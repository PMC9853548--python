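"""Semi-automatic correction of tracking errors.

Two error classes are handled:

* **Sporadic misses** — frames where the detector underestimated the number
  of animals. These are filled automatically by carrying the animal's last
  known record forward (coordinates held constant, ``filled = 1``), up to a
  configurable maximum gap; longer gaps are structural and reported, not
  filled.

* **Irreversible ID switches** — persistent exchanges of two identities after
  a tracking error. These cannot be fixed safely without a human: the machine
  emits *tracking warnings* (an ID whose previous position is strictly closer
  to some other ID's new position than to its own) and a reviewer answers
  with swap directives, which relabel the two IDs from a frame onward.

Warnings are advisory only and never trigger an automatic swap — most
warnings come from near passes, not real switches, and a wrong automatic
swap would corrupt the rest of the track.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import CorrectionParams
from .io import make_track_table

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class WarningRecord:
    """A candidate ID switch between frames N and N+1, for human review."""

    frame_index: int  # the N+1 frame
    animal_id: int
    dist_same: float  # px, ID's own frame-N -> frame-N+1 displacement
    dist_min: float  # px, smallest distance from ID's frame-N position
    nearest_other_id: int


@dataclass(frozen=True)
class SwapDirective:
    """Human instruction: exchange labels id_a and id_b from from_frame on."""

    from_frame: int
    id_a: int
    id_b: int

    def __post_init__(self) -> None:
        if self.id_a == self.id_b:
            raise ValueError("swap directive needs two distinct IDs")


@dataclass
class GapReport:
    animal_id: int
    start_frame: int
    length: int


def fill_misses(
    table: pd.DataFrame, params: CorrectionParams | None = None
) -> tuple[pd.DataFrame, list[GapReport]]:
    """Fill sporadic misses by carrying each ID's last record forward.

    For every frame after an ID's first appearance where the ID has no
    record, a record is copied from its most recent frame (centroid and area
    unchanged, ``filled = 1``). Gaps longer than ``params.max_gap`` frames
    are left unfilled and returned as :class:`GapReport` entries. Existing
    real records are never altered.
    """
    if params is None:
        params = CorrectionParams()
    if table.empty:
        return table.copy(), []
    frames = np.arange(table["frame"].min(), table["frame"].max() + 1)
    new_rows: list[dict] = []
    gaps: list[GapReport] = []
    for animal_id, sub in table.groupby("id"):
        present = set(sub["frame"])
        by_frame = sub.set_index("frame")
        first = sub["frame"].min()
        missing = [f for f in frames if f > first and f not in present]
        # group consecutive missing frames into gaps
        run: list[int] = []
        runs: list[list[int]] = []
        for f in missing:
            if run and f == run[-1] + 1:
                run.append(f)
            else:
                run = [f]
                runs.append(run)
        for run in runs:
            if len(run) > params.max_gap:
                gaps.append(GapReport(int(animal_id), int(run[0]), len(run)))
                logger.warning(
                    "ID %d: gap of %d frames at %d exceeds max_gap=%d, not filled",
                    animal_id, len(run), run[0], params.max_gap,
                )
                continue
            src = by_frame.loc[: run[0] - 1].iloc[-1]
            for f in run:
                new_rows.append(
                    {
                        "frame": int(f),
                        "id": int(animal_id),
                        "cx_px": float(src["cx_px"]),
                        "cy_px": float(src["cy_px"]),
                        "area_px": float(src["area_px"]),
                        "filled": 1,
                        "warned": 0,
                    }
                )
    if not new_rows:
        return table.sort_values(["frame", "id"], ignore_index=True), gaps
    filled = make_track_table(table.to_dict("records") + new_rows)
    return filled, gaps


def detect_warnings(table: pd.DataFrame) -> list[WarningRecord]:
    """Flag candidate ID switches between consecutive frames.

    For each consecutive frame pair (N, N+1) and each ID ``i`` present in
    both: compute the distance from i's centroid at N to every ID's centroid
    at N+1; emit a warning iff some other ID is *strictly* closer than i's
    own new position. Exact ties emit no warning. Run on a miss-filled table
    so every frame compares all ID pairs.
    """
    warnings: list[WarningRecord] = []
    if table.empty:
        return warnings
    pivot_x = table.pivot_table(index="frame", columns="id", values="cx_px")
    pivot_y = table.pivot_table(index="frame", columns="id", values="cy_px")
    frames = pivot_x.index.to_numpy()
    ids = pivot_x.columns.to_numpy()
    X = pivot_x.to_numpy()
    Y = pivot_y.to_numpy()
    for t in range(len(frames) - 1):
        if frames[t + 1] != frames[t] + 1:
            continue  # only consecutive frames are compared
        dx = X[t][:, None] - X[t + 1][None, :]
        dy = Y[t][:, None] - Y[t + 1][None, :]
        dist = np.hypot(dx, dy)  # dist[i, j] = ID i at N -> ID j at N+1
        for a, i in enumerate(ids):
            row = dist[a]
            if np.isnan(row[a]) or np.isnan(row).all():
                continue
            own = row[a]
            others = np.where(np.arange(len(ids)) != a, row, np.inf)
            b = int(np.nanargmin(np.where(np.isnan(others), np.inf, others)))
            if others[b] < own:
                warnings.append(
                    WarningRecord(
                        frame_index=int(frames[t + 1]),
                        animal_id=int(i),
                        dist_same=float(own),
                        dist_min=float(others[b]),
                        nearest_other_id=int(ids[b]),
                    )
                )
    warnings.sort(key=lambda w: (w.frame_index, w.animal_id))
    return warnings


def mark_warnings(table: pd.DataFrame, warnings: list[WarningRecord]) -> pd.DataFrame:
    """Return a copy of the table with ``warned = 1`` on flagged records."""
    out = table.copy()
    flagged = {(w.frame_index, w.animal_id) for w in warnings}
    if flagged:
        key = list(zip(out["frame"], out["id"]))
        out["warned"] = [1 if k in flagged else w for k, w in zip(key, out["warned"])]
    return out


class SwapError(ValueError):
    """A swap directive referenced an unknown ID or out-of-range frame."""


def apply_swaps(
    table: pd.DataFrame, directives: list[SwapDirective]
) -> tuple[pd.DataFrame, list[tuple[SwapDirective, str]]]:
    """Exchange two ID labels from a frame to the end of the table.

    Directives are applied in ``from_frame`` order. Invalid directives
    (unknown ID, frame outside the table range) are skipped and returned as
    ``(directive, reason)`` pairs so a caller can signal partial failure;
    valid directives are still applied.
    """
    out = table.copy()
    failures: list[tuple[SwapDirective, str]] = []
    if out.empty:
        return out, [(d, "empty table") for d in directives]
    known_ids = set(out["id"].unique())
    fmin, fmax = int(out["frame"].min()), int(out["frame"].max())
    for d in sorted(directives, key=lambda d: d.from_frame):
        if d.id_a not in known_ids or d.id_b not in known_ids:
            failures.append((d, f"unknown ID in {d}"))
            continue
        if not (fmin <= d.from_frame <= fmax):
            failures.append((d, f"frame {d.from_frame} outside [{fmin}, {fmax}]"))
            continue
        sel = out["frame"] >= d.from_frame
        ids = out.loc[sel, "id"].to_numpy().copy()
        a_mask, b_mask = ids == d.id_a, ids == d.id_b
        ids[a_mask], ids[b_mask] = d.id_b, d.id_a
        out.loc[sel, "id"] = ids
    out = out.sort_values(["frame", "id"], ignore_index=True)
    return out, failures
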