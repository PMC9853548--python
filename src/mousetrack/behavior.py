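"""Social-behavior analytics over a corrected track table.

All quantities are computed from geometric centers (area centroids) in
calibrated centimetres: per-animal cumulative traveled distance, per-pair
centroid distance, and cumulative proximity time — the duration two animals'
centers are strictly closer than a threshold (6 cm by default), a standard
sociality proxy for group-housed mice.

Tables must be corrected (miss-filled) first so every frame carries all IDs;
filled frames hold coordinates constant and therefore contribute zero-length
steps to cumulative distance.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .config import AnalysisParams, Calibration


def _trajectory(table: pd.DataFrame, animal_id: int) -> pd.DataFrame:
    sub = table[table["id"] == animal_id].sort_values("frame")
    if sub.empty:
        raise KeyError(f"no records for ID {animal_id}")
    return sub


def cumulative_distance(
    table: pd.DataFrame, animal_id: int, calibration: Calibration
) -> pd.Series:
    """Cumulative traveled distance (cm) of one animal, indexed by frame."""
    sub = _trajectory(table, animal_id)
    x = calibration.to_cm(sub["cx_px"].to_numpy())
    y = calibration.to_cm(sub["cy_px"].to_numpy())
    steps = np.hypot(np.diff(x), np.diff(y))
    cum = np.concatenate([[0.0], np.cumsum(steps)])
    return pd.Series(cum, index=sub["frame"].to_numpy(), name=f"cumdist_cm_{animal_id}")


def _aligned_pair(table: pd.DataFrame, id_a: int, id_b: int):
    a = _trajectory(table, id_a).set_index("frame")
    b = _trajectory(table, id_b).set_index("frame")
    if not a.index.equals(b.index):
        raise ValueError(
            f"IDs {id_a} and {id_b} are not present on the same frames; "
            "run correction (fill_misses) first"
        )
    return a, b


def pair_distance(
    table: pd.DataFrame, id_a: int, id_b: int, calibration: Calibration
) -> pd.Series:
    """Per-frame Euclidean centroid distance (cm) between two animals."""
    a, b = _aligned_pair(table, id_a, id_b)
    d_px = np.hypot(
        a["cx_px"].to_numpy() - b["cx_px"].to_numpy(),
        a["cy_px"].to_numpy() - b["cy_px"].to_numpy(),
    )
    return pd.Series(
        calibration.to_cm(d_px), index=a.index.to_numpy(), name=f"dist_cm_{id_a}_{id_b}"
    )


def proximity_time(
    table: pd.DataFrame,
    id_a: int,
    id_b: int,
    params: AnalysisParams,
    calibration: Calibration,
) -> pd.Series:
    """Cumulative proximity time (s) between two animals, indexed by frame.

    A frame counts as proximate iff the pair distance is *strictly* less than
    ``params.proximity_cm``; the count is divided by ``params.fps``.
    """
    d = pair_distance(table, id_a, id_b, calibration)
    proximate = (d.to_numpy() < params.proximity_cm).astype(np.float64)
    return pd.Series(
        np.cumsum(proximate) / params.fps, index=d.index, name=f"proxtime_s_{id_a}_{id_b}"
    )


def behavior_summary(
    table: pd.DataFrame, params: AnalysisParams, calibration: Calibration
) -> dict:
    """All per-ID and per-pair series for a corrected table."""
    ids = sorted(table["id"].unique())
    out = {
        "cumulative_distance_cm": {
            i: cumulative_distance(table, i, calibration) for i in ids
        },
        "pair_distance_cm": {},
        "proximity_time_s": {},
    }
    for k, a in enumerate(ids):
        for b in ids[k + 1 :]:
            out["pair_distance_cm"][(a, b)] = pair_distance(table, a, b, calibration)
            out["proximity_time_s"][(a, b)] = proximity_time(
                table, a, b, params, calibration
            )
    return out
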