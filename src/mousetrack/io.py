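"""Reading and writing external artifacts.

Covers VIA 2.x polygon annotations (both the bare image-map export and the
full project export), the track-table CSV, warnings and swap-directive CSVs,
and frame streams (PNG/TIFF image directories or video files).

Track tables are plain pandas DataFrames with columns
``frame, id, cx_px, cy_px, area_px, filled, warned`` — one row per detected
(or filled-in) animal per frame. Boolean flags are serialized as 0/1.
"""

from __future__ import annotations

import json
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd

from .config import Calibration

logger = logging.getLogger(__name__)

#: canonical in-memory track-table schema
TRACK_COLUMNS = ["frame", "id", "cx_px", "cy_px", "area_px", "filled", "warned"]


def empty_track_table() -> pd.DataFrame:
    return pd.DataFrame(
        {
            "frame": pd.Series(dtype=np.int64),
            "id": pd.Series(dtype=np.int64),
            "cx_px": pd.Series(dtype=np.float64),
            "cy_px": pd.Series(dtype=np.float64),
            "area_px": pd.Series(dtype=np.float64),
            "filled": pd.Series(dtype=np.int64),
            "warned": pd.Series(dtype=np.int64),
        }
    )


def make_track_table(rows: list[dict]) -> pd.DataFrame:
    """Build a normalized track table from row dicts (missing flags -> 0)."""
    if not rows:
        return empty_track_table()
    df = pd.DataFrame(rows)
    for flag in ("filled", "warned"):
        if flag not in df:
            df[flag] = 0
        else:
            df[flag] = df[flag].fillna(0)
    df = df[TRACK_COLUMNS].astype(
        {
            "frame": np.int64,
            "id": np.int64,
            "cx_px": np.float64,
            "cy_px": np.float64,
            "area_px": np.float64,
            "filled": np.int64,
            "warned": np.int64,
        }
    )
    return df.sort_values(["frame", "id"], ignore_index=True)


def write_track_csv(table: pd.DataFrame, calibration: Calibration, path) -> None:
    """Write a track table with both pixel and calibrated cm coordinates.

    Header: ``frame,id,cx_px,cy_px,cx_cm,cy_cm,area_px,filled,warned``; rows
    sorted by (frame, id); flags as 0/1.
    """
    out = table.sort_values(["frame", "id"]).reset_index(drop=True).copy()
    out["cx_cm"] = calibration.to_cm(out["cx_px"])
    out["cy_cm"] = calibration.to_cm(out["cy_px"])
    cols = ["frame", "id", "cx_px", "cy_px", "cx_cm", "cy_cm", "area_px", "filled", "warned"]
    out[cols].to_csv(path, index=False, float_format="%.17g")


def read_track_csv(path) -> pd.DataFrame:
    """Read a track CSV back into the in-memory schema (cm columns dropped)."""
    df = pd.read_csv(path)
    missing = [c for c in TRACK_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"track CSV {path} missing columns: {missing}")
    return make_track_table(df[TRACK_COLUMNS].to_dict("records"))


# ---------------------------------------------------------------- VIA 2.x JSON


@dataclass
class AnnotatedFrame:
    """Polygons annotated on one image (VIA region order preserved)."""

    filename: str
    polygons: list[np.ndarray]  # each (n >= 3, 2) float, (x, y)
    attributes: list[dict] = field(default_factory=list)


def _via_image_map(data: dict) -> dict:
    if "_via_img_metadata" in data:
        return data["_via_img_metadata"]
    return data


def read_via_annotations(path) -> list[AnnotatedFrame]:
    """Read polygon regions from a VIA 2.x JSON export.

    Accepts both the bare image-map export and the full project export
    (regions nested under ``_via_img_metadata``). Non-polygon regions (rects,
    circles, ...) are skipped with a logged count; a polygon with fewer than
    three vertices is a validation error.
    """
    path = Path(path)
    try:
        data = json.loads(path.read_text())
    except json.JSONDecodeError as exc:
        raise ValueError(f"malformed VIA JSON in {path}: {exc}") from exc
    if not isinstance(data, dict):
        raise ValueError(f"malformed VIA JSON in {path}: top level is not an object")
    frames = []
    skipped = 0
    for key, entry in _via_image_map(data).items():
        if not isinstance(entry, dict) or "regions" not in entry:
            raise ValueError(f"malformed VIA JSON: image key {key!r} has no regions")
        polygons, attrs = [], []
        regions = entry["regions"]
        if isinstance(regions, dict):  # VIA <= 2.0.0 dict form
            regions = [regions[k] for k in sorted(regions, key=int)]
        for region in regions:
            shape = region.get("shape_attributes", {})
            if shape.get("name") != "polygon":
                skipped += 1
                continue
            xs, ys = shape.get("all_points_x"), shape.get("all_points_y")
            if xs is None or ys is None or len(xs) != len(ys):
                raise ValueError(f"malformed polygon in image key {key!r}")
            if len(xs) < 3:
                raise ValueError(f"polygon with < 3 vertices in image key {key!r}")
            polygons.append(np.column_stack([xs, ys]).astype(float))
            attrs.append(region.get("region_attributes", {}))
        frames.append(
            AnnotatedFrame(
                filename=entry.get("filename", key), polygons=polygons, attributes=attrs
            )
        )
    if skipped:
        logger.info("skipped %d non-polygon regions in %s", skipped, path)
    read_via_annotations.last_skipped = skipped
    return frames


read_via_annotations.last_skipped = 0


def write_via_annotations(frames: list[AnnotatedFrame], path, size: int = 0) -> None:
    """Write AnnotatedFrames as a bare VIA 2.x image-map JSON."""
    out = {}
    for fr in frames:
        regions = []
        for i, poly in enumerate(fr.polygons):
            attrs = fr.attributes[i] if i < len(fr.attributes) else {}
            regions.append(
                {
                    "shape_attributes": {
                        "name": "polygon",
                        "all_points_x": [float(x) for x in poly[:, 0]],
                        "all_points_y": [float(y) for y in poly[:, 1]],
                    },
                    "region_attributes": attrs,
                }
            )
        out[f"{fr.filename}{size}"] = {
            "filename": fr.filename,
            "size": size,
            "regions": regions,
            "file_attributes": {},
        }
    Path(path).write_text(json.dumps(out, indent=1, sort_keys=True))


# ------------------------------------------------------- warnings / swaps CSV


def write_warnings_csv(warnings, path) -> None:
    """Columns: frame,id,dist_same,dist_min,other_id."""
    rows = [
        {
            "frame": w.frame_index,
            "id": w.animal_id,
            "dist_same": w.dist_same,
            "dist_min": w.dist_min,
            "other_id": w.nearest_other_id,
        }
        for w in warnings
    ]
    pd.DataFrame(rows, columns=["frame", "id", "dist_same", "dist_min", "other_id"]).to_csv(
        path, index=False, float_format="%.17g"
    )


def read_swaps_csv(path) -> list[tuple[int, int, int]]:
    """Read swap directives (columns frame,id_a,id_b) as tuples."""
    df = pd.read_csv(path)
    for col in ("frame", "id_a", "id_b"):
        if col not in df.columns:
            raise ValueError(f"swaps CSV {path} missing column {col!r}")
    return [(int(r.frame), int(r.id_a), int(r.id_b)) for r in df.itertuples()]


def write_swaps_csv(swaps, path) -> None:
    pd.DataFrame(swaps, columns=["frame", "id_a", "id_b"]).to_csv(path, index=False)


# -------------------------------------------------------------- frame streams

_NUM_RE = re.compile(r"(\d+)")


def _numeric_key(name: str):
    return [int(t) if t.isdigit() else t for t in _NUM_RE.split(name)]


class FrameStream:
    """Sequential access to video frames by 0-based index.

    Sources: a directory of numbered images (sorted numerically) or a video
    file readable by imageio. All frames share width/height.
    """

    def __init__(self, frames, fps: float = 60.0):
        self._frames = frames  # list of paths or arrays
        self.fps = fps
        first = self[0]
        self.height, self.width = first.shape[:2]

    @classmethod
    def from_directory(cls, path, fps: float = 60.0, pattern: str = "*.png") -> "FrameStream":
        files = sorted(Path(path).glob(pattern), key=lambda p: _numeric_key(p.name))
        if not files:
            raise FileNotFoundError(f"no frames matching {pattern} in {path}")
        return cls(files, fps=fps)

    @classmethod
    def from_video(cls, path, fps: float = 60.0) -> "FrameStream":
        frames = list(iio.imiter(path))
        if not frames:
            raise ValueError(f"no frames decoded from {path}")
        return cls(frames, fps=fps)

    @classmethod
    def from_arrays(cls, arrays, fps: float = 60.0) -> "FrameStream":
        return cls(list(arrays), fps=fps)

    @classmethod
    def open(cls, source, fps: float = 60.0) -> "FrameStream":
        p = Path(source)
        if p.is_dir():
            return cls.from_directory(p, fps=fps)
        return cls.from_video(p, fps=fps)

    def __len__(self) -> int:
        return len(self._frames)

    def __getitem__(self, i: int) -> np.ndarray:
        item = self._frames[i]
        if isinstance(item, (str, Path)):
            return np.asarray(iio.imread(item))
        return np.asarray(item)

    def __iter__(self):
        for i in range(len(self)):
            yield self[i]
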