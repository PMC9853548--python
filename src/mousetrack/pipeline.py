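"""End-to-end orchestration: synth/load -> track -> correct -> analyze.

Stages communicate only through documented files (PNG frames, track CSVs,
warnings CSV, stats CSVs), so any stage can be re-run in isolation. A run
manifest (JSON) snapshots the configuration, seed, package version, SHA-256
of every stage output, and the warning/event counts; deterministic stages
reproduce byte-identical outputs from the same manifest.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path

import imageio.v3 as iio
import pandas as pd

from . import __version__
from .behavior import behavior_summary
from .config import RunConfig, config_snapshot
from .correction import apply_swaps, detect_warnings, fill_misses, mark_warnings
from .io import (
    FrameStream,
    read_via_annotations,
    write_track_csv,
    write_warnings_csv,
)
from .segmentation import RegionFromMask
from .tracking import track_video
from .synthetic import SceneParams, SyntheticScene

logger = logging.getLogger(__name__)


def sha256_file(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def detector_from_via(via_path, frame_shape: tuple[int, int]):
    """Build a detector that replays precomputed VIA polygon masks.

    Frame order follows the VIA file's image order; polygons are rasterized
    to masks at the given frame shape.
    """
    from skimage.draw import polygon as draw_polygon

    frames = read_via_annotations(via_path)

    def detector(frame, frame_index):
        if frame_index >= len(frames):
            return []
        regions = []
        for poly in frames[frame_index].polygons:
            rr, cc = draw_polygon(poly[:, 1], poly[:, 0], shape=frame_shape)
            if rr.size == 0:
                continue
            import numpy as np

            mask = np.zeros(frame_shape, dtype=bool)
            mask[rr, cc] = True
            regions.append(RegionFromMask.build(frame_index, mask))
        regions.sort(key=lambda r: -r.area_px)
        return regions

    return detector


def write_scene(scene: SyntheticScene, out_dir) -> dict:
    """Write a synthetic scene: PNG frames, truth CSV, event log."""
    out = Path(out_dir)
    frames_dir = out / "frames"
    frames_dir.mkdir(parents=True, exist_ok=True)
    for t in range(scene.params.n_frames):
        iio.imwrite(frames_dir / f"frame_{t:06d}.png", scene.render_frame(t))
    truth = scene.truth()
    write_track_csv(truth.table, truth.calibration, out / "truth.csv")
    (out / "events.json").write_text(json.dumps(truth.events, indent=1))
    return {
        "frames_dir": str(frames_dir),
        "truth_csv": str(out / "truth.csv"),
        "events_json": str(out / "events.json"),
    }


def run_pipeline(
    config: RunConfig,
    out_dir,
    scene_params: SceneParams | None = None,
    swaps=None,
) -> dict:
    """Run synth (optional) -> track -> correct -> analyze; return the manifest.

    Either ``config.frames`` (a frame source on disk) or ``scene_params``
    (a synthetic scene, rendered in memory) must be provided.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stages: dict[str, dict] = {}

    if scene_params is not None:
        scene = SyntheticScene(scene_params)
        stream = scene.frame_stream()
        truth = scene.truth()
        write_track_csv(truth.table, truth.calibration, out / "truth.csv")
        stages["synth"] = {
            "n_frames": scene_params.n_frames,
            "events": len(truth.events),
            "outputs": {"truth.csv": sha256_file(out / "truth.csv")},
        }
    elif config.frames:
        stream = FrameStream.open(config.frames, fps=config.analysis.fps)
        stages["input"] = {"frames": str(config.frames), "n_frames": len(stream)}
    else:
        raise ValueError("config has no frames path and no synthetic scene was given")

    detector = None
    if config.masks_from:
        detector = detector_from_via(config.masks_from, (stream.height, stream.width))

    table, _state = track_video(stream, config, detector=detector)
    write_track_csv(table, config.calibration, out / "tracks.csv")
    stages["track"] = {
        "n_records": len(table),
        "outputs": {"tracks.csv": sha256_file(out / "tracks.csv")},
    }

    filled, gaps = fill_misses(table, config.correction)
    warnings = detect_warnings(filled)
    corrected = mark_warnings(filled, warnings)
    if swaps:
        corrected, failures = apply_swaps(corrected, swaps)
        if failures:
            logger.error("%d swap directives failed", len(failures))
    write_track_csv(corrected, config.calibration, out / "corrected.csv")
    write_warnings_csv(warnings, out / "warnings.csv")
    stages["correct"] = {
        "filled": int(corrected["filled"].sum()),
        "unfilled_gaps": len(gaps),
        "warnings": len(warnings),
        "outputs": {
            "corrected.csv": sha256_file(out / "corrected.csv"),
            "warnings.csv": sha256_file(out / "warnings.csv"),
        },
    }

    stats_dir = out / "stats"
    stats_dir.mkdir(exist_ok=True)
    summary = behavior_summary(corrected, config.analysis, config.calibration)
    outputs = {}
    cum = pd.DataFrame(summary["cumulative_distance_cm"])
    cum.columns = [f"id{i}" for i in cum.columns]
    cum.index.name = "frame"
    cum.to_csv(stats_dir / "cumulative_distance_cm.csv", float_format="%.17g")
    outputs["cumulative_distance_cm.csv"] = sha256_file(
        stats_dir / "cumulative_distance_cm.csv"
    )
    for name in ("pair_distance_cm", "proximity_time_s"):
        if summary[name]:
            df = pd.DataFrame(
                {f"id{a}_id{b}": s for (a, b), s in summary[name].items()}
            )
            df.index.name = "frame"
            df.to_csv(stats_dir / f"{name}.csv", float_format="%.17g")
            outputs[f"{name}.csv"] = sha256_file(stats_dir / f"{name}.csv")
    stages["analyze"] = {"outputs": outputs}

    manifest = {
        "version": __version__,
        "seed": config.seed,
        "config": config_snapshot(config),
        "scene": dataclasses.asdict(scene_params) if scene_params else None,
        "stages": stages,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True, default=str))
    return manifest
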