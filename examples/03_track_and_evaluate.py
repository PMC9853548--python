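"""Track a clean synthetic scene end to end and score it against ground truth.

Runs the full tracking-by-detection loop (threshold detection, correlogram
fingerprinting, greedy ascending matching) over 300 frames of a 3-mouse
scene and evaluates identity preservation and centroid accuracy.
"""

from mousetrack import (
    RunConfig,
    SceneParams,
    SyntheticScene,
    evaluate_tracks,
    track_video,
)

scene = SyntheticScene(SceneParams(n_mice=3, n_frames=300, seed=42))
config = RunConfig(n_mice=3, seed=42)

table, state = track_video(scene.frame_stream(), config)
print(f"tracked {table['frame'].nunique()} frames, {len(table)} records")

report = evaluate_tracks(table, scene.truth())
print(f"miss rate:            {report.miss_pct:.2f} %")
print(f"identity switches:    {report.n_switches}")
print(f"max centroid error:   {report.max_error_cm:.4f} cm")
print(f"errors < 0.5 cm:      {100 * report.frac_below_05:.1f} %")
# On a clean scene the appearance fingerprints keep every identity for the
# whole recording and centroids are pixel-exact (well under 0.1 cm).
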