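import numpy as np
import pytest
from hypothesis import settings

from mousetrack import RunConfig, SceneParams, SyntheticScene, track_video

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("ci")

# twelve single-frame misses spread over a 600-frame, 3-animal scene
MISS_EVENTS = tuple(
    (f, i) for f, i in zip(range(40, 520, 40), [0, 1, 2, 0, 1, 2, 0, 1, 2, 0, 1, 2])
)
SWAP_FRAME = 200


@pytest.fixture(scope="session")
def clean_scene():
    """Default 3-animal, 600-frame scene with no injected errors."""
    return SyntheticScene(SceneParams(n_mice=3, n_frames=600, seed=11))


@pytest.fixture(scope="session")
def clean_tracks(clean_scene):
    cfg = RunConfig(n_mice=3, seed=11)
    table, state = track_video(clean_scene.frame_stream(), cfg)
    return table


@pytest.fixture(scope="session")
def miss_scene():
    """Same conditions with 12 injected single-frame detection misses."""
    return SyntheticScene(
        SceneParams(n_mice=3, n_frames=600, seed=11, miss_events=MISS_EVENTS)
    )


@pytest.fixture(scope="session")
def miss_tracks(miss_scene):
    cfg = RunConfig(n_mice=3, seed=11)
    table, state = track_video(miss_scene.frame_stream(), cfg)
    return table


@pytest.fixture(scope="session")
def swap_scene():
    """Same conditions with one injected appearance exchange (ID switch)."""
    return SyntheticScene(
        SceneParams(n_mice=3, n_frames=600, seed=11, swap_events=((SWAP_FRAME, 0, 1),))
    )


@pytest.fixture(scope="session")
def swap_tracks(swap_scene):
    cfg = RunConfig(n_mice=3, seed=11)
    table, state = track_video(swap_scene.frame_stream(), cfg)
    return table


@pytest.fixture(scope="session")
def small_scene():
    """Cheap 2-animal scene for unit tests that just need real frames."""
    return SyntheticScene(
        SceneParams(n_mice=2, n_frames=40, arena_px=480, arena_cm=24.0, seed=3)
    )


def random_polygon(rng: np.random.Generator, n_vertices: int = 40) -> np.ndarray:
    """Non-self-intersecting random polygon: jittered radial star shape."""
    angles = np.sort(rng.uniform(0, 2 * np.pi, n_vertices))
    radii = rng.uniform(5, 50, n_vertices)
    pts = np.column_stack([radii * np.cos(angles), radii * np.sin(angles)])
    # drop consecutive duplicates
    keep = np.ones(len(pts), dtype=bool)
    keep[1:] = np.any(np.diff(pts, axis=0) != 0, axis=1)
    return pts[keep] + 60.0
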