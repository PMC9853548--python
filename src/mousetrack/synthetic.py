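"""Synthetic arena scenes with exact ground truth.

Emulates the recording setup the pipeline targets: a bright square open-field
arena (32 cm side) filmed from above, with 1-4 dark, individually textured,
roughly mouse-sized elliptical animals (~8 cm body length) moving as a
persistent random walk with reflecting walls. Every aspect of a scene is
determined by its seed, and the generator logs exact per-frame ground truth
(masks, geometric centers, path lengths) plus any injected error events, so
detection, tracking, correction and analytics can all be verified without
real videos.

Two error modes can be injected, mirroring the failure modes observed with
real detectors:

* **misses** — an animal is simply not rendered for a frame (the detector
  then genuinely misses it);
* **appearance swaps** — two animals exchange coat textures permanently from
  a given frame, which makes any appearance-based tracker swap their IDs
  while their true (positional) identities continue — an irreversible ID
  switch by construction.

Textures are seeded multiplicative noise fields fixed in each animal's body
frame and rotated with its heading, so correlogram fingerprints are
informative but not trivially constant.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.optimize import linear_sum_assignment

from .config import Calibration, ConfigError
from .io import FrameStream, make_track_table


@dataclass(frozen=True)
class SceneParams:
    """Parameters of a synthetic scene; every default is the study condition.

    640 px at 32 cm gives 20 px/cm, so the default animals (8 cm x 3 cm)
    are ~160 px long — comparable, relative to the arena, to a mouse in a
    1080p top-view recording.
    """

    arena_px: int = 640
    arena_cm: float = 32.0
    n_mice: int = 3
    n_frames: int = 600
    fps: float = 60.0
    body_length_cm: float = 8.0
    body_width_cm: float = 3.0
    base_intensities: tuple[float, ...] | None = None  # default: spaced in 40..90
    texture_strength: float = 0.25
    background_intensity: float = 230.0
    background_noise_sd: float = 3.0
    max_step_px: float = 6.0
    heading_jitter: float = 0.2
    seed: int = 0
    miss_rate: float = 0.0
    miss_events: tuple[tuple[int, int], ...] | None = None  # (frame, id)
    swap_events: tuple[tuple[int, int, int], ...] = ()  # (frame, id_a, id_b)

    @property
    def px_per_cm(self) -> float:
        return self.arena_px / self.arena_cm

    @property
    def semi_major_px(self) -> float:
        return self.body_length_cm / 2 * self.px_per_cm

    @property
    def semi_minor_px(self) -> float:
        return self.body_width_cm / 2 * self.px_per_cm

    @property
    def calibration(self) -> Calibration:
        return Calibration(arena_cm=self.arena_cm, arena_px=float(self.arena_px))


@dataclass
class GroundTruth:
    """Exact per-frame state of a scene plus the injected-event log.

    ``table`` holds every animal on every frame (virtual: an animal missed
    from the render still has its true mask statistics here); ``path_cm``
    is the cumulative centroid path length ledger per animal.
    """

    table: pd.DataFrame
    path_cm: dict[int, np.ndarray]
    events: list[dict] = field(default_factory=list)
    calibration: Calibration = field(default_factory=Calibration)

    @property
    def n_mice(self) -> int:
        return int(self.table["id"].nunique())

    @property
    def miss_events(self) -> set[tuple[int, int]]:
        return {
            (e["frame"], e["id"]) for e in self.events if e["type"] == "miss"
        }


class SyntheticScene:
    """A fully seeded synthetic arena scene.

    Frames are rendered on demand (``render_frame``) so long scenes never
    hold a full frame stack in memory; animal states are precomputed once.
    """

    def __init__(self, params: SceneParams):
        p = params
        a, b = p.semi_major_px, p.semi_minor_px
        margin = a + 2
        if 2 * margin >= p.arena_px:
            raise ConfigError("animals larger than arena")
        if p.n_mice < 1:
            raise ConfigError("n_mice must be >= 1")
        self.params = p
        self._margin = margin
        self._min_sep = 2 * a + 6  # bounding circles disjoint -> masks disjoint
        self._simulate_motion()
        self._make_textures()
        self._plan_events()
        self._truth_cache: GroundTruth | None = None

    # --------------------------------------------------------------- motion

    def _simulate_motion(self) -> None:
        p = self.params
        n, T = p.n_mice, p.n_frames
        rng = np.random.default_rng(np.random.SeedSequence([p.seed, 1]))
        lo, hi = self._margin, p.arena_px - self._margin
        # start on jittered quadrant centers: guaranteed separated for n <= 4
        q = p.arena_px / 4
        anchors = np.array([[q, q], [3 * q, q], [q, 3 * q], [3 * q, 3 * q]])
        pos = anchors[:n] + rng.uniform(-q / 8, q / 8, size=(n, 2))
        pos = self._separate(np.clip(pos, lo, hi), lo, hi)
        heading = rng.uniform(0, 2 * np.pi, size=n)
        speed = rng.uniform(1.0, p.max_step_px, size=n)
        positions = np.empty((T, n, 2))
        headings = np.empty((T, n))
        for t in range(T):
            positions[t] = pos
            headings[t] = heading
            heading = heading + rng.normal(0, p.heading_jitter, size=n)
            speed = np.clip(speed + rng.normal(0, 0.5, size=n), 0.5, p.max_step_px)
            step = np.column_stack([np.cos(heading), np.sin(heading)]) * speed[:, None]
            pos = pos + step
            # reflecting walls: mirror position and heading component
            bounce_x = (pos[:, 0] < lo) | (pos[:, 0] > hi)
            bounce_y = (pos[:, 1] < lo) | (pos[:, 1] > hi)
            pos[:, 0] = np.where(pos[:, 0] < lo, 2 * lo - pos[:, 0], pos[:, 0])
            pos[:, 0] = np.where(pos[:, 0] > hi, 2 * hi - pos[:, 0], pos[:, 0])
            pos[:, 1] = np.where(pos[:, 1] < lo, 2 * lo - pos[:, 1], pos[:, 1])
            pos[:, 1] = np.where(pos[:, 1] > hi, 2 * hi - pos[:, 1], pos[:, 1])
            heading = np.where(bounce_x, np.pi - heading, heading)
            heading = np.where(bounce_y, -heading, heading)
            pos = self._separate(pos, lo, hi)
        self.positions = positions  # (T, n, 2) of (x, y)
        self.headings = headings

    def _separate(self, pos: np.ndarray, lo: float, hi: float) -> np.ndarray:
        """Push colliding pairs apart symmetrically until all are separated."""
        n = len(pos)
        pos = pos.copy()
        for _ in range(20):
            moved = False
            for i in range(n):
                for j in range(i + 1, n):
                    d = pos[j] - pos[i]
                    dist = np.hypot(*d)
                    if dist < self._min_sep:
                        if dist < 1e-9:
                            d, dist = np.array([1.0, 0.0]), 1.0
                        push = (self._min_sep - dist + 1.0) / 2
                        u = d / dist
                        pos[i] = pos[i] - u * push
                        pos[j] = pos[j] + u * push
                        moved = True
            pos = np.clip(pos, lo, hi)
            if not moved:
                break
        return pos

    # -------------------------------------------------------------- textures

    def _make_textures(self) -> None:
        p = self.params
        a, b = p.semi_major_px, p.semi_minor_px
        H = int(2 * b) + 5
        W = int(2 * a) + 5
        if p.base_intensities is not None:
            if len(p.base_intensities) != p.n_mice:
                raise ConfigError("base_intensities must have one value per animal")
            bases = list(p.base_intensities)
        else:
            bases = list(np.linspace(40.0, 90.0, p.n_mice)) if p.n_mice > 1 else [65.0]
        self.base_intensities = bases
        self.textures = []
        for i in range(p.n_mice):
            rng = np.random.default_rng(np.random.SeedSequence([p.seed, 2, i]))
            field_ = ndimage.gaussian_filter(rng.standard_normal((H, W)), sigma=2.0)
            field_ /= max(field_.std(), 1e-12)
            tex = 1.0 + p.texture_strength * np.clip(field_, -2.0, 2.0) / 2.0
            self.textures.append(tex)

    # ---------------------------------------------------------------- events

    def _plan_events(self) -> None:
        p = self.params
        events: list[dict] = []
        if p.miss_events is not None:
            misses = [(int(f), int(i)) for f, i in p.miss_events]
        elif p.miss_rate > 0:
            rng = np.random.default_rng(np.random.SeedSequence([p.seed, 3]))
            count = int(round(p.miss_rate * p.n_frames * p.n_mice))
            pool = [(f, i) for f in range(1, p.n_frames) for i in range(p.n_mice)]
            sel = rng.choice(len(pool), size=min(count, len(pool)), replace=False)
            misses = [pool[k] for k in sorted(sel)]
        else:
            misses = []
        for f, i in misses:
            if not (0 <= f < p.n_frames) or not (0 <= i < p.n_mice):
                raise ConfigError(f"miss event ({f}, {i}) out of range")
            events.append({"type": "miss", "frame": f, "id": i})
        self._missed = set(misses)
        # appearance permutation over time: swaps exchange textures permanently
        perm = np.tile(np.arange(p.n_mice), (p.n_frames, 1))
        for f, ia, ib in sorted(p.swap_events):
            if not (0 <= f < p.n_frames):
                raise ConfigError(f"swap event frame {f} out of range")
            perm[f:, [ia, ib]] = perm[f:, [ib, ia]]
            events.append({"type": "swap", "frame": int(f), "id_a": int(ia), "id_b": int(ib)})
        self._appearance = perm
        self.events = events

    # -------------------------------------------------------------- rendering

    def _animal_patch(self, frame_index: int, animal_id: int):
        """Rasterize one animal: (rows, cols, intensities) in frame coords."""
        p = self.params
        a, b = p.semi_major_px, p.semi_minor_px
        cx, cy = self.positions[frame_index, animal_id]
        theta = self.headings[frame_index, animal_id]
        r = int(np.ceil(a)) + 2
        x0, x1 = int(np.floor(cx)) - r, int(np.floor(cx)) + r + 1
        y0, y1 = int(np.floor(cy)) - r, int(np.floor(cy)) + r + 1
        x0, y0 = max(x0, 0), max(y0, 0)
        x1, y1 = min(x1, p.arena_px), min(y1, p.arena_px)
        ys, xs = np.mgrid[y0:y1, x0:x1]
        dx, dy = xs - cx, ys - cy
        ct, st = np.cos(theta), np.sin(theta)
        u = ct * dx + st * dy  # along-body coordinate
        v = -st * dx + ct * dy
        inside = (u / a) ** 2 + (v / b) ** 2 <= 1.0
        rows, cols = ys[inside], xs[inside]
        app = self._appearance[frame_index, animal_id]
        tex = self.textures[app]
        th, tw = tex.shape
        ti = np.clip(v[inside] + th / 2, 0, th - 1)
        tj = np.clip(u[inside] + tw / 2, 0, tw - 1)
        vals = ndimage.map_coordinates(tex, [ti, tj], order=1, mode="nearest")
        intens = np.clip(self.base_intensities[app] * vals, 0, 255)
        return rows, cols, intens

    def render_frame(self, frame_index: int) -> np.ndarray:
        """Render one uint8 grayscale frame (deterministic per seed)."""
        p = self.params
        rng = np.random.default_rng(np.random.SeedSequence([p.seed, 4, frame_index]))
        frame = p.background_intensity + rng.normal(
            0, p.background_noise_sd, size=(p.arena_px, p.arena_px)
        )
        for i in range(p.n_mice):
            if (frame_index, i) in self._missed:
                continue
            rows, cols, intens = self._animal_patch(frame_index, i)
            frame[rows, cols] = intens
        return np.clip(np.round(frame), 0, 255).astype(np.uint8)

    def render_masks(self, frame_index: int) -> dict[int, np.ndarray]:
        """Boolean mask per rendered (non-missed) animal for one frame."""
        p = self.params
        out = {}
        for i in range(p.n_mice):
            if (frame_index, i) in self._missed:
                continue
            rows, cols, _ = self._animal_patch(frame_index, i)
            m = np.zeros((p.arena_px, p.arena_px), dtype=bool)
            m[rows, cols] = True
            out[i] = m
        return out

    def frame_stream(self) -> FrameStream:
        return FrameStream(_LazyFrames(self), fps=self.params.fps)

    # ------------------------------------------------------------ ground truth

    def truth(self) -> GroundTruth:
        """Ground-truth table, path ledger and event log (cached).

        Mask statistics are virtual: an animal missed from the render still
        contributes its true centroid and area, since the animal exists — it
        merely escaped detection.
        """
        if self._truth_cache is not None:
            return self._truth_cache
        p = self.params
        rows = []
        cents = np.empty((p.n_frames, p.n_mice, 2))
        for t in range(p.n_frames):
            for i in range(p.n_mice):
                rr, cc, _ = self._animal_patch(t, i)
                cx, cy = float(cc.mean()), float(rr.mean())
                cents[t, i] = (cx, cy)
                rows.append(
                    {"frame": t, "id": i, "cx_px": cx, "cy_px": cy,
                     "area_px": float(rr.size)}
                )
        cal = p.calibration
        path = {}
        for i in range(p.n_mice):
            steps = np.hypot(
                np.diff(cents[:, i, 0]), np.diff(cents[:, i, 1])
            ) / cal.px_per_cm
            path[i] = np.concatenate([[0.0], np.cumsum(steps)])
        self._truth_cache = GroundTruth(
            table=make_track_table(rows), path_cm=path, events=list(self.events),
            calibration=cal,
        )
        return self._truth_cache


class _LazyFrames:
    """Sequence adapter rendering scene frames on demand."""

    def __init__(self, scene: SyntheticScene):
        self._scene = scene

    def __len__(self) -> int:
        return self._scene.params.n_frames

    def __getitem__(self, i: int) -> np.ndarray:
        return self._scene.render_frame(i)


def generate_scene(params: SceneParams) -> tuple[SyntheticScene, GroundTruth]:
    """Build a scene and its ground truth in one call."""
    scene = SyntheticScene(params)
    return scene, scene.truth()


# ------------------------------------------------------------------ evaluation


@dataclass
class EvalReport:
    """Tracking quality versus ground truth under a fixed ID mapping."""

    errors_cm: pd.DataFrame  # frame, id (truth), err_cm, filled
    miss_pct: float
    n_switches: int
    n_warnings: int
    id_mapping: dict[int, int]  # predicted id -> truth id
    max_error_cm: float
    frac_below_05: float
    frac_below_15: float


def evaluate_tracks(
    predicted: pd.DataFrame,
    truth: GroundTruth,
    calibration: Calibration | None = None,
    warnings=None,
) -> EvalReport:
    """Score a predicted track table against ground truth.

    The predicted IDs are mapped to truth animals by the fixed one-to-one
    mapping minimizing total centroid distance over all frames; per-frame
    centroid errors (cm), the miss percentage, and the identity-switch count
    (changes of the per-frame optimal mapping between consecutive frames)
    are reported, together with the fractions of errors below 0.5 cm and
    1.5 cm.
    """
    cal = calibration or truth.calibration
    tt = truth.table
    truth_frames = set(tt["frame"].unique())
    extra = set(predicted["frame"].unique()) - truth_frames
    if extra:
        raise ValueError(f"predicted table has frames outside ground truth: {sorted(extra)[:5]}")
    n = truth.n_mice
    pred_ids = sorted(predicted["id"].unique())
    truth_ids = sorted(tt["id"].unique())
    tx = tt.pivot_table(index="frame", columns="id", values="cx_px")
    ty = tt.pivot_table(index="frame", columns="id", values="cy_px")
    px = predicted.pivot_table(index="frame", columns="id", values="cx_px")
    py = predicted.pivot_table(index="frame", columns="id", values="cy_px")
    px, py = px.reindex(tx.index), py.reindex(tx.index)
    # fixed mapping: minimize total distance over all frames
    cost = np.zeros((len(pred_ids), len(truth_ids)))
    for ai, a in enumerate(pred_ids):
        dx = px[a].to_numpy()[:, None] - tx[truth_ids].to_numpy()
        dy = py[a].to_numpy()[:, None] - ty[truth_ids].to_numpy()
        d = np.hypot(dx, dy)
        cost[ai] = np.nansum(d, axis=0)
    ri, ci = linear_sum_assignment(cost)
    mapping = {pred_ids[i]: truth_ids[j] for i, j in zip(ri, ci)}
    # per-frame errors under the fixed mapping
    filled_flag = predicted.set_index(["frame", "id"])["filled"]
    err_rows = []
    for a, g in mapping.items():
        d_px = np.hypot(px[a] - tx[g], py[a] - ty[g])
        for f, v in d_px.dropna().items():
            err_rows.append(
                {"frame": int(f), "id": int(g), "err_cm": cal.to_cm(float(v)),
                 "filled": int(filled_flag.get((f, a), 0))}
            )
    errors = pd.DataFrame(err_rows, columns=["frame", "id", "err_cm", "filled"])
    total_slots = len(truth_frames) * n
    miss_pct = 100.0 * (total_slots - len(errors)) / total_slots
    # switch count: per-frame optimal mapping transitions
    n_switches = 0
    prev_map: dict[int, int] | None = None
    P = np.stack([px[a].to_numpy() for a in pred_ids], axis=1)
    Py_ = np.stack([py[a].to_numpy() for a in pred_ids], axis=1)
    Tx = tx[truth_ids].to_numpy()
    Ty = ty[truth_ids].to_numpy()
    for t in range(len(tx.index)):
        present = [k for k in range(len(pred_ids)) if not np.isnan(P[t, k])]
        if not present:
            continue
        d = np.hypot(
            P[t, present][:, None] - Tx[t][None, :],
            Py_[t, present][:, None] - Ty[t][None, :],
        )
        ri2, ci2 = linear_sum_assignment(d)
        cur = {pred_ids[present[i]]: truth_ids[j] for i, j in zip(ri2, ci2)}
        if prev_map is not None:
            common = set(cur) & set(prev_map)
            if any(cur[k] != prev_map[k] for k in common):
                n_switches += 1
        prev_map = cur
    errs = errors["err_cm"].to_numpy()
    return EvalReport(
        errors_cm=errors,
        miss_pct=miss_pct,
        n_switches=n_switches,
        n_warnings=0 if warnings is None else len(warnings),
        id_mapping=mapping,
        max_error_cm=float(errs.max()) if errs.size else float("nan"),
        frac_below_05=float((errs < 0.5).mean()) if errs.size else float("nan"),
        frac_below_15=float((errs < 1.5).mean()) if errs.size else float("nan"),
    )
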