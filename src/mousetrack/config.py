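"""Run configuration, calibration, and the flat key=value config format.

All tunable constants of the pipeline live here as dataclass defaults:
contour post-processing (``expand_px=5``, ``rdp_epsilon=1.5``), fingerprint
buffering (``dilation_iters=10``, 3x3 kernel, 7x7 Gaussian blur, quarter-scale
resize), the social-proximity threshold (6 cm), and the recording geometry
(60 Hz, 32 cm square arena).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path


class ConfigError(ValueError):
    """Raised for invalid or missing configuration values."""


@dataclass(frozen=True)
class Calibration:
    """Isotropic pixel/centimetre conversion from the arena side length.

    The camera is assumed overhead and distortion-free, so a single scale
    factor ``px_per_cm = arena_px / arena_cm`` applies to both axes.
    """

    arena_cm: float = 32.0
    arena_px: float = 640.0

    def __post_init__(self) -> None:
        if self.arena_cm <= 0 or self.arena_px <= 0:
            raise ConfigError("arena_cm and arena_px must be positive")

    @property
    def px_per_cm(self) -> float:
        return self.arena_px / self.arena_cm

    def to_cm(self, px):
        return px / self.px_per_cm

    def to_px(self, cm):
        return cm * self.px_per_cm


@dataclass(frozen=True)
class SegmentationParams:
    """Classical threshold/blob detector settings.

    ``threshold`` is either a fixed grayscale level or ``"otsu"``; animals are
    darker than the background, so foreground is ``pixel < level``.
    """

    threshold: float | str = "otsu"
    min_area_px: int = 400
    max_area_px: int = 1_000_000
    expand_px: int = 5
    rdp_epsilon: float = 1.5

    def __post_init__(self) -> None:
        if not (0 <= self.min_area_px < self.max_area_px):
            raise ConfigError("need 0 <= min_area_px < max_area_px")
        if self.expand_px < 0:
            raise ConfigError("expand_px must be >= 0")
        if self.rdp_epsilon < 0:
            raise ConfigError("rdp_epsilon must be >= 0")
        if isinstance(self.threshold, str) and self.threshold != "otsu":
            raise ConfigError(f"unknown threshold mode {self.threshold!r}")


def _check_kernel(k: int, name: str) -> None:
    if k < 1 or k % 2 == 0:
        raise ConfigError(f"{name} must be odd and >= 1, got {k}")


@dataclass(frozen=True)
class FingerprintParams:
    """Correlogram fingerprint settings.

    The detected mask is buffered (dilated ``dilation_iters`` times with a
    square ``dilation_kernel`` then blurred with a ``blur_kernel`` Gaussian and
    thresholded above zero), the frame is cropped along the buffered mask,
    downscaled by ``downscale``, and every unordered pixel pair contributes a
    (distance, intensity-sum) count to a 2-D histogram.
    """

    dilation_iters: int = 10
    dilation_kernel: int = 3
    blur_kernel: int = 7
    downscale: int = 4
    n_dist_bins: int = 32
    n_sum_bins: int = 32
    max_dist_px: float = 64.0
    max_pairs: int | None = None
    pair_seed: int = 0

    def __post_init__(self) -> None:
        _check_kernel(self.dilation_kernel, "dilation_kernel")
        _check_kernel(self.blur_kernel, "blur_kernel")
        if self.downscale < 1:
            raise ConfigError("downscale must be >= 1")
        if self.n_dist_bins < 2 or self.n_sum_bins < 2:
            raise ConfigError("bin counts must be >= 2")
        if self.max_dist_px <= 0:
            raise ConfigError("max_dist_px must be positive")


@dataclass(frozen=True)
class CorrectionParams:
    #: longest gap (frames) still considered a sporadic miss and carried forward
    max_gap: int = 60

    def __post_init__(self) -> None:
        if self.max_gap < 1:
            raise ConfigError("max_gap must be >= 1")


@dataclass(frozen=True)
class AnalysisParams:
    proximity_cm: float = 6.0
    fps: float = 60.0

    def __post_init__(self) -> None:
        if self.proximity_cm <= 0:
            raise ConfigError("proximity_cm must be positive")
        if self.fps <= 0:
            raise ConfigError("fps must be positive")


@dataclass(frozen=True)
class RunConfig:
    """Complete configuration for a tracking run."""

    n_mice: int
    calibration: Calibration = field(default_factory=Calibration)
    segmentation: SegmentationParams = field(default_factory=SegmentationParams)
    fingerprint: FingerprintParams = field(default_factory=FingerprintParams)
    correction: CorrectionParams = field(default_factory=CorrectionParams)
    analysis: AnalysisParams = field(default_factory=AnalysisParams)
    seed: int = 0
    frames: str | None = None
    masks_from: str | None = None
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.n_mice < 1:
            raise ConfigError(f"n_mice must be >= 1, got {self.n_mice}")


# flat config keys -> (sub-config name, field name, parser)
def _num(s: str) -> float | int:
    try:
        return int(s)
    except ValueError:
        return float(s)


def _threshold(s: str):
    return s if s == "otsu" else _num(s)


_KEYMAP = {
    "arena_cm": ("calibration", "arena_cm", float),
    "arena_px": ("calibration", "arena_px", float),
    "threshold": ("segmentation", "threshold", _threshold),
    "min_area_px": ("segmentation", "min_area_px", int),
    "max_area_px": ("segmentation", "max_area_px", int),
    "expand_px": ("segmentation", "expand_px", int),
    "rdp_epsilon": ("segmentation", "rdp_epsilon", float),
    "dilation_iters": ("fingerprint", "dilation_iters", int),
    "dilation_kernel": ("fingerprint", "dilation_kernel", int),
    "blur_kernel": ("fingerprint", "blur_kernel", int),
    "downscale": ("fingerprint", "downscale", int),
    "n_dist_bins": ("fingerprint", "n_dist_bins", int),
    "n_sum_bins": ("fingerprint", "n_sum_bins", int),
    "max_dist_px": ("fingerprint", "max_dist_px", float),
    "max_pairs": ("fingerprint", "max_pairs", int),
    "max_gap": ("correction", "max_gap", int),
    "proximity_cm": ("analysis", "proximity_cm", float),
    "fps": ("analysis", "fps", float),
}

_TOP = {
    "n_mice": int,
    "seed": int,
    "frames": str,
    "masks_from": str,
}


def parse_config_text(text: str, **overrides) -> RunConfig:
    """Parse flat ``key = value`` text (``#`` comments, blank lines allowed)."""
    sub: dict[str, dict] = {}
    top: dict = {}
    extra: dict = {}
    for lineno, raw in enumerate(text.splitlines(), 1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ConfigError(f"line {lineno}: expected key=value, got {raw!r}")
        key, _, value = line.partition("=")
        key, value = key.strip(), value.strip()
        if key in _KEYMAP:
            block, fname, conv = _KEYMAP[key]
            try:
                sub.setdefault(block, {})[fname] = conv(value)
            except ValueError as exc:
                raise ConfigError(f"line {lineno}: bad value for {key}: {value!r}") from exc
        elif key in _TOP:
            try:
                top[key] = _TOP[key](value)
            except ValueError as exc:
                raise ConfigError(f"line {lineno}: bad value for {key}: {value!r}") from exc
        else:
            extra[key] = value
    top.update(overrides)
    if "n_mice" not in top:
        raise ConfigError("n_mice is required")
    # fps belongs to analysis; mirror it there if given flat
    blocks = {
        "calibration": Calibration(**sub.get("calibration", {})),
        "segmentation": SegmentationParams(**sub.get("segmentation", {})),
        "fingerprint": FingerprintParams(**sub.get("fingerprint", {})),
        "correction": CorrectionParams(**sub.get("correction", {})),
        "analysis": AnalysisParams(**sub.get("analysis", {})),
    }
    return RunConfig(extra=extra, **top, **blocks)


def load_config(path, **overrides) -> RunConfig:
    """Load a :class:`RunConfig` from a flat key=value text file.

    Missing keys take the documented defaults. ``overrides`` win over file
    values (used by CLI flags such as ``--seed``).
    """
    return parse_config_text(Path(path).read_text(), **overrides)


def config_snapshot(cfg: RunConfig) -> dict:
    """JSON-serializable snapshot of a RunConfig (for manifests)."""
    return dataclasses.asdict(cfg)
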