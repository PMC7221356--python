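"""Shared domain types, configuration, coordinate conventions, and calibration.

Coordinate convention (fixed package-wide): the origin is the centre of the
top-left pixel, ``x`` increases rightward (columns), ``y`` increases downward
(rows), indices are 0-based.  Images are 2-D ``uint8``-valued arrays indexed
``pixels[y, x]``.

The pipeline's native speed unit is pixels per frame; conversion to
centimetres per second is an explicit, separate calibration step performed
off-line with a :class:`Calibration`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum
from pathlib import Path
from typing import Union

import numpy as np

__all__ = [
    "Polarity",
    "Point2D",
    "Frame",
    "PipelineConfig",
    "Calibration",
    "CalibrationError",
    "ConfigError",
    "StreamError",
    "GRAYSCALE_WEIGHTS",
    "calibrate_point",
    "calibrate_speed",
    "to_grayscale",
    "load_config",
]

#: RGB -> luminance weights (ITU-R BT.601) used when colour input must be
#: collapsed to the pipeline's 8-bit grayscale intensity model.
GRAYSCALE_WEIGHTS = (0.299, 0.587, 0.114)


class ConfigError(ValueError):
    """Invalid pipeline or simulator configuration."""


class CalibrationError(ValueError):
    """Invalid real-world calibration (non-positive scale or rate)."""


class StreamError(RuntimeError):
    """Inconsistent frame stream (shape change, non-monotone index/time)."""


class Polarity(str, Enum):
    """Photometric polarity of the subject relative to the arena floor."""

    DARK_SUBJECT = "dark_subject"   # black mouse on white floor
    LIGHT_SUBJECT = "light_subject"  # white mouse on black floor


@dataclass(frozen=True)
class Point2D:
    """A point in image coordinates (x rightward, y downward), in pixels
    unless a calibration has been applied."""

    x: float
    y: float

    def __post_init__(self) -> None:
        if not (math.isfinite(self.x) and math.isfinite(self.y)):
            raise ValueError("Point2D coordinates must be finite")

    def distance_to(self, other: "Point2D") -> float:
        return math.hypot(self.x - other.x, self.y - other.y)


@dataclass(frozen=True)
class Frame:
    """One grayscale image with a frame counter and a session-relative
    timestamp in seconds."""

    pixels: np.ndarray
    index: int
    timestamp: float

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 2 or px.shape[0] < 1 or px.shape[1] < 1:
            raise ValueError("Frame.pixels must be a non-empty 2-D array")
        if px.size and (px.min() < 0 or px.max() > 255):
            raise ValueError("Frame intensities must lie in [0, 255]")
        if self.index < 0:
            raise ValueError("Frame.index must be nonnegative")
        object.__setattr__(self, "pixels", px)

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]


@dataclass(frozen=True)
class PipelineConfig:
    """Tracking-pipeline parameters.

    ``min_blob_area``/``max_blob_area`` default to fractions of the image
    area (0.1% and 25%) resolved at session start, so the size filter
    transfers across resolutions; explicit pixel values override this.
    """

    polarity: Polarity = Polarity.DARK_SUBJECT
    threshold_update_interval: int = 50
    min_blob_area: float | None = None
    max_blob_area: float | None = None
    frame_rate: float = 15.0
    connectivity: int = 8
    min_area_fraction: float = 0.001
    max_area_fraction: float = 0.25

    def __post_init__(self) -> None:
        if isinstance(self.polarity, str) and not isinstance(self.polarity, Polarity):
            object.__setattr__(self, "polarity", Polarity(self.polarity))
        if self.threshold_update_interval < 1:
            raise ConfigError("threshold_update_interval must be >= 1")
        if self.frame_rate <= 0:
            raise ConfigError("frame_rate must be positive")
        if self.connectivity not in (4, 8):
            raise ConfigError("connectivity must be 4 or 8")
        if self.min_blob_area is not None and self.max_blob_area is not None:
            if not (0 < self.min_blob_area <= self.max_blob_area):
                raise ConfigError("need 0 < min_blob_area <= max_blob_area")

    def resolve_areas(self, shape: tuple[int, int]) -> tuple[float, float]:
        """Concrete (min_area, max_area) in pixels for an image shape."""
        npx = shape[0] * shape[1]
        lo = self.min_blob_area if self.min_blob_area is not None else self.min_area_fraction * npx
        hi = self.max_blob_area if self.max_blob_area is not None else self.max_area_fraction * npx
        if not (0 < lo <= hi):
            raise ConfigError("resolved blob-area bounds are invalid")
        return float(lo), float(hi)


@dataclass(frozen=True)
class Calibration:
    """Off-line calibration from pixel units to real-world units.

    ``pixels_per_cm`` converts lengths; ``frame_rate`` (Hz) converts the
    pipeline's native pixels-per-frame speeds to per-second rates.
    """

    pixels_per_cm: float
    frame_rate: float = 15.0

    def __post_init__(self) -> None:
        if self.pixels_per_cm <= 0 or self.frame_rate <= 0:
            raise CalibrationError("pixels_per_cm and frame_rate must be positive")


def calibrate_point(p: Point2D, cal: Calibration) -> Point2D:
    """Convert a pixel-coordinate point to centimetres."""
    return Point2D(p.x / cal.pixels_per_cm, p.y / cal.pixels_per_cm)


def calibrate_speed(v: float, cal: Calibration) -> float:
    """Convert a pixels-per-frame speed to centimetres per second.

    Raises
    ------
    ValueError
        If ``v`` is negative (speeds are magnitudes).
    """
    if v < 0:
        raise ValueError("speed must be nonnegative")
    return v * cal.frame_rate / cal.pixels_per_cm


def to_grayscale(image: np.ndarray) -> np.ndarray:
    """Collapse an (H, W, 3) or (H, W, 4) colour image to 8-bit grayscale
    with the package's fixed luma weights; pass 2-D input through."""
    arr = np.asarray(image)
    if arr.ndim == 2:
        return arr
    if arr.ndim == 3 and arr.shape[2] in (3, 4):
        w = np.asarray(GRAYSCALE_WEIGHTS)
        gray = arr[..., :3].astype(np.float64) @ w
        return np.clip(np.rint(gray), 0, 255).astype(np.uint8)
    raise ValueError(f"cannot convert array of shape {arr.shape} to grayscale")


_CONFIG_CASTS = {
    "polarity": Polarity,
    "threshold_update_interval": int,
    "min_blob_area": float,
    "max_blob_area": float,
    "frame_rate": float,
    "connectivity": int,
    "min_area_fraction": float,
    "max_area_fraction": float,
}


def load_config(path: Union[str, Path]) -> PipelineConfig:
    """Load a :class:`PipelineConfig` from a flat ``key = value`` text file.

    Keys are exactly the config field names; unknown keys are rejected.
    Blank lines and ``#`` comments are ignored.
    """
    kwargs: dict = {}
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ConfigError(f"{path}:{lineno}: expected 'key = value', got {raw!r}")
        key, _, value = line.partition("=")
        key, value = key.strip(), value.strip()
        if key not in _CONFIG_CASTS:
            raise ConfigError(f"{path}:{lineno}: unknown config key {key!r}")
        kwargs[key] = _CONFIG_CASTS[key](value)
    return PipelineConfig(**kwargs)
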