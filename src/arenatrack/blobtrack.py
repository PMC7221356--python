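"""Connected-component blob extraction, size filtering, subject selection,
and per-frame centroid/speed tracking.

A frame's binary mask is partitioned into maximal connected foreground
regions (8-connectivity by default — a mouse silhouette with a thin tail
fragments under 4-connectivity).  Regions are filtered by an inclusive
[min_area, max_area] window, which rejects both pixel noise and large bright
artefacts such as infrared glare reflections, and the largest surviving blob
is taken as the subject.  Speed is the inter-frame centroid displacement in
pixels per frame; after a detection gap of g frames, the speed on
reacquisition is distance / g (gap-normalised), keeping the unit consistent
and avoiding spurious spikes.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional

import numpy as np
from scipy import ndimage

from .core import Frame, PipelineConfig, Point2D, StreamError
from .logio import SessionLog
from .segmentation import ThresholdState, apply_threshold, maybe_update

__all__ = [
    "Blob",
    "TrackPoint",
    "label_components",
    "filter_blobs",
    "select_subject",
    "step_track",
    "track_session",
]

_STRUCTURES = {
    4: np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]], bool),
    8: np.ones((3, 3), bool),
}


@dataclass(frozen=True)
class Blob:
    """A connected foreground region: pixel count, unweighted centroid of
    member pixel coordinates, and inclusive bounding box."""

    area: int
    centroid: Point2D
    bbox: tuple[int, int, int, int]  # (min_x, min_y, max_x, max_y), inclusive

    def __post_init__(self) -> None:
        if self.area < 1:
            raise ValueError("blob area must be >= 1")
        min_x, min_y, max_x, max_y = self.bbox
        if not (min_x <= self.centroid.x <= max_x and min_y <= self.centroid.y <= max_y):
            raise ValueError("centroid must lie within bbox")


@dataclass(frozen=True)
class TrackPoint:
    """Per-frame tracking record.  ``valid`` iff a subject was detected;
    ``speed`` (px/frame) is present only when a previous valid point exists."""

    frame_index: int
    timestamp: float
    position: Optional[Point2D] = None
    speed: Optional[float] = None
    valid: bool = False

    def __post_init__(self) -> None:
        if self.valid != (self.position is not None):
            raise ValueError("valid must be True exactly when position is present")
        if self.speed is not None and not self.valid:
            raise ValueError("speed requires a valid position")


def label_components(mask: np.ndarray, connectivity: int = 8) -> list[Blob]:
    """Partition a binary mask into maximal connected blobs.

    Returns blobs ordered by decreasing area, ties broken by the bounding
    box's (min_y, min_x).  An empty mask yields an empty list.
    """
    if connectivity not in _STRUCTURES:
        raise ValueError("connectivity must be 4 or 8")
    mask = np.asarray(mask).astype(bool)
    labels, n = ndimage.label(mask, structure=_STRUCTURES[connectivity])
    if n == 0:
        return []
    areas = np.bincount(labels.ravel())[1:]
    ys, xs = np.nonzero(labels)
    lab = labels[ys, xs]
    cx = np.bincount(lab, weights=xs)[1:] / areas
    cy = np.bincount(lab, weights=ys)[1:] / areas
    slices = ndimage.find_objects(labels)
    blobs = []
    for i in range(n):
        sy, sx = slices[i]
        blobs.append(
            Blob(
                area=int(areas[i]),
                centroid=Point2D(float(cx[i]), float(cy[i])),
                bbox=(sx.start, sy.start, sx.stop - 1, sy.stop - 1),
            )
        )
    blobs.sort(key=lambda b: (-b.area, b.bbox[1], b.bbox[0]))
    return blobs


def filter_blobs(blobs: list[Blob], min_area: float, max_area: float) -> list[Blob]:
    """Keep blobs with min_area <= area <= max_area (inclusive), preserving order."""
    if min_area > max_area:
        raise ValueError("min_area must not exceed max_area")
    return [b for b in blobs if min_area <= b.area <= max_area]


def select_subject(valid_blobs: list[Blob]) -> Optional[Blob]:
    """The largest-area blob, or None for an empty list.  Ties go to the
    topmost-then-leftmost bounding box."""
    if not valid_blobs:
        return None
    return min(valid_blobs, key=lambda b: (-b.area, b.bbox[1], b.bbox[0]))


def step_track(
    prev: Optional[TrackPoint],
    subject: Optional[Blob],
    frame_index: int,
    timestamp: float,
) -> TrackPoint:
    """Build the track point for one frame.

    ``prev`` is the most recent *valid* track point (None before first
    detection).  Speed on a valid frame is the centroid distance to ``prev``
    divided by the frame gap; absent when there is no prior valid point.
    """
    if prev is not None and frame_index <= prev.frame_index:
        raise StreamError(
            f"non-monotone frame index: {frame_index} after {prev.frame_index}"
        )
    if subject is None:
        return TrackPoint(frame_index, timestamp, valid=False)
    pos = subject.centroid
    speed = None
    if prev is not None and prev.valid:
        gap = frame_index - prev.frame_index
        speed = pos.distance_to(prev.position) / gap
    return TrackPoint(frame_index, timestamp, position=pos, speed=speed, valid=True)


def track_session(
    frames: Iterable[Frame],
    config: PipelineConfig,
    session_id: str = "session",
    start_datetime=None,
) -> SessionLog:
    """Run the full tracking pipeline over an ordered frame stream.

    Per frame: (periodic) threshold update -> binary mask -> connected
    components -> size filter -> largest-blob selection -> track step.
    Returns a :class:`~arenatrack.logio.SessionLog` with one
    :class:`TrackPoint` per input frame.  Deterministic for a fixed stream
    and config.
    """
    points: list[TrackPoint] = []
    state: Optional[ThresholdState] = None
    last_valid: Optional[TrackPoint] = None
    shape: Optional[tuple[int, int]] = None
    min_area = max_area = None
    last_index = None
    for frame in frames:
        if shape is None:
            shape = frame.shape
            min_area, max_area = config.resolve_areas(shape)
        elif frame.shape != shape:
            raise StreamError(f"frame shape changed from {shape} to {frame.shape}")
        if last_index is not None and frame.index <= last_index:
            raise StreamError(f"non-monotone frame index {frame.index}")
        last_index = frame.index
        state = maybe_update(
            state, frame, config.threshold_update_interval, config.polarity
        )
        mask = apply_threshold(frame, state)
        blobs = filter_blobs(label_components(mask, config.connectivity), min_area, max_area)
        subject = select_subject(blobs)
        point = step_track(last_valid, subject, frame.index, frame.timestamp)
        if point.valid:
            last_valid = point
        points.append(point)
    if shape is None:
        raise ValueError("empty frame stream")
    return SessionLog(
        session_id=session_id,
        start_datetime=start_datetime,
        points=points,
        events=[],
        config_snapshot=config,
        frame_shape=shape,
    )
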