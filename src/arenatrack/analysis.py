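"""Downstream analyses of session logs.

Three analyses mirror the tracker's canonical use cases:

* :func:`activity_profile` — distance travelled per time bin over a long
  recording, the raw material of a circadian actogram (default bin 10 min);
* :func:`perievent_speed` — event-aligned raster and mean trace of subject
  speed around logged device events such as pellet retrievals (default
  window −10 s..+10 s in 0.5 s bins);
* :func:`side_preference` — time spent on each side of the arena per
  session segment, the readout of a real-time place-preference assay;

plus :func:`track_plot_data`, a pure data transform feeding xy track plots
with optional event overlays.

All binning uses half-open intervals [left, right), so bins partition time.
Speeds are used as logged (pixels/frame) unless a :class:`~arenatrack.core.
Calibration` is supplied, in which case distances are reported in cm and
speeds in cm/s; mixing calibrated and uncalibrated quantities is refused.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .core import Calibration, Point2D
from .closed_loop import EventKind, Zone, in_zone
from .logio import SessionLog

__all__ = [
    "ActivityProfile",
    "PerieventResult",
    "PreferenceResult",
    "activity_profile",
    "perievent_speed",
    "side_preference",
    "track_plot_data",
]


@dataclass
class ActivityProfile:
    """Distance travelled per time bin (px, or cm when calibrated) and the
    fraction of valid frames per bin."""

    bin_edges: np.ndarray          # seconds, len = n_bins + 1
    distance_per_bin: np.ndarray   # len = n_bins
    valid_fraction_per_bin: np.ndarray
    unit: str = "px"

    @property
    def bin_centers(self) -> np.ndarray:
        return (self.bin_edges[:-1] + self.bin_edges[1:]) / 2

    @property
    def total_distance(self) -> float:
        return float(self.distance_per_bin.sum())


@dataclass
class PerieventResult:
    """Event-aligned speed: one raster row per usable event, with the
    column-wise mean over non-missing entries."""

    raster: np.ndarray        # (n_events, n_bins), NaN where no frames fell
    mean_trace: np.ndarray    # (n_bins,)
    bin_centers: np.ndarray   # seconds relative to the event (negative = before)
    event_times: np.ndarray   # usable events only
    unit: str = "px/frame"


@dataclass
class PreferenceResult:
    """Per-segment occupancy of a zone: seconds in/out of the zone over the
    segment's valid frames, and the in-zone fraction (None when the segment
    has no valid frames)."""

    segments: list[tuple[float, float]]
    seconds_in: list[float]
    seconds_out: list[float]
    fraction_in: list[Optional[float]]


def activity_profile(
    log: SessionLog,
    bin_width: float = 600.0,
    cal: Optional[Calibration] = None,
) -> ActivityProfile:
    """Distance travelled per time bin.

    Each displacement between consecutive-frame valid point pairs is
    credited to the bin containing the later frame's timestamp; detection
    gaps contribute nothing.  Binning conserves total distance.
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    if not log.points:
        raise ValueError("empty session log")
    t_end = log.points[-1].timestamp
    n_bins = max(1, int(np.ceil((t_end + 1e-12) / bin_width)))
    edges = np.arange(n_bins + 1) * bin_width
    dist = np.zeros(n_bins)
    valid_counts = np.zeros(n_bins)
    frame_counts = np.zeros(n_bins)
    scale = 1.0 / cal.pixels_per_cm if cal is not None else 1.0
    for prev, cur in zip(log.points, log.points[1:]):
        if cur.valid and prev.valid and cur.frame_index == prev.frame_index + 1:
            b = min(int(cur.timestamp / bin_width), n_bins - 1)
            dist[b] += cur.position.distance_to(prev.position) * scale
    for p in log.points:
        b = min(int(p.timestamp / bin_width), n_bins - 1)
        frame_counts[b] += 1
        valid_counts[b] += p.valid
    with np.errstate(invalid="ignore", divide="ignore"):
        vf = np.where(frame_counts > 0, valid_counts / np.maximum(frame_counts, 1), 0.0)
    return ActivityProfile(
        bin_edges=edges,
        distance_per_bin=dist,
        valid_fraction_per_bin=vf,
        unit="cm" if cal is not None else "px",
    )


def perievent_speed(
    log: SessionLog,
    events: Optional[Sequence[float]] = None,
    window: tuple[float, float] = (10.0, 10.0),
    bin_width: float = 0.5,
    cal: Optional[Calibration] = None,
) -> PerieventResult:
    """Event-aligned speed raster and mean trace.

    For each event time t, frame speeds within [t − pre, t + post) are
    averaged within bins aligned to the event.  Events whose window extends
    past the session are dropped with a warning; with no usable events the
    result is empty (zero raster rows), not an exception.

    ``events`` defaults to the log's input_ttl event timestamps.
    """
    pre, post = window
    if pre <= 0 or post <= 0 or bin_width <= 0:
        raise ValueError("window and bin width must be positive")
    if events is None:
        events = [e.timestamp for e in log.events if e.kind is EventKind.INPUT_TTL]
    events = list(events)
    edges = np.arange(-pre, post + bin_width / 2, bin_width)
    n_bins = len(edges) - 1
    centers = (edges[:-1] + edges[1:]) / 2

    t0 = log.points[0].timestamp if log.points else 0.0
    t_end = log.points[-1].timestamp if log.points else 0.0
    usable = [t for t in events if t - pre >= t0 and t + post <= t_end]
    dropped = len(events) - len(usable)
    if dropped:
        warnings.warn(f"dropped {dropped} event(s) whose window exceeds the session")
    if not usable:
        warnings.warn("no usable events for perievent analysis")
        return PerieventResult(
            raster=np.empty((0, n_bins)),
            mean_trace=np.full(n_bins, np.nan),
            bin_centers=centers,
            event_times=np.array([]),
            unit="cm/s" if cal is not None else "px/frame",
        )

    times = np.array([p.timestamp for p in log.points])
    speeds = np.array(
        [p.speed if (p.valid and p.speed is not None) else np.nan for p in log.points]
    )
    if cal is not None:
        speeds = speeds * cal.frame_rate / cal.pixels_per_cm
    raster = np.full((len(usable), n_bins), np.nan)
    for i, t in enumerate(usable):
        rel = times - t
        sel = (rel >= -pre) & (rel < post)
        idx = np.floor((rel[sel] + pre) / bin_width).astype(int)
        idx = np.clip(idx, 0, n_bins - 1)
        vals = speeds[sel]
        for b in range(n_bins):
            cell = vals[idx == b]
            cell = cell[~np.isnan(cell)]
            if cell.size:
                raster[i, b] = cell.mean()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN columns
        mean_trace = np.nanmean(raster, axis=0)
    return PerieventResult(
        raster=raster,
        mean_trace=mean_trace,
        bin_centers=centers,
        event_times=np.array(usable),
        unit="cm/s" if cal is not None else "px/frame",
    )


def side_preference(
    log: SessionLog,
    zone: Zone,
    segments: Optional[Sequence[tuple[float, float]]] = None,
) -> PreferenceResult:
    """Time on each side of the arena per session segment.

    Valid frames with position inside/outside ``zone`` are counted per
    segment (half-open [start, end)) and converted to seconds via the
    logged frame rate.  A segment with zero valid frames reports an absent
    fraction rather than NaN arithmetic.
    """
    if log.frame_shape is None:
        raise ValueError("session log lacks frame dimensions; cannot test zone membership")
    height, width = log.frame_shape
    if segments is None:
        segments = [(0.0, log.duration + 1e-9)]
    segs = sorted(segments)
    for (a0, a1), (b0, b1) in zip(segs, segs[1:]):
        if b0 < a1:
            raise ValueError("segments must be nonoverlapping")
    frame_rate = log.config_snapshot.frame_rate
    sec_in, sec_out, frac = [], [], []
    for start, end in segments:
        if start >= end:
            raise ValueError("segment start must precede end")
        n_in = n_out = 0
        for p in log.points:
            if not (start <= p.timestamp < end) or not p.valid:
                continue
            if in_zone(p.position, zone, width, height):
                n_in += 1
            else:
                n_out += 1
        sec_in.append(n_in / frame_rate)
        sec_out.append(n_out / frame_rate)
        total = n_in + n_out
        frac.append(n_in / total if total else None)
    return PreferenceResult(
        segments=list(segments), seconds_in=sec_in, seconds_out=sec_out, fraction_in=frac
    )


def track_plot_data(
    log: SessionLog, overlay_events: bool = False
) -> tuple[np.ndarray, dict[str, np.ndarray]]:
    """The valid (x, y) sequence of a track plus, when requested, event
    positions grouped by event kind — ready for a scatter track plot."""
    xy = np.array(
        [(p.position.x, p.position.y) for p in log.points if p.valid]
    ).reshape(-1, 2)
    overlays: dict[str, np.ndarray] = {}
    if overlay_events:
        for kind in EventKind:
            pts = [
                (e.position.x, e.position.y)
                for e in log.events
                if e.kind is kind and e.position is not None
            ]
            if pts:
                overlays[kind.value] = np.array(pts)
    return xy, overlays
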