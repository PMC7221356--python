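"""Zone-based real-time control and external-event logging.

Implements the closed-loop behaviours of the tracker: while the subject
occupies the active zone, a fixed-rate pulse train (15 Hz by default, the
rate used to trigger optogenetic stimulation in real-time place-preference
assays) is emitted as timestamped event records; the active half-zone can be
reversed mid-session; and externally supplied TTL-style input events (e.g.
pellet retrievals from a feeding device) are logged together with the
subject's concurrent position.

Pulse scheduling is anchored to dwell-episode onset: the first pulse fires
immediately on zone entry and subsequent pulses at intervals of
``1 / pulse_rate`` seconds, which bounds the count of any dwell episode of
duration d by ``|pulses - floor(d * rate)| <= 1``.  When tracking drops, the
controller holds the last in/out state for up to ``hold_frames`` consecutive
invalid frames, then stops pulsing.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from enum import Enum
from typing import Optional

from .core import Point2D, StreamError
from .blobtrack import TrackPoint

__all__ = [
    "ZoneKind",
    "Zone",
    "EventKind",
    "EventRecord",
    "ControllerState",
    "in_zone",
    "controller_step",
    "reverse_zone",
    "log_input_event",
    "run_controller",
]


class ZoneKind(str, Enum):
    LEFT_HALF = "left_half"
    RIGHT_HALF = "right_half"
    TOP_HALF = "top_half"
    BOTTOM_HALF = "bottom_half"
    RECT = "rect"


_COMPLEMENT = {
    ZoneKind.LEFT_HALF: ZoneKind.RIGHT_HALF,
    ZoneKind.RIGHT_HALF: ZoneKind.LEFT_HALF,
    ZoneKind.TOP_HALF: ZoneKind.BOTTOM_HALF,
    ZoneKind.BOTTOM_HALF: ZoneKind.TOP_HALF,
}


@dataclass(frozen=True)
class Zone:
    """A spatial trigger zone: one of the four frame halves, or an explicit
    rectangle with inclusive integer-pixel bounds (min_x, min_y, max_x, max_y)."""

    kind: ZoneKind
    rect: Optional[tuple[float, float, float, float]] = None

    def __post_init__(self) -> None:
        if isinstance(self.kind, str) and not isinstance(self.kind, ZoneKind):
            object.__setattr__(self, "kind", ZoneKind(self.kind))
        if self.kind is ZoneKind.RECT:
            if self.rect is None:
                raise ValueError("rect zone requires bounds")
            x0, y0, x1, y1 = self.rect
            if x0 > x1 or y0 > y1:
                raise ValueError("rect bounds must be ordered")
        elif self.rect is not None:
            raise ValueError("half-zones take no rect bounds")


class EventKind(str, Enum):
    INPUT_TTL = "input_ttl"
    OUTPUT_PULSE = "output_pulse"
    ZONE_REVERSAL = "zone_reversal"
    SESSION_MARK = "session_mark"


@dataclass(frozen=True)
class EventRecord:
    """A timestamped device event, optionally tagged with the subject's
    last known position."""

    timestamp: float
    kind: EventKind
    position: Optional[Point2D] = None

    def __post_init__(self) -> None:
        if isinstance(self.kind, str) and not isinstance(self.kind, EventKind):
            object.__setattr__(self, "kind", EventKind(self.kind))


def in_zone(p: Point2D, zone: Zone, frame_width: int, frame_height: int) -> bool:
    """Zone membership under the half-open convention.

    Halves split at width/2 or height/2 with the boundary belonging to the
    right/bottom half, so left/right (and top/bottom) partition the frame.
    Rect membership is ``min <= coord < max + 1`` (inclusive bounds on
    integer pixels).  Points outside the frame are an error.
    """
    if not (0 <= p.x < frame_width and 0 <= p.y < frame_height):
        raise ValueError(f"point ({p.x}, {p.y}) outside {frame_width}x{frame_height} frame")
    k = zone.kind
    if k is ZoneKind.LEFT_HALF:
        return p.x < frame_width / 2
    if k is ZoneKind.RIGHT_HALF:
        return p.x >= frame_width / 2
    if k is ZoneKind.TOP_HALF:
        return p.y < frame_height / 2
    if k is ZoneKind.BOTTOM_HALF:
        return p.y >= frame_height / 2
    x0, y0, x1, y1 = zone.rect
    return (x0 <= p.x < x1 + 1) and (y0 <= p.y < y1 + 1)


@dataclass(frozen=True)
class ControllerState:
    """Immutable closed-loop controller state; :func:`controller_step`
    returns the successor state plus any events it emitted."""

    active_zone: Zone
    frame_width: int
    frame_height: int
    pulse_rate: float = 15.0
    hold_frames: int = 5
    inside: bool = False
    pulses_emitted: int = 0
    last_pulse_time: Optional[float] = None
    dwell_anchor: Optional[float] = None
    episode_pulses: int = 0
    invalid_streak: int = 0
    last_position: Optional[Point2D] = None
    last_now: Optional[float] = None

    def __post_init__(self) -> None:
        if self.pulse_rate <= 0:
            raise ValueError("pulse_rate must be positive")
        if self.hold_frames < 0:
            raise ValueError("hold_frames must be nonnegative")


def controller_step(
    state: ControllerState, point: TrackPoint, now: float
) -> tuple[ControllerState, list[EventRecord]]:
    """Advance the controller by one frame.

    If the subject is in the active zone, emits every pulse scheduled at
    ``dwell_anchor + k / pulse_rate`` up to ``now``.  Invalid points hold the
    previous in/out state for at most ``hold_frames`` consecutive frames.
    """
    if state.last_now is not None and now < state.last_now:
        raise StreamError(f"time went backwards: {now} after {state.last_now}")

    if point.valid:
        position = point.position
        inside = in_zone(position, state.active_zone, state.frame_width, state.frame_height)
        streak = 0
    else:
        position = state.last_position
        streak = state.invalid_streak + 1
        inside = state.inside and streak <= state.hold_frames

    events: list[EventRecord] = []
    anchor = state.dwell_anchor
    episode_pulses = state.episode_pulses
    last_pulse = state.last_pulse_time
    if inside:
        if not state.inside or anchor is None:
            anchor = now
            episode_pulses = 0
        period = 1.0 / state.pulse_rate
        # Emit all pulses due by `now`; float-safe via index arithmetic.
        n_due = int((now - anchor) / period + 1e-9) + 1
        for k in range(episode_pulses, n_due):
            t = anchor + k * period
            events.append(EventRecord(t, EventKind.OUTPUT_PULSE, position))
            last_pulse = t
        episode_pulses = max(episode_pulses, n_due)
    else:
        anchor = None
        episode_pulses = 0

    new_state = replace(
        state,
        inside=inside,
        pulses_emitted=state.pulses_emitted + len(events),
        last_pulse_time=last_pulse,
        dwell_anchor=anchor,
        episode_pulses=episode_pulses,
        invalid_streak=streak,
        last_position=position,
        last_now=now,
    )
    return new_state, events


def reverse_zone(state: ControllerState, now: float) -> tuple[ControllerState, EventRecord]:
    """Swap the active half-zone for its complement, resetting the pulse
    schedule; records a zone_reversal event.  Rect zones have no complement."""
    if state.active_zone.kind not in _COMPLEMENT:
        raise ValueError("only half-zones can be reversed")
    new_zone = Zone(_COMPLEMENT[state.active_zone.kind])
    event = EventRecord(now, EventKind.ZONE_REVERSAL, state.last_position)
    new_state = replace(
        state,
        active_zone=new_zone,
        inside=False,
        dwell_anchor=None,
        episode_pulses=0,
        last_now=now,
    )
    return new_state, event


def log_input_event(now: float, point: Optional[TrackPoint]) -> EventRecord:
    """Record an external TTL-style input (e.g. a pellet retrieval) stamped
    ``now`` and carrying the most recent valid position, if any."""
    position = point.position if (point is not None and point.valid) else None
    return EventRecord(now, EventKind.INPUT_TTL, position)


def run_controller(
    points: list[TrackPoint],
    frame_shape: tuple[int, int],
    zone: Zone,
    pulse_rate: float = 15.0,
    reversal_time: Optional[float] = None,
    hold_frames: int = 5,
) -> list[EventRecord]:
    """Replay a completed track through the closed-loop controller.

    Applies :func:`reverse_zone` at the first frame whose timestamp reaches
    ``reversal_time`` (if given) and returns the full ordered event log.
    """
    height, width = frame_shape
    state = ControllerState(
        active_zone=zone,
        frame_width=width,
        frame_height=height,
        pulse_rate=pulse_rate,
        hold_frames=hold_frames,
    )
    events: list[EventRecord] = []
    reversed_ = False
    for point in points:
        if reversal_time is not None and not reversed_ and point.timestamp >= reversal_time:
            state, ev = reverse_zone(state, point.timestamp)
            events.append(ev)
            reversed_ = True
        state, pulses = controller_step(state, point, point.timestamp)
        events.extend(pulses)
    return events
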