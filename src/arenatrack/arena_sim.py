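"""Synthetic-arena session generator with per-frame ground truth.

Renders the conditions the tracker was designed for: a single subject —
a filled ellipse, optionally with a thin rectangular "tail" to stress
connectivity handling — moving over a uniform high-contrast floor, under a
dark-on-light or light-on-dark polarity, with optional step changes in
background illumination, static bright glare discs (emulating near-infrared
LED reflections off the floor), additive Gaussian sensor noise, and timed
external device events (virtual pellet retrievals).

Motion is a reflecting Gaussian random walk; place-preference behaviour is
modelled as a constant drift toward the centre of the active half, so a
simulated subject develops a measurable side bias that a real-time
place-preference controller can detect and that reverses when the active
side flips.  All randomness flows from the single config seed; the same
config always renders the identical frame stream.

Defaults mirror the physical device's operating point: a 160x120 sensor at
15 Hz, a dark subject (intensity 30) on a light floor (230), an elliptical
subject of ~190 px (about 1% of the image), a 3 px/frame step scale, and
sensor noise of 5 intensity units.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

from .core import ConfigError, Frame, Point2D
from .closed_loop import EventKind, EventRecord, Zone, ZoneKind, in_zone

__all__ = [
    "ArenaSimConfig",
    "GroundTruth",
    "reflecting_step",
    "simulate_session",
    "virtual_fed",
    "simulate_rtpp",
]


@dataclass(frozen=True)
class ArenaSimConfig:
    """Full description of one synthetic session; a fixed seed makes the
    rendered stream fully reproducible."""

    width: int = 160
    height: int = 120
    background_intensity: float = 230.0
    subject_intensity: float = 30.0
    subject_axes: tuple[float, float] = (10.0, 6.0)  # (semi-major, semi-minor) px
    step_sigma: float = 3.0
    n_frames: int = 500
    frame_rate: float = 15.0
    lighting_schedule: tuple[tuple[int, float], ...] = ()
    glare_spots: tuple[tuple[tuple[float, float], float, float], ...] = ()
    noise_sigma: float = 5.0
    pellet_schedule: tuple[float, ...] = ()
    tail: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        a, b = self.subject_axes
        if 2 * a >= min(self.width, self.height) or a <= 0 or b <= 0 or b > a:
            raise ConfigError("subject must fit inside the arena (0 < minor <= major)")
        for v in (self.background_intensity, self.subject_intensity):
            if not 0 <= v <= 255:
                raise ConfigError("intensities must lie in [0, 255]")
        if self.n_frames < 1:
            raise ConfigError("n_frames must be >= 1")
        if self.frame_rate <= 0 or self.step_sigma < 0 or self.noise_sigma < 0:
            raise ConfigError("rates and scales must be nonnegative (frame_rate positive)")
        ts = [t for t in self.pellet_schedule]
        if any(b < a for a, b in zip(ts, ts[1:])):
            raise ConfigError("pellet_schedule must be nondecreasing")
        duration = self.n_frames / self.frame_rate
        if any(t < 0 or t > duration for t in ts):
            raise ConfigError("pellet timestamps must lie within the session")


@dataclass
class GroundTruth:
    """Per-frame truth for a simulated session: subject centres, binary
    subject masks, and device events with the subject's true position."""

    positions: list[Point2D]
    label_masks: list[np.ndarray]
    events: list[EventRecord] = field(default_factory=list)
    side_in_zone: Optional[list[bool]] = None  # RTPP: per-frame active-zone occupancy


def reflecting_step(
    center: Point2D,
    sigma: float,
    bounds: tuple[float, float, float, float],
    rng: np.random.Generator,
    drift: tuple[float, float] = (0.0, 0.0),
) -> Point2D:
    """One random-walk step with Gaussian displacements, reflected off the
    walls so the result stays strictly inside ``bounds``
    (min_x, min_y, max_x, max_y)."""
    min_x, min_y, max_x, max_y = bounds
    dx, dy = rng.normal(0.0, sigma, size=2) if sigma > 0 else (0.0, 0.0)
    x = _reflect(center.x + dx + drift[0], min_x, max_x)
    y = _reflect(center.y + dy + drift[1], min_y, max_y)
    return Point2D(x, y)


def _reflect(v: float, lo: float, hi: float) -> float:
    # Fold the coordinate into [lo, hi] by successive wall reflections.
    span = hi - lo
    if span <= 0:
        return lo
    v = (v - lo) % (2 * span)
    if v > span:
        v = 2 * span - v
    return lo + v


def _render_frame(
    cfg: ArenaSimConfig,
    center: Point2D,
    background: float,
    rng: Optional[np.random.Generator],
    yy: np.ndarray,
    xx: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """Render one frame and its ground-truth subject mask."""
    img = np.full((cfg.height, cfg.width), background, dtype=np.float64)
    for (gx, gy), radius, intensity in cfg.glare_spots:
        disc = (xx - gx) ** 2 + (yy - gy) ** 2 <= radius**2
        img[disc] = intensity
    a, b = cfg.subject_axes
    mask = ((xx - center.x) / a) ** 2 + ((yy - center.y) / b) ** 2 <= 1.0
    if cfg.tail:
        # thin 1-px horizontal tail trailing the ellipse, to stress
        # 8- vs 4-connectivity
        tail_len = 2 * a
        y0 = int(round(center.y))
        x1 = int(round(center.x - a))
        x0 = max(0, int(round(x1 - tail_len)))
        if 0 <= y0 < cfg.height and x0 < x1:
            mask[y0, x0:x1] = True
    img[mask] = cfg.subject_intensity
    if rng is not None and cfg.noise_sigma > 0:
        img = img + rng.normal(0.0, cfg.noise_sigma, img.shape)
    img = np.clip(np.rint(img), 0, 255).astype(np.uint8)
    return img, mask


def _background_at(cfg: ArenaSimConfig, frame_index: int) -> float:
    bg = cfg.background_intensity
    for idx, value in sorted(cfg.lighting_schedule):
        if frame_index >= idx:
            bg = value
    return bg


def simulate_session(cfg: ArenaSimConfig) -> tuple[list[Frame], GroundTruth]:
    """Render a full session: a reflecting random walk of the subject centre,
    lighting schedule applied, glare and noise added, pellet events stamped
    with the true subject position at the event frame."""
    # separate streams: the trajectory is invariant to noise settings
    motion_rng, noise_rng = np.random.default_rng(cfg.seed).spawn(2)
    a, _ = cfg.subject_axes
    margin = a + 1.0
    bounds = (margin, margin, cfg.width - 1 - margin, cfg.height - 1 - margin)
    if bounds[2] <= bounds[0] or bounds[3] <= bounds[1]:
        raise ConfigError("arena too small for the subject")
    center = Point2D((bounds[0] + bounds[2]) / 2, (bounds[1] + bounds[3]) / 2)

    frames: list[Frame] = []
    positions: list[Point2D] = []
    masks: list[np.ndarray] = []
    yy, xx = np.mgrid[0 : cfg.height, 0 : cfg.width].astype(np.float64)
    for i in range(cfg.n_frames):
        if i > 0:
            center = reflecting_step(center, cfg.step_sigma, bounds, motion_rng)
        img, mask = _render_frame(cfg, center, _background_at(cfg, i), noise_rng, yy, xx)
        frames.append(Frame(img, index=i, timestamp=i / cfg.frame_rate))
        positions.append(center)
        masks.append(mask)

    events = []
    for t in cfg.pellet_schedule:
        idx = min(int(round(t * cfg.frame_rate)), cfg.n_frames - 1)
        events.append(EventRecord(t, EventKind.INPUT_TTL, positions[idx]))
    return frames, GroundTruth(positions=positions, label_masks=masks, events=events)


def virtual_fed(
    schedule: tuple[float, ...] | list[float], duration: Optional[float] = None
) -> list[EventRecord]:
    """Emit TTL-style input events at the scheduled times (a virtual pellet
    dispenser); positions are attached later by the event logger."""
    ts = list(schedule)
    if any(b < a for a, b in zip(ts, ts[1:])):
        raise ConfigError("schedule must be nondecreasing")
    if duration is not None and any(t < 0 or t > duration for t in ts):
        raise ConfigError("scheduled timestamp outside the session")
    return [EventRecord(t, EventKind.INPUT_TTL) for t in ts]


def simulate_rtpp(
    cfg: ArenaSimConfig,
    zone: Zone = Zone(ZoneKind.LEFT_HALF),
    pulse_rate: float = 15.0,
    reversal_time: Optional[float] = None,
    preference_strength: float = 0.5,
) -> tuple[list[Frame], GroundTruth]:
    """Render a real-time place-preference session.

    The subject's random walk acquires a drift toward the centre of the
    active half, scaled by ``preference_strength`` in [0, 1] (0 = no
    preference, 1 = drift of one step scale per frame), emulating the rapid
    acquisition of side preference under reinforcing stimulation.  At
    ``reversal_time`` the active half flips and the drift target follows.
    Ground truth records per-frame occupancy of the *initial* active zone.
    """
    if not 0.0 <= preference_strength <= 1.0:
        raise ConfigError("preference_strength must lie in [0, 1]")
    if zone.kind not in (ZoneKind.LEFT_HALF, ZoneKind.RIGHT_HALF, ZoneKind.TOP_HALF, ZoneKind.BOTTOM_HALF):
        raise ConfigError("RTPP simulation needs a half-zone")
    motion_rng, noise_rng = np.random.default_rng(cfg.seed).spawn(2)
    a, _ = cfg.subject_axes
    margin = a + 1.0
    bounds = (margin, margin, cfg.width - 1 - margin, cfg.height - 1 - margin)
    center = Point2D((bounds[0] + bounds[2]) / 2, (bounds[1] + bounds[3]) / 2)

    def zone_target(active: Zone) -> Point2D:
        cx, cy = (cfg.width - 1) / 2, (cfg.height - 1) / 2
        k = active.kind
        if k is ZoneKind.LEFT_HALF:
            return Point2D(cfg.width / 4, cy)
        if k is ZoneKind.RIGHT_HALF:
            return Point2D(3 * cfg.width / 4, cy)
        if k is ZoneKind.TOP_HALF:
            return Point2D(cx, cfg.height / 4)
        return Point2D(cx, 3 * cfg.height / 4)

    frames: list[Frame] = []
    positions: list[Point2D] = []
    masks: list[np.ndarray] = []
    occupancy: list[bool] = []
    yy, xx = np.mgrid[0 : cfg.height, 0 : cfg.width].astype(np.float64)
    active = zone
    for i in range(cfg.n_frames):
        t = i / cfg.frame_rate
        if reversal_time is not None and t >= reversal_time and active is zone:
            active = Zone(_opposite(zone.kind))
        if i > 0:
            target = zone_target(active)
            dx, dy = target.x - center.x, target.y - center.y
            norm = max(np.hypot(dx, dy), 1e-9)
            scale = preference_strength * cfg.step_sigma / norm
            center = reflecting_step(
                center, cfg.step_sigma, bounds, motion_rng, drift=(dx * scale, dy * scale)
            )
        img, mask = _render_frame(cfg, center, _background_at(cfg, i), noise_rng, yy, xx)
        frames.append(Frame(img, index=i, timestamp=t))
        positions.append(center)
        masks.append(mask)
        occupancy.append(in_zone(center, zone, cfg.width, cfg.height))
    gt = GroundTruth(positions=positions, label_masks=masks, side_in_zone=occupancy)
    return frames, gt


def _opposite(kind: ZoneKind) -> ZoneKind:
    return {
        ZoneKind.LEFT_HALF: ZoneKind.RIGHT_HALF,
        ZoneKind.RIGHT_HALF: ZoneKind.LEFT_HALF,
        ZoneKind.TOP_HALF: ZoneKind.BOTTOM_HALF,
        ZoneKind.BOTTOM_HALF: ZoneKind.TOP_HALF,
    }[kind]
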