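"""Session-log file I/O and video/frame-sequence input.

A session is stored as a single CSV text file holding one row per frame plus
interleaved device-event rows — no video is ever written, so file size
scales linearly with frame count.  The dialect is fixed so files are
byte-reproducible:

* ``#``-prefixed ``key=value`` metadata lines (session id, session start
  date-time, frame dimensions, pipeline configuration), then the mandatory
  header ``datetime,frame,x,y,speed,event``;
* comma separator, ``.`` decimal, ``\\n`` line endings;
* per-row date-time in ISO-8601 with milliseconds (session start plus the
  frame timestamp);
* coordinates at 2 decimals, speed at 3 decimals (below tracking noise);
* invalid frames keep their row but with empty x/y/speed fields (missing,
  not zero);
* event rows carry the event kind in the ``event`` column, the event
  position (when known) in x/y, and an empty frame/speed field.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass, field
from pathlib import Path
from typing import TYPE_CHECKING, Iterable, Optional, Union

import imageio.v3 as iio
import numpy as np

from .core import Frame, PipelineConfig, Point2D, Polarity, to_grayscale

if TYPE_CHECKING:  # imported lazily at run time to avoid an import cycle
    from .blobtrack import TrackPoint
    from .closed_loop import EventRecord

__all__ = [
    "SessionLog",
    "FormatError",
    "IntegrityError",
    "write_session",
    "read_session",
    "new_session",
    "read_video",
    "write_frames",
]

HEADER = "datetime,frame,x,y,speed,event"
_DEFAULT_START = _dt.datetime(2000, 1, 1, 0, 0, 0)


class FormatError(ValueError):
    """Session file does not conform to the documented CSV dialect."""


class IntegrityError(ValueError):
    """Session file parsed but violates ordering invariants."""


@dataclass
class SessionLog:
    """One recording session: ordered per-frame track points, ordered device
    events, and the configuration snapshot they were produced under."""

    session_id: str
    points: list["TrackPoint"] = field(default_factory=list)
    events: list["EventRecord"] = field(default_factory=list)
    config_snapshot: PipelineConfig = field(default_factory=PipelineConfig)
    start_datetime: Optional[_dt.datetime] = None
    frame_shape: Optional[tuple[int, int]] = None  # (height, width)

    def __post_init__(self) -> None:
        if not self.session_id:
            raise ValueError("session_id must be nonempty")
        if self.start_datetime is None:
            self.start_datetime = _DEFAULT_START
        for a, b in zip(self.points, self.points[1:]):
            if b.frame_index <= a.frame_index:
                raise IntegrityError("points must be ordered by frame_index")
        for a, b in zip(self.events, self.events[1:]):
            if b.timestamp < a.timestamp:
                raise IntegrityError("events must be ordered by timestamp")

    @property
    def duration(self) -> float:
        return self.points[-1].timestamp if self.points else 0.0

    @property
    def valid_fraction(self) -> float:
        if not self.points:
            return 0.0
        return sum(p.valid for p in self.points) / len(self.points)


def _fmt_dt(start: _dt.datetime, seconds: float) -> str:
    stamp = start + _dt.timedelta(seconds=seconds)
    return stamp.strftime("%Y-%m-%dT%H:%M:%S.") + f"{stamp.microsecond // 1000:03d}"


def _meta_lines(log: SessionLog) -> list[str]:
    cfg = log.config_snapshot
    h, w = log.frame_shape if log.frame_shape is not None else ("", "")
    opt = lambda v: "" if v is None else repr(float(v))
    return [
        f"# session_id={log.session_id}",
        f"# start_datetime={log.start_datetime.isoformat(timespec='seconds')}",
        f"# frame_height={h}",
        f"# frame_width={w}",
        f"# polarity={cfg.polarity.value}",
        f"# threshold_update_interval={cfg.threshold_update_interval}",
        f"# min_blob_area={opt(cfg.min_blob_area)}",
        f"# max_blob_area={opt(cfg.max_blob_area)}",
        f"# frame_rate={cfg.frame_rate!r}",
        f"# connectivity={cfg.connectivity}",
        f"# min_area_fraction={cfg.min_area_fraction!r}",
        f"# max_area_fraction={cfg.max_area_fraction!r}",
    ]


def write_session(log: SessionLog, destination: Union[str, Path]) -> Path:
    """Write a session to its CSV file.  Byte-deterministic for a given log."""
    lines = _meta_lines(log) + [HEADER]
    # rows interleave on the millisecond datetime string the file actually
    # stores (points before events at equal times), so re-sorting after a
    # round trip is stable and rewrites are byte-identical
    rows: list[tuple[str, int, str]] = []  # (stored datetime, tiebreak, line)
    for p in log.points:
        if p.valid:
            x, y = f"{p.position.x:.2f}", f"{p.position.y:.2f}"
            s = "" if p.speed is None else f"{p.speed:.3f}"
        else:
            x = y = s = ""
        stamp = _fmt_dt(log.start_datetime, p.timestamp)
        line = f"{stamp},{p.frame_index},{x},{y},{s},"
        rows.append((stamp, 0, line))
    for e in log.events:
        if e.position is not None:
            x, y = f"{e.position.x:.2f}", f"{e.position.y:.2f}"
        else:
            x = y = ""
        stamp = _fmt_dt(log.start_datetime, e.timestamp)
        line = f"{stamp},,{x},{y},,{e.kind.value}"
        rows.append((stamp, 1, line))
    rows.sort(key=lambda r: (r[0], r[1]))
    lines.extend(line for _, _, line in rows)
    path = Path(destination)
    path.write_text("\n".join(lines) + "\n")
    return path


def _parse_meta(lines: list[str]) -> dict:
    meta: dict = {}
    for raw in lines:
        body = raw[1:].strip()
        if "=" in body:
            k, _, v = body.partition("=")
            meta[k.strip()] = v.strip()
    return meta


def read_session(source: Union[str, Path]) -> SessionLog:
    """Parse a session CSV written by :func:`write_session` (its inverse).

    Malformed rows raise :class:`FormatError` with their line number;
    non-monotone frame indices raise :class:`IntegrityError`.
    """
    from .blobtrack import TrackPoint
    from .closed_loop import EventKind, EventRecord

    text = Path(source).read_text()
    lines = text.splitlines()
    meta_lines = []
    i = 0
    while i < len(lines) and lines[i].startswith("#"):
        meta_lines.append(lines[i])
        i += 1
    if i >= len(lines) or lines[i] != HEADER:
        raise FormatError(f"{source}: missing header {HEADER!r}")
    meta = _parse_meta(meta_lines)
    start = (
        _dt.datetime.fromisoformat(meta["start_datetime"])
        if "start_datetime" in meta
        else _DEFAULT_START
    )
    optf = lambda s: None if s in ("", None) else float(s)
    cfg = PipelineConfig(
        polarity=Polarity(meta.get("polarity", "dark_subject")),
        threshold_update_interval=int(meta.get("threshold_update_interval", 50)),
        min_blob_area=optf(meta.get("min_blob_area", "")),
        max_blob_area=optf(meta.get("max_blob_area", "")),
        frame_rate=float(meta.get("frame_rate", 15.0)),
        connectivity=int(meta.get("connectivity", 8)),
        min_area_fraction=float(meta.get("min_area_fraction", 0.001)),
        max_area_fraction=float(meta.get("max_area_fraction", 0.25)),
    )
    shape = None
    if meta.get("frame_height") and meta.get("frame_width"):
        shape = (int(meta["frame_height"]), int(meta["frame_width"]))

    points: list[TrackPoint] = []
    events: list[EventRecord] = []
    last_frame = None
    for lineno, line in enumerate(lines[i + 1 :], start=i + 2):
        if not line.strip():
            continue
        parts = line.split(",")
        if len(parts) != 6:
            raise FormatError(f"{source}:{lineno}: expected 6 fields, got {len(parts)}")
        dt_s, frame_s, x_s, y_s, speed_s, event_s = parts
        try:
            stamp = _dt.datetime.fromisoformat(dt_s)
        except ValueError as exc:
            raise FormatError(f"{source}:{lineno}: bad datetime {dt_s!r}") from exc
        t = round((stamp - start).total_seconds(), 3)
        if event_s:
            pos = Point2D(float(x_s), float(y_s)) if x_s and y_s else None
            events.append(EventRecord(t, EventKind(event_s), pos))
            continue
        if not frame_s:
            raise FormatError(f"{source}:{lineno}: row has neither frame nor event")
        frame_index = int(frame_s)
        if last_frame is not None and frame_index <= last_frame:
            raise IntegrityError(
                f"{source}:{lineno}: frame index {frame_index} not after {last_frame}"
            )
        last_frame = frame_index
        if x_s and y_s:
            points.append(
                TrackPoint(
                    frame_index,
                    t,
                    position=Point2D(float(x_s), float(y_s)),
                    speed=float(speed_s) if speed_s else None,
                    valid=True,
                )
            )
        else:
            points.append(TrackPoint(frame_index, t, valid=False))
    sid = meta.get("session_id", Path(source).stem)
    return SessionLog(
        session_id=sid,
        points=points,
        events=events,
        config_snapshot=cfg,
        start_datetime=start,
        frame_shape=shape,
    )


_session_counters: dict[str, tuple[str, int]] = {}


def new_session(prefix: str, now: _dt.datetime) -> str:
    """Mint a session identifier ``<prefix>_<YYYYmmdd>_<HHMMSS>_<NN>``.

    The date-time is embedded at second resolution; ``NN`` is a monotone
    counter that disambiguates calls within the same second (mirroring the
    one-file-per-button-press behaviour of the physical device).
    """
    if not prefix:
        raise ValueError("prefix must be nonempty")
    stamp = now.strftime("%Y%m%d_%H%M%S")
    last_stamp, count = _session_counters.get(prefix, ("", -1))
    count = count + 1 if stamp == last_stamp else 0
    _session_counters[prefix] = (stamp, count)
    return f"{prefix}_{stamp}_{count:02d}"


def _is_image_dir(path: Path) -> bool:
    return path.is_dir()


def read_video(
    source: Union[str, Path],
    target_rate: Optional[float] = None,
    native_rate: float = 15.0,
) -> list[Frame]:
    """Read a video file or an image-sequence directory as grayscale frames.

    Timestamps come from container metadata (or ``native_rate`` for image
    sequences).  When ``target_rate`` is given the stream is resampled by
    dropping frames (keeping every ``round(native/target)``-th frame) to
    emulate a slower sensor honestly; kept frames retain their original
    timestamps and are reindexed sequentially.
    """
    path = Path(source)
    if _is_image_dir(path):
        files = sorted(
            f for f in path.iterdir() if f.suffix.lower() in (".png", ".tif", ".tiff", ".bmp")
        )
        if not files:
            raise IOError(f"no image files in {path}")
        images = [to_grayscale(iio.imread(f)) for f in files]
        fps = native_rate
    else:
        if not path.exists():
            raise IOError(f"no such video file: {path}")
        images = [to_grayscale(im) for im in iio.imiter(path)]
        meta = iio.immeta(path)
        fps = float(meta.get("fps", native_rate)) or native_rate
        if not images:
            raise IOError(f"zero frames in {path}")

    step = 1
    if target_rate is not None:
        if target_rate <= 0:
            raise ValueError("target_rate must be positive")
        step = max(1, round(fps / target_rate))
    frames = []
    for out_idx, src_idx in enumerate(range(0, len(images), step)):
        frames.append(Frame(images[src_idx], index=out_idx, timestamp=src_idx / fps))
    return frames


def write_frames(frames: Iterable[Frame], directory: Union[str, Path]) -> Path:
    """Write frames as a zero-padded PNG sequence ``frame_00000.png``..."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for frame in frames:
        iio.imwrite(
            directory / f"frame_{frame.index:05d}.png",
            np.asarray(frame.pixels, dtype=np.uint8),
        )
    return directory
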