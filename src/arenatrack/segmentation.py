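"""Dynamic global thresholding of grayscale frames.

The subject is separated from the arena floor by a single global intensity
threshold that is recomputed periodically (every ``threshold_update_interval``
frames, 50 by default, ~4 s at 15 Hz) so segmentation adapts automatically
to lighting changes.  The threshold rule is Otsu's criterion: the cut of the
256-bin intensity histogram that maximises between-class variance.  The rule
is pluggable via the ``threshold_fn`` argument of :func:`maybe_update` so an
alternative procedure can be substituted.

The stored threshold is the midpoint of the empty intensity gap containing
the optimal histogram cut (mid-gap placement): no pixel can ever equal it,
so the strict comparisons used by :func:`apply_threshold` are unambiguous,
masks are bit-reproducible, and photometric inversion maps a threshold ``t``
to ``255 - t`` exactly — segmenting an inverted frame with the opposite
polarity yields a pixel-identical mask.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from typing import Callable, Optional

import numpy as np

from .core import Frame, Polarity, StreamError

__all__ = [
    "ThresholdState",
    "DegenerateFrameWarning",
    "compute_threshold",
    "apply_threshold",
    "maybe_update",
]

#: Fallback threshold when the very first frame has no separable classes.
_DEFAULT_THRESHOLD = 127.5


class DegenerateFrameWarning(UserWarning):
    """A frame had fewer than two distinct intensities; the previous
    threshold was retained."""


@dataclass(frozen=True)
class ThresholdState:
    """Current segmentation threshold and when it was last recomputed."""

    value: float
    last_update_frame: int
    polarity: Polarity

    def __post_init__(self) -> None:
        if not (0.0 <= self.value <= 255.0):
            raise ValueError("threshold must lie in [0, 255]")
        if self.last_update_frame < 0:
            raise ValueError("last_update_frame must be nonnegative")


def compute_threshold(frame: Frame | np.ndarray) -> Optional[float]:
    """Otsu threshold of a frame: the histogram cut maximising between-class
    variance, placed at the midpoint of the empty intensity gap between the
    two classes it separates.

    Returns ``None`` for degenerate frames (fewer than two distinct
    intensities), signalling the caller to retain its previous threshold.
    Ties between cuts are broken toward the smallest, then the mid-gap
    placement makes the result both deterministic and symmetric under
    photometric inversion.
    """
    pixels = frame.pixels if isinstance(frame, Frame) else np.asarray(frame)
    if pixels.size == 0:
        raise ValueError("cannot threshold an empty frame")
    hist = np.bincount(np.rint(pixels).astype(np.int64).ravel(), minlength=256).astype(np.float64)
    if np.count_nonzero(hist) < 2:
        return None

    # Between-class variance at each cut k + 0.5: classes {I <= k}, {I > k}.
    total = hist.sum()
    w0 = np.cumsum(hist)[:-1]            # weight of lower class at cut k
    w1 = total - w0
    csum = np.cumsum(hist * np.arange(256))[:-1]
    mu_total = (hist * np.arange(256)).sum()
    with np.errstate(divide="ignore", invalid="ignore"):
        mu0 = csum / w0
        mu1 = (mu_total - csum) / w1
        var_between = w0 * w1 * (mu0 - mu1) ** 2
    var_between = np.where((w0 > 0) & (w1 > 0), var_between, -np.inf)
    k = int(np.argmax(var_between))      # argmax takes the first (smallest) maximiser
    # mid-gap placement: centre the threshold between the highest intensity
    # of the lower class and the lowest intensity of the upper class
    present = np.nonzero(hist)[0]
    lo = present[present <= k].max()
    hi = present[present > k].min()
    return (float(lo) + float(hi)) / 2.0


def apply_threshold(frame: Frame | np.ndarray, state: ThresholdState) -> np.ndarray:
    """Binary foreground mask of a frame under the current threshold.

    ``dark_subject``: foreground is strictly below the threshold;
    ``light_subject``: strictly above.  The mask has the frame's shape and
    dtype bool.
    """
    pixels = frame.pixels if isinstance(frame, Frame) else np.asarray(frame)
    if state.polarity is Polarity.DARK_SUBJECT:
        return pixels < state.value
    return pixels > state.value


def maybe_update(
    state: Optional[ThresholdState],
    frame: Frame,
    interval: int,
    polarity: Polarity = Polarity.DARK_SUBJECT,
    threshold_fn: Callable[[Frame], Optional[float]] = compute_threshold,
) -> ThresholdState:
    """Recompute the threshold iff due: at frame 0 (or when ``state`` is
    ``None``, initialisation), or once ``frame.index - last_update_frame``
    reaches ``interval``.  Otherwise the state is returned unchanged.

    Degenerate frames keep the previous threshold and emit a
    :class:`DegenerateFrameWarning` instead of failing: a momentary sensor
    saturation must not kill a session.
    """
    if interval < 1:
        raise ValueError("interval must be >= 1")
    due = state is None or frame.index == 0 or (frame.index - state.last_update_frame) >= interval
    if not due:
        return state
    value = threshold_fn(frame)
    if value is None:
        warnings.warn(
            f"frame {frame.index}: no separable intensity classes; keeping previous threshold",
            DegenerateFrameWarning,
            stacklevel=2,
        )
        if state is None:
            return ThresholdState(_DEFAULT_THRESHOLD, frame.index, polarity)
        return replace(state, last_update_frame=frame.index)
    pol = state.polarity if state is not None else polarity
    return ThresholdState(float(value), frame.index, pol)
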