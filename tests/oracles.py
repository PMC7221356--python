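"""Independent brute-force oracles used to validate the implementation.

Each oracle is written as the most direct, obviously-correct computation of
its quantity (exhaustive scans, recursive region growing, literal
slice-and-bin) and shares no code with the implementation path it checks.
"""

from __future__ import annotations

import numpy as np


def otsu_bruteforce(pixels: np.ndarray) -> float | None:
    """Exhaustive scan of all 255 half-integer cuts, maximising
    between-class variance of the two pixel populations directly; the final
    threshold is the centre of the intensity gap at the best cut."""
    flat = np.rint(np.asarray(pixels, dtype=float)).ravel()
    if np.unique(flat).size < 2:
        return None
    best_cut, best_var = None, -1.0
    for k in range(255):
        cut = k + 0.5
        lo = flat[flat < cut]
        hi = flat[flat > cut]
        if lo.size == 0 or hi.size == 0:
            continue
        w0 = lo.size / flat.size
        w1 = hi.size / flat.size
        var = w0 * w1 * (lo.mean() - hi.mean()) ** 2
        if var > best_var + 1e-12:  # strict improvement -> smallest cut wins ties
            best_var, best_cut = var, cut
    return (flat[flat < best_cut].max() + flat[flat > best_cut].min()) / 2.0


def floodfill_components(mask: np.ndarray, connectivity: int) -> list[frozenset]:
    """Partition a binary mask into connected components by iterative
    stack-based flood fill.  Returns a list of frozensets of (y, x) pixels."""
    mask = np.asarray(mask, dtype=bool)
    h, w = mask.shape
    if connectivity == 4:
        nbrs = [(-1, 0), (1, 0), (0, -1), (0, 1)]
    elif connectivity == 8:
        nbrs = [(dy, dx) for dy in (-1, 0, 1) for dx in (-1, 0, 1) if (dy, dx) != (0, 0)]
    else:
        raise ValueError("connectivity must be 4 or 8")
    seen = np.zeros_like(mask)
    components = []
    for sy in range(h):
        for sx in range(w):
            if not mask[sy, sx] or seen[sy, sx]:
                continue
            stack = [(sy, sx)]
            seen[sy, sx] = True
            pixels = []
            while stack:
                y, x = stack.pop()
                pixels.append((y, x))
                for dy, dx in nbrs:
                    ny, nx = y + dy, x + dx
                    if 0 <= ny < h and 0 <= nx < w and mask[ny, nx] and not seen[ny, nx]:
                        seen[ny, nx] = True
                        stack.append((ny, nx))
            components.append(frozenset(pixels))
    return components


def perievent_bruteforce(
    times: np.ndarray,
    speeds: np.ndarray,
    events: list[float],
    pre: float,
    post: float,
    bin_width: float,
) -> tuple[np.ndarray, np.ndarray]:
    """Literal per-event slice-and-bin: for each event and each bin
    [t + left, t + left + bin), average the speeds of frames falling in it."""
    edges = np.arange(-pre, post + bin_width / 2, bin_width)
    n_bins = len(edges) - 1
    raster = np.full((len(events), n_bins), np.nan)
    for i, t in enumerate(events):
        for b in range(n_bins):
            left, right = t + edges[b], t + edges[b + 1]
            vals = [
                s
                for tt, s in zip(times, speeds)
                if left <= tt < right and not np.isnan(s)
            ]
            if vals:
                raster[i, b] = float(np.mean(vals))
    mean_trace = np.array(
        [
            np.mean(col[~np.isnan(col)]) if np.any(~np.isnan(col)) else np.nan
            for col in raster.T
        ]
    )
    return raster, mean_trace


def weighted_centroid_tracker(frames, background: float, dark_subject: bool = True):
    """Reference tracker: intensity-weighted centroid of the deviation from
    the background level, independent of thresholding and blob logic."""
    xs, ys = [], []
    for frame in frames:
        px = np.asarray(frame.pixels, dtype=float)
        w = np.clip(background - px, 0, None) if dark_subject else np.clip(px - background, 0, None)
        total = w.sum()
        yy, xx = np.mgrid[0 : px.shape[0], 0 : px.shape[1]]
        xs.append(float((w * xx).sum() / total))
        ys.append(float((w * yy).sum() / total))
    return np.array(xs), np.array(ys)


def pulse_schedule_bruteforce(entry: float, exit_: float, rate: float) -> list[float]:
    """Enumerate the pulse times of one dwell episode: first pulse at entry,
    then every 1/rate seconds, strictly before exit."""
    pulses = []
    k = 0
    while True:
        t = entry + k / rate
        if t >= exit_ - 1e-12:
            break
        pulses.append(t)
        k += 1
    return pulses
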