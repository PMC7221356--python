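# arenatrack

Machine-vision tracking of a single rodent in a high-contrast arena, at desk
scale.  `arenatrack` re-implements, as a tested Python library and CLI, the
processing pipeline of compact embedded tracking cameras used in behavioral
neuroscience: per-frame global segmentation with a dynamically updated
threshold, blob size filtering with largest-blob centroid selection,
inter-frame speed, plain-text per-frame logging, and closed-loop control
that emits a fixed-rate pulse train while the animal occupies a trigger
zone.  It is intended for researchers who want to prototype, validate, or
re-analyze this style of tracking without camera hardware — every stage can
be driven by the included ground-truthed arena simulator.

## The pipeline

For each grayscale frame *I<sub>t</sub>* (rows = *y*, columns = *x*, 8-bit):

1. **Dynamic threshold.**  Every *K* frames (default *K* = 50, ~4 s at
   15 Hz) a global threshold is recomputed by Otsu's criterion — the
   histogram cut maximizing the between-class variance
   σ²<sub>b</sub>(θ) = ω₀ω₁(μ₀ − μ₁)² — and placed at the midpoint of the
   empty intensity gap between the two classes.  Periodic recomputation
   makes segmentation self-adjusting under lighting changes.
2. **Segmentation.**  Foreground is *I* < θ for a dark subject on a light
   floor, *I* > θ for the inverse polarity (white coat on dark floor).
3. **Blob filtering.**  Connected components (8-connectivity) are filtered
   to an inclusive area window [*A*<sub>min</sub>, *A*<sub>max</sub>]
   (defaults 0.1 % and 25 % of the image), rejecting pixel noise and large
   bright artifacts such as infrared glare; the largest surviving blob is
   the subject and its unweighted pixel centroid (x̄, ȳ) is the position.
4. **Speed.**  v<sub>t</sub> = ‖c<sub>t</sub> − c<sub>t′</sub>‖ / (t − t′)
   in pixels/frame, where t′ is the previous frame with a valid detection
   (gap-normalized).  Conversion to cm/s is an explicit off-line
   calibration step.
5. **Logging.**  One CSV row per frame (ISO-8601 datetime, frame index,
   x, y, speed) with device events interleaved; no video is stored, so
   file size grows linearly with session length.
6. **Closed loop.**  While the tracked position is inside the active zone
   (e.g. the left half of the arena) the controller emits pulses at a fixed
   rate (default 15 Hz) — the trigger signal of a real-time
   place-preference (RTPP) assay — and the active half can be reversed
   mid-session.

Downstream analyses cover the pipeline's canonical use cases: circadian
activity profiles (distance per time bin), perievent speed rasters around
logged events such as pellet retrievals, and per-segment side-preference
quantification.

## Worked example

```python
import numpy as np
from arenatrack import (ArenaSimConfig, PipelineConfig, simulate_session,
                        track_session, activity_profile, Calibration)

# a 30 s synthetic session: dark subject (30) on a light floor (230),
# 160x120 px at 15 Hz, sensor noise sigma = 5
cfg = ArenaSimConfig(n_frames=450, seed=42, pellet_schedule=(10.0, 20.0))
frames, truth = simulate_session(cfg)

log = track_session(frames, PipelineConfig())
err = [p.position.distance_to(g) for p, g in zip(log.points, truth.positions)]
print(f"frames tracked      : {len(log.points)}")
print(f"valid fraction      : {log.valid_fraction:.3f}")
print(f"centroid RMSE (px)  : {np.sqrt(np.mean(np.square(err))):.3f}")

cal = Calibration(pixels_per_cm=4.0, frame_rate=15.0)
prof = activity_profile(log, bin_width=10.0, cal=cal)
print(f"distance in 30 s    : {prof.total_distance:.1f} {prof.unit}")
```

prints

```
frames tracked      : 450
valid fraction      : 1.000
centroid RMSE (px)  : 0.088
distance in 30 s    : 414.5 cm
```

Every frame yielded a detection (`valid fraction 1.000` — no lost
tracking), the recovered centroid sits within a tenth of a pixel of the
simulator's ground truth on average, and with a 4 px/cm calibration the
animal covered ~414 cm in the 30 s session.

The same flow is available from the shell:

```bash
arenatrack simulate session_dir --seed 42 --n-frames 450
arenatrack track session_dir/frames session.csv
arenatrack analyze session.csv activity activity.csv --bin 10 --px-per-cm 4
arenatrack rtpp rtpp.csv --seed 1 --duration 120 --reversal-time 60
```

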