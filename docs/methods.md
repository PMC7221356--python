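# Methods

This note documents the models, numerical choices, and design decisions
behind `arenatrack`, and what the synthetic-arena tests do and do not
establish about real recordings.

## Scope and shape of the package

The core artifact is a deterministic image-processing pipeline plus a
closed-loop controller, not a statistical model fitted to data, so the
package is organized as a set of pipeline stages (`segmentation`,
`blobtrack`, `closed_loop`), I/O (`logio`), a simulator (`arena_sim`),
analyses (`analysis`), and a thin CLI — each stage independently callable
and testable.

## Segmentation: dynamic global thresholding

The device this package emulates advertises only "a dynamic thresholding
procedure" that re-adapts every 50 frames.  We fix the rule as **Otsu's
between-class-variance criterion**, chosen because it is parameter-free and
self-adjusting under global lighting changes, which is the stated purpose of
the periodic update.  The threshold function is pluggable
(`maybe_update(..., threshold_fn=...)`) so an alternative rule can be
substituted without touching the rest of the pipeline.

Numerical details that matter:

* **Mid-gap placement.**  After the optimal histogram cut is found
  (ties broken toward the smallest cut), the stored threshold is the
  midpoint between the highest intensity of the lower class and the lowest
  intensity of the upper class.  Three consequences: no pixel can ever
  equal the threshold, so the strict comparisons (`<` for dark subjects,
  `>` for light ones) are unambiguous and masks are bit-reproducible;
  the threshold sits maximally far from both populations, so small noise
  excursions do not flip pixels; and photometric inversion maps a
  threshold *t* to exactly 255 − *t*, making segmentation of an inverted
  frame with the opposite polarity pixel-identical.  Edge-of-class
  placement (e.g. always returning the integer cut index) fails the last
  property by one intensity level.
* **Degenerate frames** (fewer than two distinct intensities, e.g. full
  sensor saturation) keep the previous threshold and emit a warning rather
  than raising: a momentary glitch must not kill a session.  If the very
  first frame is degenerate the threshold falls back to mid-range (127.5).
* **Update schedule.**  The threshold is recomputed at frame 0 and
  whenever `frame.index - last_update_frame >= interval` (default 50
  frames, ~4 s at 15 Hz).  Between updates the threshold is frozen, which
  bounds the recovery latency after a lighting step by one interval.

## Blob extraction and tracking

Connected components are computed by `scipy.ndimage.label`; the default
connectivity is 8 because thin body parts (a tail rendered 1 px wide)
fragment under 4-connectivity.  The size filter is inclusive on both
bounds; since no canonical pixel values exist for the area window, defaults
are expressed as fractions of the image area (min 0.1 %, max 25 %) so they
transfer across resolutions.  The upper bound is what rejects large bright
glare regions under light-subject polarity.  Blob order and largest-blob
ties are made deterministic by sorting on (area desc, bbox min-y, bbox
min-x).

The centroid is the unweighted mean of member pixel coordinates — binary
mask semantics; intensity weighting would couple position to lighting.
Coordinates follow standard image-array indexing: origin at the top-left
pixel center, x rightward, y downward, 0-based.

**Speed policy.**  Native speed is pixels/frame.  After a detection gap of
g frames, the speed on reacquisition is distance ÷ g (gap-normalized)
rather than distance per frame: bounded, unit-consistent, and free of
spurious spikes.  The first valid detection of a session has no speed.
Conversion to cm/s (`Calibration`, `calibrate_speed`) is an explicit
separate step, mirroring the off-line calibration workflow of the physical
device; there is no automatic arena-size calibration.

## Closed-loop controller

Pulse scheduling is anchored to dwell-episode onset: the first pulse fires
immediately on zone entry, subsequent pulses at 1/rate intervals, which
bounds any episode's count by |pulses − ⌊duration × rate⌋| ≤ 1.  The
half-zones use a half-open boundary (the center column/row belongs to the
right/bottom half) so left/right partition the frame exactly.  When
tracking drops, the controller holds the last in/out state for up to 5
consecutive invalid frames (configurable) before stopping the train — a
policy choice, since dropped-frame behavior during stimulation is not
otherwise specified.  Zone reversal is a software flip of the active half
(physically this was done by rotating the camera 180°; the effect on the
control law is the same) and resets the pulse schedule.  Pulses are
timestamped event records; no electrical signaling layer exists here.

## Session files

One CSV per session: `#`-prefixed `key=value` metadata (session id, start
date-time, frame dimensions, full pipeline configuration), a mandatory
`datetime,frame,x,y,speed,event` header, then one row per frame with event
rows interleaved.  Fixed dialect — comma separator, `.` decimal, `\n` line
endings, ISO-8601 datetimes at millisecond resolution, coordinates at 2
decimals, speed at 3 (both below tracking noise) — so rewrites are
byte-identical, which the tests assert.  Invalid frames keep their row with
*empty* x/y/speed fields (missing is not zero).  Rows are ordered by the
stored millisecond timestamp with points before events at equal times;
sorting on the stored representation (not the float) is what makes a
read→write round trip byte-stable.  Video input is decimated by frame
dropping (never interpolation) when a lower target rate is requested, to
emulate a slower sensor honestly.

## The arena simulator

`arena_sim` renders what the tracker was built for, with exact ground
truth per frame:

* geometry: 160×120 px (a typical embedded-sensor processing resolution)
  at 15 Hz, the native processing rate of the emulated device;
* photometry: uniform floor at intensity 230 with a dark subject at 30
  (or any other pairing, including the inverse polarity), additive
  Gaussian sensor noise σ = 5, clipped to [0, 255];
* subject: a filled ellipse with semi-axes (10, 6) px (~190 px², ~1 % of
  the image), optionally with a 1-px tail to stress connectivity;
* motion: a reflecting Gaussian random walk, step scale 3 px/frame
  (≈ 11 cm/s at 4 px/cm — a briskly moving mouse); place preference is
  modeled as a constant drift toward the active half's center, scaled by
  `preference_strength` ∈ [0, 1];
* perturbations: scheduled background intensity steps, static bright glare
  discs, and timed virtual pellet events.

Motion and sensor noise draw from two independent generator streams
spawned from the single config seed, so the trajectory is invariant to
noise settings — this is what lets a noise-free re-render of the same
trajectory serve as input to an independent reference tracker.

**What passing tests do not show.**  The simulator has a rigid,
always-visible subject on a spatially uniform floor.  It does not model
posture change, rearing, partial occlusion, bedding disturbance, spatially
varying illumination, shadows that move with the animal, or camera optics
(vignetting, lens distortion).  Accuracy numbers from the simulator are
therefore a validation of the algorithmic chain, not a performance claim
for any specific arena; real deployments need their own contrast check.

## Analyses

* **Activity profile:** distance per time bin (default 10 min, the usual
  resolution for multi-day circadian actograms); each consecutive-frame
  displacement is credited to the bin containing the later frame, so
  binning conserves total distance; gaps contribute nothing.
* **Perievent speed:** default window −10 s..+10 s around each event in
  0.5 s bins — unstated in the original workflow, exposed as parameters;
  bins are half-open and aligned to the event; events whose window exceeds
  the session are dropped with a warning; an empty event list is a warning,
  not an error.  Speeds stay in px/frame unless a calibration is supplied.
* **Side preference:** per segment, valid frames in/out of the zone
  converted to seconds via the logged frame rate; a segment with no valid
  frames reports an absent fraction instead of NaN.  Segment windows are
  explicit parameters (no canonical values exist).

## Problem sizes

Tests and the acceptance script use 200–500-frame sessions at 160×120 px,
a 20-session accuracy battery (10 000 frames), 10 seeds for the
place-preference reversal check, and 50 randomized dwell episodes for the
pulse bound — sizes chosen so the full battery remains a minutes-scale,
single-CPU run while every probability statement still has a usable n.

## Known limitations

* Single animal only; no identity maintenance, occlusion handling, or pose.
* The thresholding rule is this package's choice of a parameter-free
  stand-in for the original device's unpublished procedure; with bimodal
  high-contrast scenes the two agree in behavior (subject/floor
  separation), but they are not the same code.
* Timestamps are stored at millisecond resolution; sub-millisecond event
  timing is rounded in the log files (in-memory values are exact).
* `read_video` relies on container metadata for frame rate; files with
  missing/wrong fps metadata need an explicit `native_rate`.
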