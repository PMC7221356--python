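import numpy as np
import pytest

from arenatrack import (
    ArenaSimConfig,
    Calibration,
    PipelineConfig,
    Point2D,
    simulate_rtpp,
    simulate_session,
    track_session,
)
from arenatrack.analysis import (
    activity_profile,
    perievent_speed,
    side_preference,
    track_plot_data,
)
from arenatrack.blobtrack import TrackPoint
from arenatrack.closed_loop import EventKind, EventRecord, Zone, ZoneKind, run_controller
from arenatrack.logio import SessionLog

from oracles import perievent_bruteforce


def _log_from_xy(xy, fps=15.0, valid=None, events=(), shape=(120, 160)):
    points, last = [], None
    for i, (x, y) in enumerate(xy):
        if valid is not None and not valid[i]:
            points.append(TrackPoint(i, i / fps, valid=False))
            continue
        pos = Point2D(float(x), float(y))
        speed = None
        if last is not None:
            speed = pos.distance_to(last.position) / (i - last.frame_index)
        points.append(TrackPoint(i, i / fps, pos, speed, True))
        last = points[-1]
    return SessionLog(
        session_id="synthetic", points=points, events=list(events),
        config_snapshot=PipelineConfig(frame_rate=fps), frame_shape=shape,
    )


class TestActivityProfile:
    def test_stationary_track_gives_zero_distance(self):
        log = _log_from_xy([(50, 50)] * 120)
        prof = activity_profile(log, bin_width=2.0)
        assert np.all(prof.distance_per_bin == 0)
        assert np.all(prof.valid_fraction_per_bin == 1.0)

    def test_constant_speed_distance_per_bin(self):
        # 2 px/frame along x at 15 Hz, 1-min bins -> 1800 px per full bin
        n = 15 * 150  # 2.5 minutes
        xy = [(i * 2.0, 50) for i in range(n)]
        log = _log_from_xy(xy, shape=(120, 6000))
        prof = activity_profile(log, bin_width=60.0)
        assert prof.distance_per_bin[0] == pytest.approx(1800, rel=0.01)
        assert prof.distance_per_bin[1] == pytest.approx(1800, rel=0.01)

    def test_binning_conserves_total_distance(self, default_track):
        log, _ = default_track
        total = sum(
            b.position.distance_to(a.position)
            for a, b in zip(log.points, log.points[1:])
            if a.valid and b.valid and b.frame_index == a.frame_index + 1
        )
        for bw in (0.7, 2.0, 5.0):
            prof = activity_profile(log, bin_width=bw)
            assert prof.total_distance == pytest.approx(total, rel=1e-9)

    def test_gaps_contribute_nothing(self):
        xy = [(i * 3.0, 50) for i in range(40)]
        valid = [i != 20 for i in range(40)]
        log = _log_from_xy(xy, valid=valid, shape=(120, 200))
        prof = activity_profile(log, bin_width=100.0)
        # 37 moving pairs of 3 px each (pairs into and out of the gap are dropped)
        assert prof.total_distance == pytest.approx(37 * 3.0)

    def test_calibration_converts_to_cm(self):
        xy = [(i * 2.0, 50) for i in range(30)]
        log = _log_from_xy(xy, shape=(120, 200))
        cal = Calibration(pixels_per_cm=10.0, frame_rate=15.0)
        prof = activity_profile(log, bin_width=10.0, cal=cal)
        assert prof.unit == "cm"
        assert prof.total_distance == pytest.approx(29 * 2.0 / 10.0)

    def test_sinusoidal_activity_period_recovered(self):
        """A sinusoidally modulated step scale shows up as the dominant
        Fourier period of the activity profile (compressed circadian run)."""
        rng = np.random.default_rng(42)
        fps, period_s, n = 15.0, 240.0, 15 * 1200  # 20 min, 5 cycles of 4 min
        amp = 3.0
        x, y, xy = 80.0, 60.0, []
        for i in range(n):
            sigma = amp * (1 + np.sin(2 * np.pi * i / (fps * period_s))) / 2 + 0.05
            x = float(np.clip(x + rng.normal(0, sigma), 11, 148))
            y = float(np.clip(y + rng.normal(0, sigma), 11, 108))
            xy.append((x, y))
        log = _log_from_xy(xy)
        prof = activity_profile(log, bin_width=10.0)
        sig = prof.distance_per_bin - prof.distance_per_bin.mean()
        freqs = np.fft.rfftfreq(len(sig), d=10.0)
        power = np.abs(np.fft.rfft(sig)) ** 2
        dominant = freqs[1:][np.argmax(power[1:])]
        assert 1 / dominant == pytest.approx(period_s, rel=0.25)

    def test_empty_log_is_error(self):
        log = SessionLog(session_id="x", frame_shape=(10, 10))
        with pytest.raises(ValueError):
            activity_profile(log, 1.0)


class TestPerieventSpeed:
    def test_constant_speed_raster_is_constant(self):
        xy = [(i * 2.0, 50.0) for i in range(600)]
        log = _log_from_xy(xy, shape=(120, 2000))
        res = perievent_speed(log, events=[15.0, 20.0], window=(5.0, 5.0), bin_width=1.0)
        assert res.raster.shape == (2, 10)
        assert np.allclose(res.raster, 2.0)
        assert np.allclose(res.mean_trace, 2.0)

    def test_matches_bruteforce_oracle_on_random_logs(self, rng):
        for _ in range(10):
            n = 300
            valid = rng.random(n) > 0.15
            xy = np.cumsum(rng.normal(0, 2, size=(n, 2)), axis=0) + 500
            log = _log_from_xy(xy, valid=valid, shape=(2000, 2000))
            events = sorted(rng.uniform(5, 15, size=3).tolist())
            pre, post, bw = 4.0, 4.0, 0.5
            res = perievent_speed(log, events=events, window=(pre, post), bin_width=bw)
            times = np.array([p.timestamp for p in log.points])
            speeds = np.array(
                [p.speed if (p.valid and p.speed is not None) else np.nan for p in log.points]
            )
            raster, trace = perievent_bruteforce(times, speeds, events, pre, post, bw)
            assert np.allclose(res.raster, raster, equal_nan=True)
            assert np.allclose(res.mean_trace, trace, equal_nan=True)

    def test_injected_speed_dip_minimises_event_bin(self):
        """A movement pause at the event time puts the mean-trace minimum in
        the bin containing the event."""
        rng = np.random.default_rng(0)
        n, fps = 1200, 15.0
        events = [20.0, 40.0, 60.0]
        x, xy = 100.0, []
        for i in range(n):
            t = i / fps
            paused = any(abs(t - e) < 0.4 for e in events)
            step = 0.0 if paused else 3.0
            x = float((x + step) % 1500)
            xy.append((x, 50.0))
        log = _log_from_xy(xy, shape=(120, 1600))
        res = perievent_speed(log, events=events, window=(8.0, 8.0), bin_width=0.5)
        min_bin = int(np.nanargmin(res.mean_trace))
        assert abs(res.bin_centers[min_bin]) <= 0.5

    def test_out_of_session_events_dropped_with_warning(self):
        log = _log_from_xy([(i, 50.0) for i in range(150)], shape=(120, 200))
        with pytest.warns(UserWarning, match="dropped"):
            res = perievent_speed(log, events=[0.5, 5.0], window=(2.0, 2.0), bin_width=0.5)
        assert res.raster.shape[0] == 1

    def test_no_usable_events_is_empty_not_error(self):
        log = _log_from_xy([(i, 50.0) for i in range(30)], shape=(120, 200))
        with pytest.warns(UserWarning):
            res = perievent_speed(log, events=[], window=(1.0, 1.0), bin_width=0.5)
        assert res.raster.shape[0] == 0
        assert np.all(np.isnan(res.mean_trace))

    def test_uses_logged_input_events_by_default(self):
        events = [EventRecord(5.0, EventKind.INPUT_TTL)]
        log = _log_from_xy([(i, 50.0) for i in range(150)], events=events, shape=(120, 200))
        res = perievent_speed(log, window=(2.0, 2.0), bin_width=0.5)
        assert list(res.event_times) == [5.0]


class TestSidePreference:
    def test_pinned_subject_full_fraction(self):
        log = _log_from_xy([(10.0, 50.0)] * 60)
        pref = side_preference(log, Zone(ZoneKind.LEFT_HALF))
        assert pref.fraction_in == [1.0]
        assert pref.seconds_out == [0.0]

    def test_driftless_sessions_near_half(self):
        """Monte-Carlo over seeds: mean occupancy within 3 SE of 0.5."""
        fracs = []
        for seed in range(8):
            cfg = ArenaSimConfig(n_frames=400, seed=seed, noise_sigma=0.0)
            _, truth = simulate_rtpp(cfg, preference_strength=0.0)
            fracs.append(np.mean(truth.side_in_zone))
        se = np.std(fracs, ddof=1) / np.sqrt(len(fracs))
        assert abs(np.mean(fracs) - 0.5) <= 3 * max(se, 0.02)

    def test_fractions_partition_valid_time(self, default_track):
        log, _ = default_track
        segs = [(0.0, 5.0), (5.0, 10.0)]
        pref = side_preference(log, Zone(ZoneKind.LEFT_HALF), segs)
        fps = log.config_snapshot.frame_rate
        for (s, e), si, so, fr in zip(segs, pref.seconds_in, pref.seconds_out, pref.fraction_in):
            n_valid = sum(1 for p in log.points if p.valid and s <= p.timestamp < e)
            assert si + so == pytest.approx(n_valid / fps)
            assert 0.0 <= fr <= 1.0

    def test_empty_segment_reports_absent_fraction(self):
        xy = [(10.0, 50.0)] * 30
        valid = [i < 15 for i in range(30)]
        log = _log_from_xy(xy, valid=valid)
        pref = side_preference(log, Zone(ZoneKind.LEFT_HALF), [(0.0, 1.0), (1.5, 2.0)])
        assert pref.fraction_in[0] == 1.0
        assert pref.fraction_in[1] is None

    def test_rtpp_preference_flips_after_reversal(self):
        cfg = ArenaSimConfig(n_frames=900, seed=12)
        frames, _ = simulate_rtpp(
            cfg, Zone(ZoneKind.LEFT_HALF), reversal_time=30.0, preference_strength=0.8
        )
        log = track_session(frames, PipelineConfig())
        pref = side_preference(
            log, Zone(ZoneKind.LEFT_HALF), [(5.0, 30.0), (35.0, 60.0)]
        )
        assert pref.fraction_in[0] > 0.5 > pref.fraction_in[1]

    def test_overlapping_segments_rejected(self, default_track):
        log, _ = default_track
        with pytest.raises(ValueError):
            side_preference(log, Zone(ZoneKind.LEFT_HALF), [(0.0, 5.0), (4.0, 8.0)])


class TestTrackPlotData:
    def test_counts_and_order(self, default_track):
        log, _ = default_track
        xy, overlays = track_plot_data(log)
        assert xy.shape == (sum(p.valid for p in log.points), 2)
        assert overlays == {}
        first_valid = next(p for p in log.points if p.valid)
        assert tuple(xy[0]) == (first_valid.position.x, first_valid.position.y)

    def test_event_overlay_positions_respect_zone(self):
        cfg = ArenaSimConfig(n_frames=450, seed=21)
        zone = Zone(ZoneKind.LEFT_HALF)
        frames, _ = simulate_rtpp(cfg, zone, reversal_time=15.0, preference_strength=0.9)
        log = track_session(frames, PipelineConfig())
        log.events = run_controller(log.points, log.frame_shape, zone, 15.0, 15.0)
        xy, overlays = track_plot_data(log, overlay_events=True)
        pulses = overlays["output_pulse"]
        assert len(pulses) > 0
        reversal_t = next(
            e.timestamp for e in log.events if e.kind is EventKind.ZONE_REVERSAL
        )
        h, w = log.frame_shape
        pulse_events = [e for e in log.events if e.kind is EventKind.OUTPUT_PULSE]
        for e in pulse_events:
            if e.timestamp < reversal_t:
                assert e.position.x < w / 2
            else:
                assert e.position.x >= w / 2
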