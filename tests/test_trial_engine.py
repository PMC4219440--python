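"""Schedule construction, trial state machine, synthetic gaze."""

import math
from collections import Counter

import numpy as np
import pytest

from phosim.geometry import DisplayModel
from phosim.stimuli import generate_sentence
from phosim.trial_engine import (
    EngineParams,
    FONT_LADDER,
    GazeParams,
    GazeTrace,
    TrialSpec,
    VIEWING_CONDITIONS,
    advance_dot_px,
    build_schedule,
    fill_gaps,
    run_trial,
    simulate_gaze_trace,
    start_dot_px,
)

IDS = [f"s{i:02d}" for i in range(1, 49)]


class TestSchedule:
    def test_forty_eight_trials(self):
        assert len(build_schedule(IDS)) == 48

    def test_first_trials_are_largest_font_clear_then_high(self):
        sched = build_schedule(IDS)
        assert (sched[0].font_logmar, sched[0].viewing_name) == (1.5, "clear")
        assert (sched[1].font_logmar, sched[1].viewing_name) == (1.5, "high")

    def test_every_class_occurs_exactly_twice(self):
        tally = Counter(
            (s.font_condition, s.viewing_condition) for s in build_schedule(IDS)
        )
        assert len(tally) == 24
        assert set(tally.values()) == {2}

    def test_each_sentence_used_once_in_order(self):
        sched = build_schedule(IDS)
        assert [s.sentence_id for s in sched] == IDS

    def test_difficulty_monotone_within_each_pass(self):
        sched = build_schedule(IDS)
        for half in (sched[:24], sched[24:]):
            fonts = [s.font_logmar for s in half]
            assert fonts == sorted(fonts, reverse=True)
            for i in range(0, 24, 4):
                assert [s.viewing_name for s in half[i : i + 4]] == list(
                    VIEWING_CONDITIONS
                )

    def test_wrong_id_count_rejected(self):
        with pytest.raises(ValueError):
            build_schedule(IDS[:47])
        with pytest.raises(ValueError):
            build_schedule(IDS[:47] + [IDS[0]])


def scripted_trace(display, engine, read_ms=3000.0, dwell_ms=None, rate_hz=300.0):
    """Noise-free trace: center hold, a reading fixation, top-dot dwell.

    Returns the trace plus the sample times bounding each segment.
    """
    dwell_ms = engine.dwell_ms + 60.0 if dwell_ms is None else dwell_ms
    dt = 1000.0 / rate_hz
    sx, sy = start_dot_px(display)
    ax, ay = advance_dot_px(display)
    segments = [
        ((sx, sy), engine.pre_stimulus_ms + 3 * dt),
        ((sx, sy - 100.0), read_ms),  # looking at the text, far from both dots
        ((ax, ay), dwell_ms),
    ]
    ts, xs, ys = [], [], []
    t = 0.0
    for (x, y), dur in segments:
        n = int(math.floor(dur / dt))
        for k in range(n):
            ts.append(t + k * dt)
            xs.append(x)
            ys.append(y)
        t = ts[-1] + dt
    return GazeTrace(
        np.array(ts), np.array(xs), np.array(ys), np.ones(len(ts), dtype=bool)
    )


@pytest.fixture(scope="module")
def setup():
    display = DisplayModel(width_px=240, height_px=135)
    engine = EngineParams()
    sentence = generate_sentence(seed=0)
    stim = np.zeros((display.height_px, display.width_px))
    spec = TrialSpec(1, 1, 1, "s01", 1)  # clear condition: no rendering
    return display, engine, sentence, stim, spec


class TestRunTrial:
    def test_scripted_reading_time_is_exact(self, setup):
        display, engine, sentence, stim, spec = setup
        trace = scripted_trace(display, engine)
        rec = run_trial(spec, sentence, stim, None, trace, display, engine)
        assert rec.complete
        dt = 1000.0 / 300.0
        # reading starts once the center hold reaches 500 ms and ends at
        # the first sample of the top-dot dwell
        t = trace.t_ms
        sx, sy = start_dot_px(display)
        on_center = np.hypot(trace.x_px - sx, trace.y_px - sy) <= (
            engine.fixation_tolerance_deg * display.px_per_deg_mean
        )
        t_read_on = t[np.flatnonzero(on_center & (t - t[0] >= 500.0))[0]]
        ax, ay = advance_dot_px(display)
        on_dot = np.hypot(trace.x_px - ax, trace.y_px - ay) <= (
            engine.fixation_tolerance_deg * display.px_per_deg_mean
        )
        dwell_start = t[np.flatnonzero(on_dot)[0]]
        assert rec.t_reading_s == pytest.approx((dwell_start - t_read_on) / 1000.0)
        assert abs(dt) > 0  # silence linters

    def test_dwell_shorter_than_350ms_does_not_trigger_end(self, setup):
        display, engine, sentence, stim, spec = setup
        trace = scripted_trace(display, engine, dwell_ms=340.0)
        rec = run_trial(spec, sentence, stim, None, trace, display, engine)
        assert not rec.complete
        assert math.isnan(rec.t_reading_s)

    def test_intertrial_pause_is_2000ms_after_trigger(self, setup):
        display, engine, sentence, stim, spec = setup
        trace = scripted_trace(display, engine)
        rec = run_trial(spec, sentence, stim, None, trace, display, engine)
        ax, ay = advance_dot_px(display)
        on_dot = np.hypot(trace.x_px - ax, trace.y_px - ay) <= (
            engine.fixation_tolerance_deg * display.px_per_deg_mean
        )
        dwell_start = trace.t_ms[np.flatnonzero(on_dot)[0]]
        trigger = trace.t_ms[
            np.flatnonzero(on_dot & (trace.t_ms - dwell_start >= engine.dwell_ms))[0]
        ]
        assert rec.t_end_ms == pytest.approx(trigger + 2000.0)

    def test_clear_condition_renders_no_frames(self, setup):
        display, engine, sentence, stim, spec = setup
        trace = scripted_trace(display, engine)
        rec = run_trial(spec, sentence, stim, None, trace, display, engine)
        assert rec.n_frames_rendered == 0


class TestSimulatedGaze:
    LAYOUT = [(20.0, 220.0, 40.0), (20.0, 220.0, 70.0), (20.0, 220.0, 100.0)]

    def test_sample_interval_is_tracker_rate(self):
        trace = simulate_gaze_trace(self.LAYOUT, GazeParams(), seed=0)
        assert np.allclose(np.diff(trace.t_ms), 1000.0 / 300.0)

    def test_zero_noise_hits_programmed_fixations_exactly(self):
        display = DisplayModel(width_px=240, height_px=135)
        params = GazeParams(fixations_per_line=3, noise_sd_deg=0.0)
        trace = simulate_gaze_trace(self.LAYOUT, params, display, seed=0)
        xs = np.unique(trace.x_px)
        expected = {20 + (i + 0.5) * 200 / 3 for i in range(3)}
        assert set(np.round(xs, 9)) == {round(v, 9) for v in expected}
        assert set(np.unique(trace.y_px)) == {40.0, 70.0, 100.0}

    def test_jitter_sd_matches_tracker_precision(self):
        display = DisplayModel()
        params = GazeParams(fixations_per_line=4, fixation_ms=3000.0)
        trace = simulate_gaze_trace(self.LAYOUT, params, display, seed=1)
        assert len(trace) >= 10_000
        # jitter = sample minus its fixation target; recover targets by
        # snapping to the nearest programmed fixation x
        targets = np.array(
            sorted({20 + (i + 0.5) * 200 / 4 for i in range(4)})
        )
        nearest = targets[np.argmin(np.abs(trace.x_px[:, None] - targets), axis=1)]
        sd_px = np.std(trace.x_px - nearest)
        sd_deg = sd_px / display.px_per_deg_mean
        assert sd_deg == pytest.approx(0.14, rel=0.05)

    def test_deterministic_given_seed(self):
        a = simulate_gaze_trace(self.LAYOUT, seed=9)
        b = simulate_gaze_trace(self.LAYOUT, seed=9)
        assert np.array_equal(a.x_px, b.x_px)


class TestFillGaps:
    def make(self, xs, valid):
        n = len(xs)
        return GazeTrace(
            np.arange(n) * 10.0,
            np.array(xs, dtype=float),
            np.array(xs, dtype=float) * 2,
            np.array(valid, dtype=bool),
        )

    def test_valid_trace_unchanged(self):
        t = self.make([1, 2, 3], [1, 1, 1])
        out = fill_gaps(t)
        assert np.array_equal(out.x_px, t.x_px)

    def test_single_missing_sample_interpolates_midpoint(self):
        t = GazeTrace(
            np.array([0.0, 10.0, 20.0]),
            np.array([0.0, 99.0, 2.0]),
            np.array([0.0, 99.0, 2.0]),
            np.array([True, False, True]),
        )
        out = fill_gaps(t)
        assert out.x_px[1] == pytest.approx(1.0)
        assert out.y_px[1] == pytest.approx(1.0)

    def test_matches_naive_reference_on_random_gap_structure(self, rng):
        n = 400
        t = np.arange(n) * (1000.0 / 300.0)
        x = rng.random(n) * 100
        y = rng.random(n) * 50
        valid = rng.random(n) > 0.25
        valid[0] = valid[-1] = True
        trace = GazeTrace(t, x.copy(), y.copy(), valid.copy())
        out = fill_gaps(trace, max_interp_gap_ms=30.0)

        # naive reference gap-filler
        def naive(vals):
            vals = vals.copy()
            idx = np.flatnonzero(valid)
            vals[: idx[0]] = vals[idx[0]]
            vals[idx[-1] + 1 :] = vals[idx[-1]]
            for a, b in zip(idx[:-1], idx[1:]):
                for k in range(a + 1, b):
                    if t[b] - t[a] <= 30.0:
                        frac = (t[k] - t[a]) / (t[b] - t[a])
                        vals[k] = vals[a] + frac * (vals[b] - vals[a])
                    else:
                        vals[k] = vals[a]
            return vals

        assert np.allclose(out.x_px, naive(x))
        assert np.allclose(out.y_px, naive(y))
        assert out.valid.all()

    def test_leading_and_trailing_gaps_repeat_nearest_valid(self):
        t = self.make([9, 9, 5, 9, 9], [0, 0, 1, 0, 0])
        out = fill_gaps(t)
        assert np.all(out.x_px == 5.0)

    def test_all_invalid_raises(self):
        t = self.make([1, 2], [0, 0])
        with pytest.raises(ValueError):
            fill_gaps(t)
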