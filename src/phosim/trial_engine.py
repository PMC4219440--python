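"""Trial scheduling, the four-phase trial state machine, and synthetic
gaze traces.

A session is a single block of 48 trials: two passes through the 6 font
sizes (1.5 down to 1.0 logMAR), each size shown under 4 viewing
conditions in the fixed order clear, high, medium, low, with a fresh
sentence on every trial.  Each trial runs through Start (fixate the
central dot), Pre-Stimulus (hold fixation), Reading (sentence shown,
frames rendered gaze-contingently for the simulation conditions), and
End (350 ms dwell on the top-center dot, screen blanked, 2000 ms
intertrial pause).  Everything runs on the simulated clock carried by
the gaze trace, so runs are exact and reproducible.

The synthetic gaze generator emulates a reading scanpath: a left-to-
right series of fixations along each text line with saccadic jumps in
between, sampled at the tracker rate (300 Hz) with isotropic Gaussian
jitter matching the instrument's precision (0.14 deg).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .geometry import DisplayModel
from .patterns import PhosphenePattern
from .renderer import render_frame
from .stimuli import SentenceStimulus

__all__ = [
    "FONT_LADDER",
    "VIEWING_CONDITIONS",
    "TrialSpec",
    "GazeTrace",
    "GazeParams",
    "EngineParams",
    "TrialRecord",
    "build_schedule",
    "start_dot_px",
    "advance_dot_px",
    "simulate_gaze_trace",
    "simulate_trial_gaze",
    "fill_gaps",
    "run_trial",
    "run_block",
    "SyntheticReader",
    "records_to_log",
]

FONT_LADDER: tuple[float, ...] = (1.5, 1.4, 1.3, 1.2, 1.1, 1.0)
VIEWING_CONDITIONS: tuple[str, ...] = ("clear", "high", "medium", "low")


@dataclass(frozen=True)
class TrialSpec:
    """One slot of the 48-trial schedule."""

    index: int  # 1..48
    font_condition: int  # 1..6 (largest to smallest)
    viewing_condition: int  # 1..4 (clear, high, medium, low)
    sentence_id: str
    repetition: int  # 1..2

    @property
    def font_logmar(self) -> float:
        return FONT_LADDER[self.font_condition - 1]

    @property
    def viewing_name(self) -> str:
        return VIEWING_CONDITIONS[self.viewing_condition - 1]

    @property
    def is_simulation(self) -> bool:
        return self.viewing_condition != 1


def build_schedule(sentence_ids: "list[str]") -> list[TrialSpec]:
    """The fixed easiest-to-hardest 48-trial schedule.

    Two passes; within each pass font sizes descend, and within each
    font size the viewing conditions run clear, high, medium, low.
    Sentences are consumed in order, each used exactly once.
    """
    ids = list(sentence_ids)
    if len(ids) != len(FONT_LADDER) * len(VIEWING_CONDITIONS) * 2:
        raise ValueError(f"need exactly 48 distinct sentence ids, got {len(ids)}")
    if len(set(ids)) != len(ids):
        raise ValueError("sentence ids must be distinct")
    schedule = []
    k = 0
    for rep in (1, 2):
        for f in range(1, len(FONT_LADDER) + 1):
            for v in range(1, len(VIEWING_CONDITIONS) + 1):
                k += 1
                schedule.append(TrialSpec(k, f, v, ids[k - 1], rep))
    return schedule


@dataclass
class GazeTrace:
    """Timestamped gaze samples in screen pixels."""

    t_ms: np.ndarray
    x_px: np.ndarray
    y_px: np.ndarray
    valid: np.ndarray

    def __post_init__(self) -> None:
        if not np.all(np.diff(self.t_ms) > 0):
            raise ValueError("timestamps must be strictly increasing")

    def __len__(self) -> int:
        return self.t_ms.size

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "t_ms": self.t_ms,
                "x_px": self.x_px,
                "y_px": self.y_px,
                "valid": self.valid.astype(int),
            }
        )

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "GazeTrace":
        return cls(
            t_ms=df["t_ms"].to_numpy(dtype=float),
            x_px=df["x_px"].to_numpy(dtype=float),
            y_px=df["y_px"].to_numpy(dtype=float),
            valid=df["valid"].to_numpy().astype(bool),
        )


@dataclass(frozen=True)
class GazeParams:
    """Synthetic scanpath parameters.

    ``rate_hz`` and ``noise_sd_deg`` default to the gaze tracker's
    streaming rate and precision; the fixation counts and durations are
    in the range of ordinary reading behavior.
    """

    fixations_per_line: int = 4
    fixation_ms: float = 200.0
    noise_sd_deg: float = 0.14
    rate_hz: float = 300.0


@dataclass(frozen=True)
class EngineParams:
    """Trial state-machine timing and tolerances."""

    pre_stimulus_ms: float = 500.0
    dwell_ms: float = 350.0
    fixation_tolerance_deg: float = 2.0
    intertrial_ms: float = 2000.0
    render_hz: float = 60.0  # one frame per display refresh


@dataclass
class TrialRecord:
    """Outcome of one trial: timing, reading outcome, and the gaze used."""

    spec: TrialSpec
    n_words: int
    t_reading_s: float
    errors: "int | None" = None
    complete: bool = True
    t_start_ms: float = 0.0
    t_reading_on_ms: float = math.nan
    t_end_ms: float = math.nan
    n_frames_rendered: int = 0
    gaze: "GazeTrace | None" = None


def start_dot_px(display: DisplayModel) -> tuple[float, float]:
    """Central fixation dot used to engage a trial."""
    return display.center_px


def advance_dot_px(display: DisplayModel) -> tuple[float, float]:
    """Dot near the top center of the screen used to advance trials."""
    return (display.width_px / 2.0, 0.05 * display.height_px)


def _sample_times(start_ms: float, duration_ms: float, rate_hz: float) -> np.ndarray:
    dt = 1000.0 / rate_hz
    n = int(math.floor(duration_ms / dt))
    return start_ms + dt * np.arange(n)


def simulate_gaze_trace(
    layout: "list[tuple[float, float, float]]",
    params: GazeParams = GazeParams(),
    display: DisplayModel | None = None,
    seed: int = 0,
    start_ms: float = 0.0,
) -> GazeTrace:
    """Reading scanpath over a three-line layout.

    ``layout`` lists each text line as ``(x_left, x_right, y_baseline)``
    in pixels.  Fixations step left to right along each line at the
    centers of equal horizontal slices, dwelling ``fixation_ms`` each,
    with instantaneous saccadic jumps between them and isotropic
    Gaussian jitter of ``noise_sd_deg`` on every sample.
    """
    display = display or DisplayModel()
    fixations = []
    for x0, x1, y in layout:
        for i in range(params.fixations_per_line):
            cx = x0 + (i + 0.5) * (x1 - x0) / params.fixations_per_line
            fixations.append((cx, y, params.fixation_ms))
    return _fixation_trace(fixations, params, display, seed, start_ms)


def _fixation_trace(
    fixations: "list[tuple[float, float, float]]",
    params: GazeParams,
    display: DisplayModel,
    seed: int,
    start_ms: float,
) -> GazeTrace:
    rng = np.random.default_rng(seed)
    ts, xs, ys = [], [], []
    t = start_ms
    for cx, cy, dur in fixations:
        tt = _sample_times(t, dur, params.rate_hz)
        ts.append(tt)
        xs.append(np.full(tt.size, cx))
        ys.append(np.full(tt.size, cy))
        t = tt[-1] + 1000.0 / params.rate_hz if tt.size else t
    t_ms = np.concatenate(ts)
    x = np.concatenate(xs)
    y = np.concatenate(ys)
    noise_px = params.noise_sd_deg * display.px_per_deg_mean
    if noise_px > 0:
        x = x + rng.normal(0.0, noise_px, x.size)
        y = y + rng.normal(0.0, noise_px, y.size)
    return GazeTrace(t_ms, x, y, np.ones(t_ms.size, dtype=bool))


def simulate_trial_gaze(
    layout: "list[tuple[float, float, float]]",
    params: GazeParams = GazeParams(),
    engine: EngineParams = EngineParams(),
    display: DisplayModel | None = None,
    seed: int = 0,
    start_ms: float = 0.0,
) -> GazeTrace:
    """Full-trial scanpath: engage the central dot, read the three
    lines, then dwell on the top-center advance dot."""
    display = display or DisplayModel()
    sx, sy = start_dot_px(display)
    ax, ay = advance_dot_px(display)
    margin_ms = 4000.0 / params.rate_hz + 100.0  # cover dwell detection slack
    fixations = [(sx, sy, engine.pre_stimulus_ms + margin_ms)]
    for x0, x1, y in layout:
        for i in range(params.fixations_per_line):
            cx = x0 + (i + 0.5) * (x1 - x0) / params.fixations_per_line
            fixations.append((cx, y, params.fixation_ms))
    fixations.append((ax, ay, engine.dwell_ms + margin_ms))
    return _fixation_trace(fixations, params, display, seed, start_ms)


def fill_gaps(trace: GazeTrace, max_interp_gap_ms: float = 100.0) -> GazeTrace:
    """Repair invalid samples the way a streaming gaze server degrades.

    Interior gaps shorter than ``max_interp_gap_ms`` are linearly
    interpolated between the surrounding valid samples; longer interior
    gaps and trailing gaps repeat the last valid sample; leading gaps
    repeat the first valid sample.
    """
    valid = trace.valid.astype(bool)
    if not valid.any():
        raise ValueError("trace contains no valid samples")
    if valid.all():
        return replace(trace)
    t = trace.t_ms
    x = trace.x_px.copy()
    y = trace.y_px.copy()
    idx = np.flatnonzero(valid)
    # leading / trailing extension
    x[: idx[0]] = x[idx[0]]
    y[: idx[0]] = y[idx[0]]
    x[idx[-1] + 1 :] = x[idx[-1]]
    y[idx[-1] + 1 :] = y[idx[-1]]
    # interior gaps
    for a, b in zip(idx[:-1], idx[1:]):
        if b - a <= 1:
            continue
        gap_ms = t[b] - t[a]
        sl = slice(a + 1, b)
        if gap_ms <= max_interp_gap_ms:
            frac = (t[sl] - t[a]) / (t[b] - t[a])
            x[sl] = x[a] + frac * (x[b] - x[a])
            y[sl] = y[a] + frac * (y[b] - y[a])
        else:
            x[sl] = x[a]
            y[sl] = y[a]
    return GazeTrace(t.copy(), x, y, np.ones_like(valid))


def run_trial(
    spec: TrialSpec,
    sentence: SentenceStimulus,
    stimulus: np.ndarray,
    pattern: "PhosphenePattern | None",
    trace: GazeTrace,
    display: DisplayModel | None = None,
    engine: EngineParams = EngineParams(),
    frame_sink=None,
) -> TrialRecord:
    """Advance the four-phase state machine over a gaze trace.

    Start waits for gaze within tolerance of the central dot;
    Pre-Stimulus requires that fixation to be held continuously;
    Reading shows the sentence (rendering gaze-contingent frames
    through ``pattern`` for simulation trials, at the display refresh
    cadence) until a continuous 350 ms dwell on the top-center dot;
    the dwell time belongs to the End trigger, so ``t_reading`` runs
    from stimulus onset to dwell onset.  ``frame_sink(t_ms, frame)``
    receives rendered frames when given.  If the trace ends before the
    End trigger the record is marked incomplete.
    """
    display = display or DisplayModel()
    trace = fill_gaps(trace)
    tol_px = engine.fixation_tolerance_deg * display.px_per_deg_mean
    sx, sy = start_dot_px(display)
    ax, ay = advance_dot_px(display)

    render = spec.is_simulation and pattern is not None
    frame_step_ms = 1000.0 / engine.render_hz
    next_render_ms = -math.inf
    n_frames = 0

    phase = "start"
    hold_t0 = math.nan
    reading_on = math.nan
    dwell_t0 = math.nan
    end_ms = math.nan
    t_reading_ms = math.nan

    for i in range(len(trace)):
        t = trace.t_ms[i]
        gx, gy = trace.x_px[i], trace.y_px[i]
        if phase == "start":
            if math.hypot(gx - sx, gy - sy) <= tol_px:
                phase = "prestim"
                hold_t0 = t
        elif phase == "prestim":
            if math.hypot(gx - sx, gy - sy) > tol_px:
                phase = "start"
            elif t - hold_t0 >= engine.pre_stimulus_ms:
                phase = "reading"
                reading_on = t
                next_render_ms = t
        if phase == "reading":
            if render and t >= next_render_ms:
                frame = render_frame(stimulus, pattern, (gx, gy), display)
                n_frames += 1
                next_render_ms += frame_step_ms
                if frame_sink is not None:
                    frame_sink(t, frame)
            if math.hypot(gx - ax, gy - ay) <= tol_px:
                if math.isnan(dwell_t0):
                    dwell_t0 = t
                elif t - dwell_t0 >= engine.dwell_ms:
                    phase = "end"
                    t_reading_ms = dwell_t0 - reading_on
                    end_ms = t + engine.intertrial_ms
                    break
            else:
                dwell_t0 = math.nan

    complete = phase == "end"
    return TrialRecord(
        spec=spec,
        n_words=sentence.n_words,
        t_reading_s=t_reading_ms / 1000.0 if complete else math.nan,
        complete=complete,
        t_start_ms=float(trace.t_ms[0]),
        t_reading_on_ms=reading_on,
        t_end_ms=end_ms,
        n_frames_rendered=n_frames,
        gaze=trace,
    )


@dataclass(frozen=True)
class SyntheticReader:
    """Scripted observer supplying word-level reading errors.

    The engine does not recognize speech; for synthetic sessions the
    number of misread words is drawn from a binomial whose per-word
    success follows a logistic psychometric curve in letter size, with
    a 50% point per viewing condition.  Defaults put the clear curve
    far below the tested range (error-free reading) and stagger the
    simulation curves by tier.
    """

    midpoints: dict = field(
        default_factory=lambda: {
            "clear": 0.2,
            "high": 1.07,
            "medium": 1.26,
            "low": 1.48,
        }
    )
    slope_per_logmar: float = 13.6  # logistic k; ~340%/logMAR peak slope
    seed: int = 0

    def errors(self, spec: TrialSpec, n_words: int) -> int:
        m = self.midpoints[spec.viewing_name]
        p_correct = 1.0 / (1.0 + math.exp(-self.slope_per_logmar * (spec.font_logmar - m)))
        rng = np.random.default_rng((self.seed, spec.index))
        return int(rng.binomial(n_words, 1.0 - p_correct))


def run_block(
    schedule: "list[TrialSpec]",
    sentences: dict,
    patterns: dict,
    display: DisplayModel | None = None,
    engine: EngineParams = EngineParams(),
    gaze_params: GazeParams = GazeParams(),
    reader: "SyntheticReader | None" = None,
    gaze_seed: int = 0,
    size_logmar_by_trial=None,
    stimulus_cache: "dict | None" = None,
    frame_sink=None,
    rasterize_kwargs: "dict | None" = None,
) -> list[TrialRecord]:
    """Run a whole synthetic session on the simulated clock.

    ``sentences`` maps sentence_id to :class:`SentenceStimulus`;
    ``patterns`` maps tier name to :class:`PhosphenePattern`.  Gaze for
    each trial is a fresh synthetic scanpath (seeded per trial from
    ``gaze_seed``); trial starts are spaced by the previous trial's end
    plus the intertrial pause.
    """
    from .stimuli import rasterize_sentence, sentence_layout

    display = display or DisplayModel()
    rkw = rasterize_kwargs or {}
    records = []
    t0 = 0.0
    for spec in schedule:
        sentence = sentences[spec.sentence_id]
        stim_key = (spec.sentence_id, spec.font_logmar)
        if stimulus_cache is not None and stim_key in stimulus_cache:
            stimulus = stimulus_cache[stim_key]
        else:
            stimulus = rasterize_sentence(sentence, spec.font_logmar, display, **rkw)
            if stimulus_cache is not None:
                stimulus_cache[stim_key] = stimulus
        layout = sentence_layout(sentence, spec.font_logmar, display, **rkw)
        trace = simulate_trial_gaze(
            layout,
            gaze_params,
            engine,
            display,
            seed=(gaze_seed * 100003 + spec.index) % 2**31,
            start_ms=t0,
        )
        pattern = patterns.get(spec.viewing_name) if spec.is_simulation else None
        rec = run_trial(
            spec, sentence, stimulus, pattern, trace, display, engine, frame_sink
        )
        if reader is not None and rec.complete:
            rec.errors = reader.errors(spec, rec.n_words)
        records.append(rec)
        t0 = rec.t_end_ms if rec.complete else trace.t_ms[-1] + engine.intertrial_ms
    return records


def records_to_log(records: "list[TrialRecord]", gaze_seed: int = 0) -> pd.DataFrame:
    """Flatten trial records into the trial-log table."""
    rows = []
    for r in records:
        rows.append(
            {
                "trial": r.spec.index,
                "font_condition": r.spec.font_condition,
                "font_logmar": r.spec.font_logmar,
                "viewing_condition": r.spec.viewing_condition,
                "viewing_name": r.spec.viewing_name,
                "sentence_id": r.spec.sentence_id,
                "repetition": r.spec.repetition,
                "n_words": r.n_words,
                "errors": r.errors,
                "t_reading_s": r.t_reading_s,
                "complete": r.complete,
                "seed": gaze_seed,
            }
        )
    return pd.DataFrame(rows)
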