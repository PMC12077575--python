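"""Epoch schedules, session state, and real-time performance monitors.

An experiment is a contiguous sequence of timed epochs — baseline, rest,
regulation, break — each tagged with an integer marker ID (1 = baseline
or break, 2 = rest, 3 = regulation), a feedback-visibility flag and a
background color.  The two monitors track whether the engine keeps up
with the stream: the *delay* monitor compares acquired frames against the
number expected from elapsed time, and the *protocol-time* monitor checks
that mean per-window processing time stays under one sample period.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

from .errors import InvalidScheduleError

MARKER_BASELINE = 1  # also breaks between runs
MARKER_REST = 2
MARKER_REGULATION = 3

#: default background colors per marker ID
MARKER_COLORS = {
    MARKER_BASELINE: "#000000",  # black
    MARKER_REST: "#0000FF",      # blue
    MARKER_REGULATION: "#00FF00",  # green
}

#: delay above this many seconds is unacceptable (strict inequality)
DELAY_LIMIT_S = 1.0


@dataclass(frozen=True)
class Epoch:
    start_s: float
    end_s: float
    marker_id: int
    feedback_visible: bool = False
    background_color: str = "#000000"

    @property
    def duration_s(self) -> float:
        return self.end_s - self.start_s

    def contains(self, t: float) -> bool:
        """Half-open convention: [start_s, end_s)."""
        return self.start_s <= t < self.end_s


@dataclass(frozen=True)
class Schedule:
    epochs: tuple[Epoch, ...]

    @property
    def total_s(self) -> float:
        return self.epochs[-1].end_s if self.epochs else 0.0

    def marker_count(self, marker_id: int) -> int:
        return sum(1 for e in self.epochs if e.marker_id == marker_id)


def build_example_schedule(
    baseline_s: float = 5.0,
    phase_s: float = 30.0,
    trials_per_run: Sequence[int] = (5, 6, 6, 6, 5),
    break_s: float = 30.0,
    feedback_runs: Sequence[int] = (2, 3, 4),
) -> Schedule:
    """Build the block-design example session.

    One initial baseline epoch (marker 1) of ``baseline_s`` lets the first
    sliding window fill before any computation.  Each run then alternates
    ``phase_s`` rest (marker 2) and regulation (marker 3) epochs — every
    regulation preceded by its rest, so a trailing rest baseline always
    exists — and consecutive runs are separated by one ``break_s`` break
    epoch (marker 1).  Feedback is visible only in ``feedback_runs``
    (1-based run numbers; runs 1 and 5 are no-feedback transfer runs by
    default).  With the defaults this yields 61 epochs: 1 baseline +
    2 × (5+6+6+6+5) rest/regulation epochs + 4 breaks.
    """
    if not trials_per_run:
        raise InvalidScheduleError("trials_per_run must be non-empty")
    if baseline_s <= 0 or phase_s <= 0 or break_s <= 0:
        raise InvalidScheduleError("all durations must be positive")
    feedback_runs = set(feedback_runs)

    epochs: list[Epoch] = []
    t = 0.0

    def add(duration: float, marker: int, visible: bool) -> None:
        nonlocal t
        epochs.append(
            Epoch(
                start_s=t,
                end_s=t + duration,
                marker_id=marker,
                feedback_visible=visible,
                background_color=MARKER_COLORS[marker],
            )
        )
        t += duration

    add(baseline_s, MARKER_BASELINE, False)
    for run_no, n_trials in enumerate(trials_per_run, start=1):
        if n_trials < 1:
            raise InvalidScheduleError("each run needs at least one trial")
        visible = run_no in feedback_runs
        for _ in range(n_trials):
            add(phase_s, MARKER_REST, visible)
            add(phase_s, MARKER_REGULATION, visible)
        if run_no < len(trials_per_run):
            add(break_s, MARKER_BASELINE, False)
    return Schedule(tuple(epochs))


def validate_schedule(schedule: Schedule) -> list[str]:
    """Return all structural violations (empty list means ok).

    Checks contiguity (each epoch starts at the previous end), positive
    durations, a zero start, and known marker IDs.
    """
    violations: list[str] = []
    eps = schedule.epochs
    if not eps:
        return ["schedule has no epochs"]
    if eps[0].start_s != 0:
        violations.append(f"epoch 1 starts at {eps[0].start_s} s, expected 0")
    for i, e in enumerate(eps, start=1):
        if e.end_s <= e.start_s:
            violations.append(
                f"epoch {i}: non-positive duration ({e.start_s}..{e.end_s} s)"
            )
        if e.marker_id not in MARKER_COLORS:
            violations.append(f"epoch {i}: unknown marker ID {e.marker_id}")
    for i in range(1, len(eps)):
        if not math.isclose(eps[i].start_s, eps[i - 1].end_s, abs_tol=1e-9):
            violations.append(
                f"contiguity break between epochs {i} and {i + 1}: "
                f"{eps[i - 1].end_s} s != {eps[i].start_s} s"
            )
    return violations


def epoch_at(schedule: Schedule, t: float) -> Epoch | None:
    """Epoch whose half-open interval [start, end) contains t, or None
    once t is at/after the end of the session (session complete)."""
    if t < 0:
        raise ValueError("t must be non-negative")
    for e in schedule.epochs:
        if e.contains(t):
            return e
    return None


def previous_epoch(schedule: Schedule, marker_id: int, t: float) -> Epoch | None:
    """Most recent fully-elapsed epoch with the given marker before t."""
    best = None
    for e in schedule.epochs:
        if e.marker_id == marker_id and e.end_s <= t:
            best = e
    return best


@dataclass
class SessionState:
    """Mutable per-session bookkeeping for the monitors."""

    fs: float
    status: str = "stopped"  # stopped | started | ended
    acquired_samples: int = 0
    expected_samples: int = 0
    lost_frames: int = 0
    delay_s: float = 0.0
    started_at: float | None = None
    ended_at: float | None = None
    duration_s: float = 0.0


@dataclass(frozen=True)
class MonitorReading:
    value: float
    status: str  # ok | exceeded
    max_value: float | None = None


def update_delay(state: SessionState, elapsed_s: float, fs: float) -> MonitorReading:
    """Recompute the stream-delay monitor.

    expected = floor(elapsed * fs); lost = expected - acquired;
    delay = lost / fs (the difference between expected and actual time).
    The reading is *exceeded* only when delay is strictly greater than
    1 s.
    """
    if fs <= 0:
        raise ValueError("fs must be positive")
    if elapsed_s < 0:
        raise ValueError("elapsed_s must be non-negative")
    state.expected_samples = int(math.floor(elapsed_s * fs))
    state.lost_frames = state.expected_samples - state.acquired_samples
    state.delay_s = state.lost_frames / fs
    state.duration_s = elapsed_s
    status = "exceeded" if state.delay_s > DELAY_LIMIT_S else "ok"
    return MonitorReading(value=state.delay_s, status=status)


def update_protocol_time(exec_times_s: Sequence[float], fs: float) -> MonitorReading:
    """Recompute the protocol-execution-time monitor.

    Reports mean and max per-window processing time; processing keeps up
    with the stream only while the mean stays at or below one sample
    period (1/fs), so *exceeded* triggers when mean > 1/fs.
    """
    if fs <= 0:
        raise ValueError("fs must be positive")
    if not exec_times_s:
        return MonitorReading(value=0.0, status="ok", max_value=0.0)
    mean = float(sum(exec_times_s) / len(exec_times_s))
    status = "exceeded" if mean > 1.0 / fs else "ok"
    return MonitorReading(value=mean, status=status, max_value=float(max(exec_times_s)))
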