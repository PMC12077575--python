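"""Rest-baseline normalization and the thermometer feedback mapping.

The feedback shown to the participant is the deviation of the current
regulation-phase HbO mean from a rest baseline, scaled by a
participant-specific correction factor and mapped affinely onto a 10-bar
thermometer:

* **Rest profile** — from the filtered across-channel HbO average over
  the last 15 s of the first rest phase, sorted ascending: drop the 10
  highest and 10 lowest values, then take the absolute difference between
  the mean of the 25 highest and the mean of the 25 lowest of the
  remainder.  That trimmed spread is the individual rest amplitude, and

      correction_factor = expected_amplitude / amplitude_rest

  normalizes feedback gain across participants and brain regions.

* **Feedback** — for every window i in a regulation phase,

      feedback_i = (meanHbOreg_i − meanHbOrest) × correction_factor

  where meanHbOrest is the trailing 5-s average of the preceding rest
  phase.

* **Thermometer** — the expected HbO range [−0.4, 0.4] μmol/L is scaled
  onto the thermometer range [0, 1]:

      r = (feedback − hbo_min) · (thermo_max − thermo_min)
          / (hbo_max − hbo_min) + thermo_min

  so zero deviation always sits at the midline (r = 0.5).  r is clipped
  into the thermometer range; the display divides it into 0.1-unit bars
  counted by their lower edge (r = 0.8 fills 9 of 10 bars).

The printed trim counts (drop 10, average 25 per tail) assume ~150 rest
samples (15 s at ~10 Hz); for other sample counts they scale
proportionally with a floor of one sample per tail.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np

from .errors import InsufficientDataError

logger = logging.getLogger(__name__)

#: guard against division by zero for flat rest windows (μmol/L)
AMPLITUDE_EPS = 1e-6

#: nominal rest-sample count the printed trim counts (10/25) refer to
_NOMINAL_REST_SAMPLES = 150


@dataclass(frozen=True)
class FeedbackSettings:
    """Feedback computation parameters, defaults as used in the reference
    protocol: expected amplitude 0.1 μmol/L, HbO range [−0.4, 0.4],
    thermometer range [0, 1] in 10 bars."""

    expected_amplitude: float = 0.1
    hbo_min: float = -0.4
    hbo_max: float = 0.4
    thermo_min: float = 0.0
    thermo_max: float = 1.0
    n_bars: int = 10
    rest_extract_s: float = 15.0
    rest_baseline_s: float = 5.0
    trim_drop: int = 10
    trim_mean_n: int = 25

    def __post_init__(self):
        if self.hbo_min >= self.hbo_max:
            raise ValueError("hbo_min must be < hbo_max")
        if self.thermo_min >= self.thermo_max:
            raise ValueError("thermo_min must be < thermo_max")
        if self.n_bars < 1:
            raise ValueError("n_bars must be >= 1")
        if self.rest_baseline_s > self.rest_extract_s:
            raise ValueError("rest_baseline_s must be <= rest_extract_s")
        if min(self.trim_drop, self.trim_mean_n) < 1:
            raise ValueError("trim counts must be >= 1")


@dataclass(frozen=True)
class RestProfile:
    """Individually normalized rest baseline for one session."""

    mean_rest_series: np.ndarray = field(repr=False)
    amplitude_rest: float
    correction_factor: float
    rest_baseline: float


@dataclass(frozen=True)
class FeedbackSample:
    """One emitted feedback value."""

    feedback: float  # corrected deviation, μmol/L scale (NaN during rest)
    thermometer: float  # r, clipped into the thermometer range
    bars_filled: int
    marker_id: int
    timestamp: float


def _scaled_trim_counts(n: int, settings: FeedbackSettings) -> tuple[int, int]:
    """Scale the printed trim counts to the available sample count."""
    drop = max(1, round(settings.trim_drop * n / _NOMINAL_REST_SAMPLES))
    mean_n = max(1, round(settings.trim_mean_n * n / _NOMINAL_REST_SAMPLES))
    while 2 * (drop + mean_n) > n and (drop > 1 or mean_n > 1):
        if drop > 1:
            drop -= 1
        elif mean_n > 1:
            mean_n -= 1
    return drop, mean_n


def compute_rest_profile(
    rest_series: np.ndarray,
    settings: FeedbackSettings = FeedbackSettings(),
    rest_baseline: float | None = None,
) -> RestProfile:
    """Extract the rest amplitude and correction factor from the filtered
    mean-NF-channel samples of the last ``rest_extract_s`` of the first
    rest phase.

    The series is sorted ascending; ``trim_drop`` extremes are dropped
    per tail; the rest amplitude is |mean(top trim_mean_n) − mean(bottom
    trim_mean_n)| of the remainder, and the correction factor divides the
    expected amplitude by it.  Degenerate (near-constant) rest windows
    cap the correction factor at expected_amplitude / 1e-6 with a logged
    warning rather than dividing by zero.
    """
    series = np.asarray(rest_series, dtype=float).ravel()
    n = series.size
    drop, mean_n = _scaled_trim_counts(n, settings)
    if n < 2 * (drop + mean_n):
        raise InsufficientDataError(
            f"rest series has {n} samples; need at least {2 * (drop + mean_n)}"
        )
    ordered = np.sort(series, kind="stable")
    trimmed = ordered[drop : n - drop]
    amplitude = abs(float(np.mean(trimmed[-mean_n:]) - np.mean(trimmed[:mean_n])))
    if amplitude < AMPLITUDE_EPS:
        logger.warning(
            "rest amplitude %.3g below guard epsilon; capping correction factor",
            amplitude,
        )
        amplitude = AMPLITUDE_EPS
    cf = settings.expected_amplitude / amplitude
    if rest_baseline is None:
        rest_baseline = trailing_rest_baseline(series, settings, fs=None)
    return RestProfile(
        mean_rest_series=series,
        amplitude_rest=amplitude,
        correction_factor=cf,
        rest_baseline=float(rest_baseline),
    )


def trailing_rest_baseline(
    previous_rest_series: np.ndarray,
    settings: FeedbackSettings = FeedbackSettings(),
    fs: float | None = None,
) -> float:
    """Trailing ``rest_baseline_s`` mean of the filtered mean-NF series of
    the rest phase preceding the current regulation phase.

    With ``fs`` given, the window is ``round(rest_baseline_s * fs)``
    samples; without it, the proportional tail of the series is used.
    A rest shorter than the baseline window falls back to the full rest
    with a warning.
    """
    series = np.asarray(previous_rest_series, dtype=float).ravel()
    if series.size == 0:
        raise InsufficientDataError("previous rest series is empty")
    if fs is not None:
        n_tail = int(round(settings.rest_baseline_s * fs))
    else:
        frac = settings.rest_baseline_s / settings.rest_extract_s
        n_tail = max(1, int(round(series.size * frac)))
    if n_tail > series.size:
        warnings.warn(
            f"rest phase shorter than {settings.rest_baseline_s} s baseline "
            "window; using the full rest",
            stacklevel=2,
        )
        n_tail = series.size
    return float(np.mean(series[-n_tail:]))


def compute_feedback(
    mean_hbo_reg_i: float, rest_baseline: float, correction_factor: float
) -> float:
    """feedback_i = (meanHbOreg_i − meanHbOrest) × correction_factor."""
    return (mean_hbo_reg_i - rest_baseline) * correction_factor


def thermometer_value(
    feedback: float, settings: FeedbackSettings = FeedbackSettings()
) -> float:
    """Affine map of the expected HbO range onto the thermometer range,
    clipped into [thermo_min, thermo_max]."""
    r = (feedback - settings.hbo_min) * (
        settings.thermo_max - settings.thermo_min
    ) / (settings.hbo_max - settings.hbo_min) + settings.thermo_min
    return float(np.clip(r, settings.thermo_min, settings.thermo_max))


def bars_filled(r: float, settings: FeedbackSettings = FeedbackSettings()) -> int:
    """Count of filled bars: bars whose lower-edge level (thermo_min,
    thermo_min + step, ...) is ≤ r, capped at n_bars.

    With the default 10-bar [0, 1] display, r = 0.8 fills 9 bars.  A
    small tolerance absorbs floating-point slop on exact bar edges.
    """
    if not settings.thermo_min <= r <= settings.thermo_max + 1e-12:
        raise ValueError(
            f"r={r} outside thermometer range "
            f"[{settings.thermo_min}, {settings.thermo_max}]"
        )
    step = (settings.thermo_max - settings.thermo_min) / settings.n_bars
    count = 0
    for k in range(settings.n_bars):
        if settings.thermo_min + k * step <= r + 1e-9:
            count += 1
    return count


def midline(settings: FeedbackSettings = FeedbackSettings()) -> float:
    """Thermometer value of zero deviation (a half-filled display)."""
    return thermometer_value(0.0, settings)
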