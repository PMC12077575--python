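"""Causal per-window preprocessing and the protocol lifecycle.

Every real-time protocol implements four functions — ``requires`` /
``init`` / ``process`` / ``finish`` — and all filtering must be causal:
the output at time t may depend only on samples at or before t, because
future samples have not been measured yet.

The reference protocol (``MovAvg_SS``) processes oxygenated-hemoglobin
(HbO) windows in a fixed stage order: short-separation regression to
remove systemic physiology, then a causal moving average to smooth
short-term fluctuations, then averaging across the selected
neurofeedback channels into a single per-window value that the feedback
engine turns into a thermometer reading.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

from .device_config import DeviceDescriptor
from .errors import InsufficientDataError, ParameterError, RequirementError
from .feedback_engine import (
    FeedbackSample,
    FeedbackSettings,
    RestProfile,
    bars_filled,
    compute_feedback,
    compute_rest_profile,
    midline,
    thermometer_value,
    trailing_rest_baseline,
)
from .protocol_session import (
    MARKER_REGULATION,
    MARKER_REST,
    Schedule,
    epoch_at,
)
from .streaming import SlidingWindowView

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Causal filters
# ---------------------------------------------------------------------------

def moving_average(series: np.ndarray, width_s: float, fs: float) -> np.ndarray:
    """Causal trailing mean: out[t] = mean(series[t-w+1 .. t]) with
    w = round(width_s * fs); early samples average the available prefix.
    """
    if width_s <= 0 or fs <= 0:
        raise ParameterError("width_s and fs must be positive")
    x = np.asarray(series, dtype=float)
    w = max(1, int(round(width_s * fs)))
    csum = np.cumsum(x, axis=0)
    out = np.empty_like(x, dtype=float)
    n = x.shape[0]
    for t in range(n):
        lo = max(0, t - w + 1)
        total = csum[t] - (csum[lo - 1] if lo > 0 else 0)
        out[t] = total / (t - lo + 1)
    return out


def gauss_lowpass(series: np.ndarray, sigma_s: float, fs: float) -> np.ndarray:
    """Causal convolution with a truncated one-sided Gaussian kernel.

    The kernel spans lags 0..4σ and is renormalized to unit sum over the
    available history, so constants pass with unit DC gain from the very
    first sample.
    """
    if sigma_s <= 0 or fs <= 0:
        raise ParameterError("sigma_s and fs must be positive")
    x = np.asarray(series, dtype=float)
    sigma = sigma_s * fs
    lags = np.arange(int(np.ceil(4 * sigma)) + 1)
    kernel = np.exp(-0.5 * (lags / sigma) ** 2)
    out = np.empty_like(x, dtype=float)
    for t in range(x.shape[0]):
        k = kernel[: t + 1]
        out[t] = np.dot(k, x[t::-1][: k.size]) / k.sum()
    return out


def bandpass_causal(
    series: np.ndarray,
    low_hz: float,
    high_hz: float,
    order: int = 2,
    fs: float = 10.17,
) -> np.ndarray:
    """Forward-only (causal) Butterworth band-pass.

    Provided as an optional stage; the reference protocol's defaults do
    not use it.
    """
    if not 0 < low_hz < high_hz < fs / 2:
        raise ParameterError(
            f"band edges must satisfy 0 < {low_hz} < {high_hz} < fs/2={fs / 2}"
        )
    sos = sps.butter(order, [low_hz, high_hz], btype="bandpass", fs=fs, output="sos")
    return sps.sosfilt(sos, np.asarray(series, dtype=float), axis=0)


def ss_regress(long_window: np.ndarray, ss_window: np.ndarray) -> np.ndarray:
    """Remove the systemic component from long-separation channels by
    ordinary least squares onto the mean short-separation channel.

    Per long channel the window is regressed onto [intercept, mean SS];
    the returned window is residual + intercept, so the systemic
    component is removed while the signal level (μmol/L scale) is
    preserved.  Zero-variance SS windows skip the correction with a
    logged warning (slope forced to 0).
    """
    long_w = np.atleast_2d(np.asarray(long_window, dtype=float))
    if long_w.shape[0] == 1 and np.asarray(long_window).ndim == 1:
        long_w = long_w.T
    ss_w = np.atleast_2d(np.asarray(ss_window, dtype=float))
    if ss_w.shape[0] == 1 and np.asarray(ss_window).ndim == 1:
        ss_w = ss_w.T
    n = long_w.shape[0]
    if n < 3 or ss_w.shape[0] != n:
        raise InsufficientDataError(
            "regression windows must be time-aligned with at least 3 rows"
        )
    x = ss_w.mean(axis=1)
    xc = x - x.mean()
    denom = float(np.dot(xc, xc))
    if denom < 1e-15:
        logger.warning("degenerate SS window (zero variance); correction skipped")
        return long_w.copy()
    slopes = (xc @ (long_w - long_w.mean(axis=0))) / denom
    # residual + intercept  ==  long - slope * x
    return long_w - np.outer(x, slopes)


# ---------------------------------------------------------------------------
# Protocol lifecycle
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ProtocolSpec:
    name: str
    modality_required: str = "NIRS"
    min_nf_channels: int = 1
    min_ss_channels: int = 1
    required_signal: str = "hbo"
    required_unit: str = "μmol/L"
    window_min_s: float = 2.0
    window_max_s: float = 30.0

    def __post_init__(self):
        if self.window_min_s > self.window_max_s:
            raise ParameterError("window_min_s must be <= window_max_s")


#: the reference moving-average + short-separation-regression protocol
MOVAVG_SS = ProtocolSpec(name="MovAvg_SS")

PROTOCOLS: dict[str, ProtocolSpec] = {MOVAVG_SS.name: MOVAVG_SS}


@dataclass(frozen=True)
class ChannelSelection:
    """Channels used for neurofeedback vs short-separation regression
    (1-based IDs, disjoint)."""

    nf_channels: tuple[int, ...]
    ss_channels: tuple[int, ...]

    def __post_init__(self):
        object.__setattr__(self, "nf_channels", tuple(self.nf_channels))
        object.__setattr__(self, "ss_channels", tuple(self.ss_channels))


def requires(
    spec: ProtocolSpec,
    selection: ChannelSelection,
    descriptor: DeviceDescriptor,
    window_s: float,
) -> list[str]:
    """Check protocol requirements; returns the violation list (empty
    means ok): modality, minimum NF/SS channel counts, disjointness,
    signal unit, and window size within the supported range."""
    v: list[str] = []
    if descriptor.modality != spec.modality_required:
        v.append(
            f"protocol requires {spec.modality_required} data, "
            f"device is {descriptor.modality}"
        )
    if len(selection.nf_channels) < spec.min_nf_channels:
        v.append(
            f"at least {spec.min_nf_channels} NF channel(s) required, "
            f"got {len(selection.nf_channels)}"
        )
    if len(selection.ss_channels) < spec.min_ss_channels:
        v.append(
            f"at least {spec.min_ss_channels} short-separation channel(s) "
            f"required, got {len(selection.ss_channels)}"
        )
    overlap = set(selection.nf_channels) & set(selection.ss_channels)
    if overlap:
        v.append(f"NF and SS selections overlap: {sorted(overlap)}")
    for cid in (*selection.nf_channels, *selection.ss_channels):
        if not 1 <= cid <= descriptor.n_channels:
            v.append(f"channel {cid} outside 1..{descriptor.n_channels}")
    if descriptor.modality == spec.modality_required == "NIRS":
        try:
            cols = descriptor.resolve_columns(
                spec.required_signal, selection.nf_channels or None
            )
            units = {descriptor.column_map[c - 1].unit for c in cols}
            if units and units != {spec.required_unit}:
                v.append(
                    f"{spec.required_signal} unit must be "
                    f"{spec.required_unit!r}, descriptor has {sorted(units)}"
                )
        except Exception as e:
            v.append(str(e))
    if not spec.window_min_s <= window_s <= spec.window_max_s:
        v.append(
            f"window {window_s} s outside supported range "
            f"[{spec.window_min_s}, {spec.window_max_s}] s"
        )
    return v


@dataclass
class PipelineState:
    """Mutable per-session pipeline state.

    Output at window k depends only on frames up to window k: the state
    holds only past per-window outputs, the rest profile once extracted,
    and the execution-time log.
    """

    spec: ProtocolSpec
    descriptor: DeviceDescriptor
    selection: ChannelSelection
    schedule: Schedule
    window_s: float
    fs: float
    feedback_settings: FeedbackSettings
    smoothing_width_s: float
    nf_cols: np.ndarray = field(repr=False, default=None)
    ss_cols: np.ndarray = field(repr=False, default=None)
    out_t: list[float] = field(default_factory=list, repr=False)
    out_mean: list[float] = field(default_factory=list, repr=False)
    out_marker: list[int] = field(default_factory=list, repr=False)
    rest_profile: RestProfile | None = None
    rest_baseline: float | None = None
    _baseline_epoch_start: float | None = None
    exec_times_s: list[float] = field(default_factory=list, repr=False)


def init(
    spec: ProtocolSpec,
    descriptor: DeviceDescriptor,
    selection: ChannelSelection,
    schedule: Schedule,
    window_s: float,
    fs: float,
    feedback_settings: FeedbackSettings | None = None,
    smoothing_width_s: float | None = None,
) -> PipelineState:
    """Initialize the pipeline for a session.

    Filter memories are empty, the rest profile absent, the execution log
    empty; a failing :func:`requires` check refuses initialization with
    the violation list.  The moving-average width defaults to the full
    sliding window.
    """
    violations = requires(spec, selection, descriptor, window_s)
    if violations:
        raise RequirementError(violations)
    nf_cols = np.array(
        descriptor.resolve_columns(spec.required_signal, selection.nf_channels)
    ) - 1
    ss_cols = np.array(
        descriptor.resolve_columns(spec.required_signal, selection.ss_channels)
    ) - 1
    return PipelineState(
        spec=spec,
        descriptor=descriptor,
        selection=selection,
        schedule=schedule,
        window_s=window_s,
        fs=fs,
        feedback_settings=feedback_settings or FeedbackSettings(),
        smoothing_width_s=(
            window_s if smoothing_width_s is None else smoothing_width_s
        ),
        nf_cols=nf_cols,
        ss_cols=ss_cols,
    )


def _rest_series_between(
    state: PipelineState, start_s: float, end_s: float
) -> np.ndarray:
    t = np.asarray(state.out_t)
    m = np.asarray(state.out_marker)
    vals = np.asarray(state.out_mean)
    sel = (t >= start_s) & (t < end_s) & (m == MARKER_REST)
    return vals[sel]


def _ensure_rest_profile(state: PipelineState, t: float) -> None:
    """Extract the rest profile once, from the last ``rest_extract_s`` of
    the first rest phase, as soon as a regulation phase begins."""
    if state.rest_profile is not None:
        return
    first_rest = next(
        (e for e in state.schedule.epochs if e.marker_id == MARKER_REST), None
    )
    if first_rest is None or t < first_rest.end_s:
        return
    fs_settings = state.feedback_settings
    series = _rest_series_between(
        state, first_rest.end_s - fs_settings.rest_extract_s, first_rest.end_s
    )
    if series.size == 0:
        return
    try:
        state.rest_profile = compute_rest_profile(series, fs_settings)
    except InsufficientDataError:
        logger.warning("too few rest samples for the rest profile; waiting")


def _refresh_rest_baseline(state: PipelineState, epoch_start: float) -> None:
    """Refresh the 5-s rest baseline at each regulation-phase onset from
    the immediately preceding rest epoch."""
    if state._baseline_epoch_start == epoch_start:
        return
    prev_rest = None
    for e in state.schedule.epochs:
        if e.marker_id == MARKER_REST and e.end_s <= epoch_start + 1e-9:
            prev_rest = e
    if prev_rest is None:
        return
    series = _rest_series_between(state, prev_rest.start_s, prev_rest.end_s)
    if series.size == 0:
        return
    state.rest_baseline = trailing_rest_baseline(
        series, state.feedback_settings, fs=state.fs
    )
    state._baseline_epoch_start = epoch_start


def process_window(
    state: PipelineState, window: SlidingWindowView | None, t: float
) -> FeedbackSample | None:
    """Process one sliding window at session time t.

    Stage order: short-separation regression → causal moving average →
    across-NF-channel mean, giving the per-window HbO value meanHbOreg_i.
    The schedule decides what happens with it: during regulation phases a
    :class:`FeedbackSample` is computed against the rest baseline; during
    rest phases the thermometer is pinned at the midline; during baseline
    and breaks (and while the first window is still filling) no feedback
    is emitted (returns None).
    """
    t0 = time.perf_counter()
    try:
        if window is None:  # first window not yet fully available
            return None
        epoch = epoch_at(state.schedule, t)
        if epoch is None:  # session complete
            return None

        long_w = window.samples[:, state.nf_cols]
        ss_w = window.samples[:, state.ss_cols]
        corrected = ss_regress(long_w, ss_w)
        channel_mean = corrected.mean(axis=1)
        smoothed = moving_average(channel_mean, state.smoothing_width_s, state.fs)
        value = float(smoothed[-1])

        state.out_t.append(t)
        state.out_mean.append(value)
        state.out_marker.append(epoch.marker_id)

        fb_settings = state.feedback_settings
        if epoch.marker_id == MARKER_REST:
            r = midline(fb_settings)
            return FeedbackSample(
                feedback=float("nan"),
                thermometer=r,
                bars_filled=bars_filled(r, fb_settings),
                marker_id=epoch.marker_id,
                timestamp=t,
            )
        if epoch.marker_id == MARKER_REGULATION:
            _ensure_rest_profile(state, t)
            _refresh_rest_baseline(state, epoch.start_s)
            if state.rest_profile is None or state.rest_baseline is None:
                return None
            fb = compute_feedback(
                value, state.rest_baseline, state.rest_profile.correction_factor
            )
            r = thermometer_value(fb, fb_settings)
            return FeedbackSample(
                feedback=fb,
                thermometer=r,
                bars_filled=bars_filled(r, fb_settings),
                marker_id=epoch.marker_id,
                timestamp=t,
            )
        return None  # baseline / break: no feedback
    finally:
        state.exec_times_s.append(time.perf_counter() - t0)


@dataclass(frozen=True)
class SessionSeries:
    """End-of-run summary: the three aligned series behind the output
    figure — mean NF-channel activity, feedback values, marker IDs."""

    t: np.ndarray
    mean_nf: np.ndarray
    feedback: np.ndarray
    marker: np.ndarray


def finish(state: PipelineState, feedback_series=None) -> SessionSeries:
    """End-of-session post-processing: emit the aligned summary series.

    ``feedback_series`` optionally supplies the per-window thermometer
    values recorded by the caller (NaN where no feedback was emitted);
    without it, the feedback column is NaN-filled.
    """
    n = len(state.out_t)
    if feedback_series is None:
        fb = np.full(n, np.nan)
    else:
        fb = np.asarray(feedback_series, dtype=float)
        if fb.shape[0] != n:
            raise ParameterError(
                f"feedback series length {fb.shape[0]} != output length {n}"
            )
    return SessionSeries(
        t=np.asarray(state.out_t, dtype=float),
        mean_nf=np.asarray(state.out_mean, dtype=float),
        feedback=fb,
        marker=np.asarray(state.out_marker, dtype=int),
    )
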