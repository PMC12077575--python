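"""End-to-end session orchestration over a transport.

Ties the modules together the way a live acquisition would: open the
stream, initialize the protocol pipeline, push frames, slide the window
by one per frame, emit markers on epoch changes, feed the feedback
samples into the session record, log the delay and protocol-time
monitors once per second, and finish with the summary series.  With the
simulated transport everything runs in accelerated time and is fully
deterministic for a given seed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .device_config import DeviceDescriptor
from .feedback_engine import FeedbackSettings
from .protocol_session import (
    SessionState,
    epoch_at,
    update_delay,
    update_protocol_time,
)
from .realtime_pipeline import (
    PROTOCOLS,
    ChannelSelection,
    SessionSeries,
    finish,
    init,
    process_window,
)
from .session_io import Settings, SessionRecord
from .simulator import SimulatedTransport, SimulationConfig
from .streaming import open_stream

logger = logging.getLogger(__name__)


@dataclass
class SessionResult:
    record: SessionRecord
    series: SessionSeries
    session_state: SessionState
    protocol_time: object = None  # final MonitorReading of the exec-time log


def default_selection(config: SimulationConfig, n_nf: int = 8) -> ChannelSelection:
    """Neurofeedback channels from the long-separation block, all short
    channels as regressors."""
    n_nf = min(n_nf, config.n_long)
    return ChannelSelection(
        nf_channels=tuple(config.long_ids[:n_nf]),
        ss_channels=tuple(config.short_ids),
    )


def run_simulated_session(
    config: SimulationConfig,
    descriptor: DeviceDescriptor,
    settings: Settings,
) -> SessionResult:
    """Run one full simulated session in accelerated time.

    Frames arriving during the optional quiet lead-in (emulating the
    acquisition software's internal baseline) are recorded but not
    processed; the protocol clock starts when the lead-in ends.
    """
    transport = SimulatedTransport(config)
    handle = open_stream(descriptor, transport, buffer_s=max(60.0, settings.window_s * 2))
    spec = PROTOCOLS[settings.protocol]
    selection = ChannelSelection(settings.nf_channels, settings.ss_channels)
    state = init(
        spec,
        descriptor,
        selection,
        settings.schedule,
        window_s=settings.window_s,
        fs=config.fs,
        feedback_settings=settings.feedback,
    )

    session = SessionState(fs=config.fs, status="started", started_at=0.0)
    thermo: list[float] = []
    markers: list[int] = []
    feedback_per_output: list[float] = []
    current_marker: int | None = None
    next_monitor_s = 1.0

    for frame in transport.frames(descriptor):
        handle.push_frame(frame)
        session.acquired_samples += 1
        t_sched = frame.timestamp - config.baseline_lead_in_s
        if t_sched < 0:  # quiet lead-in: record only
            thermo.append(float("nan"))
            markers.append(0)
            continue
        epoch = epoch_at(settings.schedule, t_sched)
        if epoch is None:
            thermo.append(float("nan"))
            markers.append(0)
            continue
        if epoch.marker_id != current_marker:
            handle.send_marker(epoch.marker_id, frame.timestamp)
            current_marker = epoch.marker_id
        window = handle.latest_window(settings.window_s)
        sample = process_window(state, window, t_sched)
        if window is not None and epoch is not None:
            feedback_per_output.append(
                sample.thermometer if sample is not None else float("nan")
            )
        thermo.append(sample.thermometer if sample is not None else float("nan"))
        markers.append(epoch.marker_id)

        if frame.timestamp >= next_monitor_s:
            delay = update_delay(session, frame.timestamp, config.fs)
            ptime = update_protocol_time(state.exec_times_s, config.fs)
            logger.info(
                "t=%.1fs samples %d/%d delay %.3fs [%s] "
                "protocol avg %.4fs max %.4fs [%s]",
                frame.timestamp, session.acquired_samples,
                session.expected_samples, delay.value, delay.status,
                ptime.value, ptime.max_value, ptime.status,
            )
            next_monitor_s += 1.0

    session.status = "ended"
    session.ended_at = handle.frame_log[-1].timestamp if handle.frame_log else 0.0
    handle.close()

    series = finish(state, feedback_per_output)
    record = build_record(
        handle.frame_log, descriptor, settings, config.fs,
        thermometer=np.asarray(thermo), markers=np.asarray(markers, dtype=int),
        started_at=0.0, ended_at=session.ended_at,
    )
    return SessionResult(
        record=record,
        series=series,
        session_state=session,
        protocol_time=update_protocol_time(state.exec_times_s, config.fs),
    )


def build_record(
    frame_log,
    descriptor: DeviceDescriptor,
    settings: Settings,
    fs: float,
    thermometer: np.ndarray,
    markers: np.ndarray,
    started_at: float,
    ended_at: float,
) -> SessionRecord:
    """Assemble the session record from the complete frame log: raw
    intensities at both wavelengths plus HbO/HbR for every selected
    channel (NF and SS selections alike)."""
    selected = tuple(sorted({*settings.nf_channels, *settings.ss_channels}))
    values = (
        np.vstack([f.values for f in frame_log])
        if frame_log
        else np.empty((0, descriptor.n_stream_columns))
    )
    wl = descriptor.wavelengths

    def cols(kind, wavelength=None):
        return np.array(
            descriptor.resolve_columns(kind, selected, wavelength=wavelength)
        ) - 1

    record = SessionRecord(
        sample_rate=fs,
        started_at=started_at,
        ended_at=ended_at,
        thermometer_series=np.asarray(thermometer, dtype=float),
        marker_series=np.asarray(markers, dtype=int),
        channel_ids=np.asarray(selected, dtype=int),
        raw_wl1=values[:, cols("raw_intensity", wl[0])] if len(wl) > 0 else values[:, :0],
        raw_wl2=values[:, cols("raw_intensity", wl[1])] if len(wl) > 1 else values[:, :0],
        hbo=values[:, cols("hbo")],
        hbr=values[:, cols("hbr")],
        settings_snapshot=settings.to_dict(),
    )
    record.validate()
    return record


def example_settings(
    schedule,
    device_name: str = "Generic NIRS (26CH)",
    nf_channels=(1, 2, 3, 4, 5, 6, 7, 8),
    ss_channels=(19, 20, 21, 22, 23, 24, 25, 26),
    window_s: float = 5.0,
    study: str = "test",
    subject: str = "1",
    run: str = "1",
    feedback: FeedbackSettings | None = None,
) -> Settings:
    """Reference settings for a simulated session: 8 NF channels from the
    long-separation block, the 8 short-separation channels as regressors,
    a 5-s window."""
    return Settings(
        device_name=device_name,
        protocol="MovAvg_SS",
        nf_channels=tuple(nf_channels),
        ss_channels=tuple(ss_channels),
        window_s=window_s,
        session_length_s=schedule.total_s,
        study=study,
        subject=subject,
        run=run,
        schedule=schedule,
        feedback=feedback or FeedbackSettings(),
    )
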