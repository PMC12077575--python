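"""Stream abstraction and the constant-size sliding-window buffer.

A :class:`StreamHandle` sits between a transport (live lab-streaming-layer
inlet or the in-process simulated transport) and the real-time pipeline.
Frames are appended to a ring buffer; once the buffer holds a full window
of ``round(window_s * fs)`` frames, :meth:`StreamHandle.latest_window`
returns a constant-size view whose rows slide by one with each new frame —
the oldest sample is discarded so the window size stays constant.

Every pushed frame is also mirrored into an append-only frame log so the
session record can retain frames after they leave the ring buffer.
"""

from __future__ import annotations

import time
from collections import deque
from dataclasses import dataclass, field
from typing import Protocol, runtime_checkable

import numpy as np

from .device_config import DeviceDescriptor
from .errors import (
    ConnectionFailedError,
    FrameShapeError,
    InvalidMarkerError,
    InvalidWindowError,
    StreamStateError,
)

#: default ring-buffer capacity, seconds of signal retained for windowing
DEFAULT_BUFFER_S = 60.0


@dataclass(frozen=True)
class Frame:
    """One multiplexed stream sample."""

    timestamp: float
    frame_index: int
    values: np.ndarray

    def __post_init__(self):
        object.__setattr__(
            self, "values", np.asarray(self.values, dtype=float)
        )


@dataclass(frozen=True)
class SlidingWindowView:
    """The most recent ``round(window_s * fs)`` frames, oldest first."""

    window_s: float
    fs: float
    samples: np.ndarray  # rows = frames, columns = stream columns
    end_timestamp: float

    @property
    def n_rows(self) -> int:
        return self.samples.shape[0]


@dataclass(frozen=True)
class StreamInfo:
    """What a transport advertises about its stream."""

    name: str
    modality: str
    n_channels: int
    sample_rate: float


@runtime_checkable
class Transport(Protocol):
    """Pluggable stream source.

    A transport either resolves a stream matching the descriptor (and then
    reports its :class:`StreamInfo`) or raises
    :class:`~nirsfeed.errors.ConnectionFailedError`.  Live and simulated
    transports share this contract, so every consumer runs unchanged
    without hardware.
    """

    def resolve(self, descriptor: DeviceDescriptor, timeout_s: float) -> StreamInfo:
        ...

    def close(self) -> None:
        ...


class StreamHandle:
    """Open stream with ring buffer, frame log, and marker outlet."""

    def __init__(
        self,
        descriptor: DeviceDescriptor,
        info: StreamInfo,
        transport: Transport,
        buffer_s: float = DEFAULT_BUFFER_S,
    ):
        self.descriptor = descriptor
        self.info = info
        self._transport = transport
        self.state = "open"
        capacity = max(1, int(round(buffer_s * info.sample_rate)))
        self._ring: deque[Frame] = deque(maxlen=capacity)
        self.frame_log: list[Frame] = []
        self.marker_log: list[tuple[int, float]] = []

    # -- properties ---------------------------------------------------
    @property
    def sample_rate(self) -> float:
        return self.info.sample_rate

    @property
    def n_stream_channels(self) -> int:
        return self.info.n_channels

    @property
    def occupancy(self) -> int:
        return len(self._ring)

    # -- lifecycle ----------------------------------------------------
    def close(self) -> None:
        if self.state != "closed":
            self._transport.close()
            self.state = "closed"

    # -- frames -------------------------------------------------------
    def push_frame(self, frame: Frame) -> int:
        """Append a frame; returns current ring-buffer occupancy."""
        if self.state == "closed":
            raise StreamStateError("cannot push frames on a closed stream")
        if frame.values.shape != (self.descriptor.n_stream_columns,):
            raise FrameShapeError(
                f"frame has {frame.values.shape[0]} values, stream has "
                f"{self.descriptor.n_stream_columns} columns"
            )
        self._ring.append(frame)
        self.frame_log.append(frame)
        return len(self._ring)

    def window_length(self, window_s: float) -> int:
        """Frames per window: round(window_s * fs)."""
        if window_s <= 0:
            raise InvalidWindowError(f"window_s must be > 0, got {window_s}")
        return int(round(window_s * self.sample_rate))

    def latest_window(self, window_s: float) -> SlidingWindowView | None:
        """Constant-size view of the most recent frames, or None if the
        first window is not yet fully available."""
        if self.state == "closed":
            raise StreamStateError("stream is closed")
        n = self.window_length(window_s)
        if len(self._ring) < n:
            return None
        frames = list(self._ring)[-n:]
        samples = np.vstack([f.values for f in frames])
        return SlidingWindowView(
            window_s=window_s,
            fs=self.sample_rate,
            samples=samples,
            end_timestamp=frames[-1].timestamp,
        )

    # -- markers ------------------------------------------------------
    def send_marker(self, marker_id: int, timestamp: float | None = None) -> tuple[int, float]:
        """Emit an event marker; returns the (id, timestamp) logged."""
        if self.state == "closed":
            raise StreamStateError("cannot send markers on a closed stream")
        if int(marker_id) < 1:
            raise InvalidMarkerError(f"marker IDs are positive, got {marker_id}")
        ts = time.time() if timestamp is None else float(timestamp)
        entry = (int(marker_id), ts)
        self.marker_log.append(entry)
        return entry


def open_stream(
    descriptor: DeviceDescriptor,
    transport: Transport,
    timeout_s: float = 5.0,
    buffer_s: float = DEFAULT_BUFFER_S,
) -> StreamHandle:
    """Open a stream matching the descriptor on the given transport.

    On success the handle reports the advertised channel count and sample
    rate; on failure a :class:`ConnectionFailedError` propagates and no
    handle is created.
    """
    info = transport.resolve(descriptor, timeout_s)
    if info.n_channels != descriptor.n_stream_columns:
        transport.close()
        raise ConnectionFailedError(
            f"stream advertises {info.n_channels} columns but descriptor "
            f"{descriptor.name!r} defines {descriptor.n_stream_columns}"
        )
    return StreamHandle(descriptor, info, transport, buffer_s=buffer_s)


class LSLTransport:
    """Live lab-streaming-layer transport (requires the optional pylsl
    dependency).  Resolves a data inlet whose type matches the descriptor
    modality and opens a marker outlet alongside it."""

    def __init__(self):
        try:
            import pylsl  # noqa: F401
        except ImportError as e:  # pragma: no cover - optional backend
            raise ConnectionFailedError(
                "pylsl is not installed; install the 'lsl' extra to use "
                "a live lab-streaming-layer transport"
            ) from e
        self._pylsl = pylsl
        self._inlet = None

    def resolve(self, descriptor: DeviceDescriptor, timeout_s: float) -> StreamInfo:  # pragma: no cover
        streams = self._pylsl.resolve_byprop(
            "type", descriptor.modality, timeout=timeout_s
        )
        if not streams:
            raise ConnectionFailedError(
                f"no {descriptor.modality} stream found within {timeout_s} s"
            )
        self._inlet = self._pylsl.StreamInlet(streams[0])
        si = self._inlet.info()
        return StreamInfo(
            name=si.name(),
            modality=si.type(),
            n_channels=si.channel_count(),
            sample_rate=si.nominal_srate(),
        )

    def close(self) -> None:  # pragma: no cover
        if self._inlet is not None:
            self._inlet.close_stream()
            self._inlet = None
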