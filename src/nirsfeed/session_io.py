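"""Session recording, settings persistence and summary export.

A completed session is archived as ``Study_Subject_Run`` in the sessions
directory — a MAT container by default, with an HDF5 dialect available —
holding the sample rate, start/end times, per-frame thermometer and
marker series, the raw data (both wavelengths, HbO, HbR) of every
selected channel, and a snapshot of the settings used.  Frames processed
before feedback existed (initial baseline, breaks, window fill-in) carry
NaN in the thermometer series so analysis can distinguish "no feedback
computed" from "pinned at the midline".

Settings (device name, protocol, channel selection, window size, session
length, ID fields, epoch table, feedback parameters) round-trip through
a JSON file.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.io import loadmat, savemat

from .errors import NirsFeedError, RecordError
from .feedback_engine import FeedbackSettings
from .protocol_session import Epoch, Schedule
from .realtime_pipeline import PROTOCOLS

#: stored in thermometer_series where no feedback was computed
THERMO_SENTINEL = float("nan")


@dataclass(frozen=True)
class Settings:
    """Everything needed to reproduce a session configuration."""

    device_name: str
    protocol: str
    nf_channels: tuple[int, ...]
    ss_channels: tuple[int, ...]
    window_s: float
    session_length_s: float
    study: str
    subject: str
    run: str
    schedule: Schedule
    feedback: FeedbackSettings = field(default_factory=FeedbackSettings)

    def to_dict(self) -> dict:
        return {
            "device_name": self.device_name,
            "protocol": self.protocol,
            "nf_channels": list(self.nf_channels),
            "ss_channels": list(self.ss_channels),
            "window_s": self.window_s,
            "session_length_s": self.session_length_s,
            "study": self.study,
            "subject": self.subject,
            "run": self.run,
            "epochs": [
                {
                    "start_s": e.start_s,
                    "end_s": e.end_s,
                    "marker": e.marker_id,
                    "visible": e.feedback_visible,
                    "color": e.background_color,
                }
                for e in self.schedule.epochs
            ],
            "feedback": dataclasses.asdict(self.feedback),
        }


def save_settings(settings: Settings, path: str | Path) -> Path:
    path = Path(path)
    path.write_text(
        json.dumps(settings.to_dict(), indent=2, ensure_ascii=False),
        encoding="utf-8",
    )
    return path


def load_settings(path: str | Path) -> Settings:
    """Load a settings file; validation of the epoch table itself is
    deferred to :func:`~nirsfeed.protocol_session.validate_schedule`, but
    an unknown protocol name is rejected here."""
    data = json.loads(Path(path).read_text(encoding="utf-8"))
    missing = [
        k
        for k in (
            "device_name", "protocol", "nf_channels", "ss_channels",
            "window_s", "session_length_s", "study", "subject", "run",
            "epochs",
        )
        if k not in data
    ]
    if missing:
        raise NirsFeedError(f"settings file missing fields: {missing}")
    if data["protocol"] not in PROTOCOLS:
        raise NirsFeedError(
            f"unknown protocol {data['protocol']!r}; "
            f"known: {sorted(PROTOCOLS)}"
        )
    schedule = Schedule(
        tuple(
            Epoch(
                start_s=float(e["start_s"]),
                end_s=float(e["end_s"]),
                marker_id=int(e["marker"]),
                feedback_visible=bool(e.get("visible", False)),
                background_color=str(e.get("color", "#000000")),
            )
            for e in data["epochs"]
        )
    )
    fb = FeedbackSettings(**data.get("feedback", {}))
    return Settings(
        device_name=str(data["device_name"]),
        protocol=str(data["protocol"]),
        nf_channels=tuple(int(c) for c in data["nf_channels"]),
        ss_channels=tuple(int(c) for c in data["ss_channels"]),
        window_s=float(data["window_s"]),
        session_length_s=float(data["session_length_s"]),
        study=str(data["study"]),
        subject=str(data["subject"]),
        run=str(data["run"]),
        schedule=schedule,
        feedback=fb,
    )


@dataclass
class SessionRecord:
    """Everything a completed acquisition wrote down."""

    sample_rate: float
    started_at: float
    ended_at: float
    thermometer_series: np.ndarray  # per frame, NaN where none computed
    marker_series: np.ndarray  # per frame, int marker IDs (0 = outside schedule)
    channel_ids: np.ndarray  # the recorded (selected) channels, 1-based
    raw_wl1: np.ndarray  # (n_frames, n_selected) intensities, first wavelength
    raw_wl2: np.ndarray  # (n_frames, n_selected) intensities, second wavelength
    hbo: np.ndarray  # (n_frames, n_selected) μmol/L
    hbr: np.ndarray  # (n_frames, n_selected) μmol/L
    settings_snapshot: dict = field(default_factory=dict)

    @property
    def n_frames(self) -> int:
        return int(self.thermometer_series.shape[0])

    def validate(self) -> None:
        n = self.n_frames
        for name in ("marker_series", "raw_wl1", "raw_wl2", "hbo", "hbr"):
            arr = getattr(self, name)
            if arr.shape[0] != n:
                raise RecordError(
                    f"{name} has {arr.shape[0]} frames, expected {n}"
                )
        c = self.channel_ids.shape[0]
        for name in ("raw_wl1", "raw_wl2", "hbo", "hbr"):
            if getattr(self, name).shape[1] != c:
                raise RecordError(
                    f"{name} has {getattr(self, name).shape[1]} channels, "
                    f"expected {c}"
                )


_RECORD_FIELDS = (
    "sample_rate", "started_at", "ended_at", "thermometer_series",
    "marker_series", "channel_ids", "raw_wl1", "raw_wl2", "hbo", "hbr",
)


def write_session_record(
    record: SessionRecord,
    study: str,
    subject: str,
    run: str,
    out_dir: str | Path,
    fmt: str = "mat",
    overwrite: bool = False,
) -> Path:
    """Write the record archive named ``Study_Subject_Run`` to
    ``out_dir`` (created if needed).  ``fmt`` is ``mat`` (default) or
    ``h5``; an existing file is refused unless ``overwrite`` is set."""
    record.validate()
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    ext = {"mat": ".mat", "h5": ".h5"}.get(fmt)
    if ext is None:
        raise RecordError(f"unknown record format {fmt!r}")
    path = out_dir / f"{study}_{subject}_{run}{ext}"
    if path.exists() and not overwrite:
        raise RecordError(f"{path} exists; pass overwrite to replace it")

    if fmt == "mat":
        payload = {f: getattr(record, f) for f in _RECORD_FIELDS}
        payload["settings_snapshot"] = json.dumps(record.settings_snapshot)
        savemat(path, payload)
    else:
        import h5py

        with h5py.File(path, "w") as f:
            for name in _RECORD_FIELDS:
                f.create_dataset(name, data=np.asarray(getattr(record, name)))
            f.attrs["settings_snapshot"] = json.dumps(record.settings_snapshot)
    return path


def read_session_record(path: str | Path) -> SessionRecord:
    """Exact inverse of :func:`write_session_record`, for either dialect."""
    path = Path(path)
    if not path.exists():
        raise RecordError(f"{path} does not exist")
    if path.suffix == ".h5":
        import h5py

        with h5py.File(path, "r") as f:
            missing = [n for n in _RECORD_FIELDS if n not in f]
            if missing:
                raise RecordError(f"record missing fields: {missing}")
            data = {n: np.asarray(f[n]) for n in _RECORD_FIELDS}
            snapshot = json.loads(f.attrs.get("settings_snapshot", "{}"))
    else:
        try:
            raw = loadmat(path)
        except Exception as e:
            raise RecordError(f"cannot read {path}: {e}") from e
        missing = [n for n in _RECORD_FIELDS if n not in raw]
        if missing:
            raise RecordError(f"record missing fields: {missing}")
        data = {n: np.asarray(raw[n]) for n in _RECORD_FIELDS}
        snap_raw = raw.get("settings_snapshot", "{}")
        snapshot = json.loads(str(np.squeeze(snap_raw)) or "{}")

    def scalar(x):
        return float(np.asarray(x).squeeze())

    def vec(x, dtype=float):
        return np.asarray(x, dtype=dtype).reshape(-1)

    def mat2d(x):
        a = np.asarray(x, dtype=float)
        return a.reshape(a.shape[0], -1) if a.ndim > 1 else a.reshape(-1, 1)

    rec = SessionRecord(
        sample_rate=scalar(data["sample_rate"]),
        started_at=scalar(data["started_at"]),
        ended_at=scalar(data["ended_at"]),
        thermometer_series=vec(data["thermometer_series"]),
        marker_series=vec(data["marker_series"], dtype=int),
        channel_ids=vec(data["channel_ids"], dtype=int),
        raw_wl1=mat2d(data["raw_wl1"]),
        raw_wl2=mat2d(data["raw_wl2"]),
        hbo=mat2d(data["hbo"]),
        hbr=mat2d(data["hbr"]),
        settings_snapshot=snapshot,
    )
    rec.validate()
    return rec


@dataclass(frozen=True)
class RunSummary:
    """The three aligned series behind the end-of-run figure."""

    mean_nf_series: np.ndarray
    feedback_series: np.ndarray
    marker_series: np.ndarray


def export_summary(record: SessionRecord) -> RunSummary:
    """Summarize a record: average HbO across the recorded NF channels
    (all recorded channels if the snapshot names no NF subset), the
    per-frame feedback (thermometer) series, and the marker series."""
    if record.n_frames == 0:
        empty = np.empty(0)
        return RunSummary(empty, empty.copy(), np.empty(0, dtype=int))
    nf_ids = record.settings_snapshot.get("nf_channels")
    if nf_ids:
        idx = [
            i
            for i, cid in enumerate(record.channel_ids)
            if int(cid) in set(int(c) for c in nf_ids)
        ]
        cols = idx or list(range(record.hbo.shape[1]))
    else:
        cols = list(range(record.hbo.shape[1]))
    return RunSummary(
        mean_nf_series=record.hbo[:, cols].mean(axis=1),
        feedback_series=record.thermometer_series.copy(),
        marker_series=record.marker_series.copy(),
    )


def render_summary(summary: RunSummary, fs: float, path: str | Path) -> Path:
    """Render the summary figure to ``path`` (side-effect-free beyond the
    written file)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    t = np.arange(summary.mean_nf_series.shape[0]) / fs
    fig, axes = plt.subplots(3, 1, sharex=True, figsize=(9, 6))
    axes[0].plot(t, summary.mean_nf_series, lw=0.7)
    axes[0].set_ylabel("mean NF HbO (μmol/L)")
    axes[1].plot(t, summary.feedback_series, lw=0.7, color="tab:red")
    axes[1].set_ylabel("thermometer")
    axes[2].step(t, summary.marker_series, lw=0.7, color="k", where="post")
    axes[2].set_ylabel("marker")
    axes[2].set_xlabel("time (s)")
    fig.tight_layout()
    fig.savefig(path, dpi=100)
    plt.close(fig)
    return Path(path)
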