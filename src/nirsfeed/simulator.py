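"""Schedule-driven synthetic fNIRS stream generator.

Emulates what a continuous-wave NIRS acquisition delivers over the wire:
per-channel HbO/HbR concentration changes (μmol/L) plus raw light
intensities at two wavelengths consistent with the modified Beer–Lambert
law (MBLL).  Long-separation channels carry a block-design activation —
the canonical hemodynamic response convolved with the schedule's
regulation boxcar — on top of systemic physiology (cardiac, respiratory
and Mayer-wave oscillations, slow drift) that is shared with the
short-separation channels; short channels carry systemic physiology and
noise only.  That construction makes the short channels a valid regressor
for removing the systemic component from the long channels, and the
exported ground-truth activation curve is the oracle for testing that
removal.

All randomness flows from one integer seed; per-channel noise streams are
spawned deterministically from it, so identical configs give bit-identical
output.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Iterator

import numpy as np

from .device_config import DeviceDescriptor
from .errors import LayoutMismatchError, SignalDomainError
from .protocol_session import MARKER_REGULATION, Schedule
from .streaming import Frame, StreamHandle, StreamInfo

#: μmol/L → mmol/L: the extinction coefficients below are on the
#: per-(mM·cm) scale, concentrations in this package are μmol/L.
_UM_TO_MM = 1e-3


@dataclass(frozen=True)
class WavelengthCoefficients:
    """Extinction coefficients (per mM per cm) and differential pathlength
    factor for one wavelength."""

    wavelength_nm: float
    eps_hbo: float
    eps_hbr: float
    dpf: float


@dataclass(frozen=True)
class OpticalCoefficients:
    """MBLL constants: per-wavelength extinction/DPF plus the
    source–detector distance in cm.

    Defaults are the fixed conversion constants the NIRx acquisition
    software applies for 760/850 nm, with a 3 cm long-channel separation.
    """

    per_wavelength: tuple[WavelengthCoefficients, ...] = (
        WavelengthCoefficients(760.0, eps_hbo=1.35, eps_hbr=3.57, dpf=6.30),
        WavelengthCoefficients(850.0, eps_hbo=2.44, eps_hbr=1.59, dpf=5.23),
    )
    distance_cm: float = 3.0

    def __post_init__(self):
        if self.distance_cm <= 0:
            raise SignalDomainError("source–detector distance must be positive")
        for wc in self.per_wavelength:
            if min(wc.eps_hbo, wc.eps_hbr, wc.dpf) <= 0:
                raise SignalDomainError("optical coefficients must be positive")

    def matrix(self) -> np.ndarray:
        """2×2 system mapping (ΔHbO, ΔHbR) in μmol/L to ΔOD per wavelength."""
        rows = [
            [
                wc.eps_hbo * self.distance_cm * wc.dpf * _UM_TO_MM,
                wc.eps_hbr * self.distance_cm * wc.dpf * _UM_TO_MM,
            ]
            for wc in self.per_wavelength
        ]
        return np.asarray(rows, dtype=float)


DEFAULT_COEFFICIENTS = OpticalCoefficients()
SHORT_SEPARATION_CM = 0.8  # 8 mm short channels


@dataclass(frozen=True)
class NoiseConfig:
    """Systemic physiology emulation.

    Frequencies in Hz, amplitudes in μmol/L.  Cardiac ~1.1 Hz,
    respiration ~0.25 Hz, Mayer waves ~0.1 Hz, plus a slow linear drift
    (μmol/L per second) and white sensor noise.
    """

    cardiac_hz: float = 1.1
    cardiac_amp: float = 0.02
    resp_hz: float = 0.25
    resp_amp: float = 0.03
    mayer_hz: float = 0.1
    mayer_amp: float = 0.04
    drift_slope: float = 0.0005
    white_sd: float = 0.01


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for one synthetic session.

    Defaults mirror the reference block-design study: 10.17 Hz sampling,
    18 long + 8 short channels, 0.1 μmol/L HbO activation per regulation
    block, hemodynamic response peaking at 5 s.
    """

    schedule: Schedule
    fs: float = 10.17
    n_long: int = 18
    n_short: int = 8
    activation_amp: float = 0.1
    hbr_ratio: float = -0.3
    hrf_peak_s: float = 5.0
    noise: NoiseConfig = field(default_factory=NoiseConfig)
    coefficients: OpticalCoefficients = DEFAULT_COEFFICIENTS
    baseline_lead_in_s: float = 0.0  # optional quiet period before the schedule
    i0: float = 1.0  # reference raw intensity (V)
    seed: int = 0

    def __post_init__(self):
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        if self.n_long < 1 or self.n_short < 0:
            raise ValueError("need at least one long channel")
        if self.activation_amp < 0:
            raise ValueError("activation_amp must be non-negative")

    @property
    def n_channels(self) -> int:
        return self.n_long + self.n_short

    @property
    def long_ids(self) -> list[int]:
        return list(range(1, self.n_long + 1))

    @property
    def short_ids(self) -> list[int]:
        return list(range(self.n_long + 1, self.n_channels + 1))


def canonical_hrf(t: np.ndarray, peak_s: float = 5.0) -> np.ndarray:
    """Canonical hemodynamic response on the time grid ``t`` (seconds).

    Double-gamma shape: a positive lobe peaking at ``peak_s`` minus a
    15%-amplitude undershoot peaking 10 s later, normalized to unit peak.
    Physiological peaks lie in 4–6 s; values outside that range warn but
    are honoured.
    """
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("t must be non-negative")
    if not 4.0 <= peak_s <= 6.0:
        warnings.warn(
            f"hrf peak {peak_s} s outside the physiological 4–6 s range",
            stacklevel=2,
        )
    # gamma-like lobes (p/b)=shape chosen so each lobe peaks exactly at p
    def lobe(p: float, b: float) -> np.ndarray:
        a = p / b
        with np.errstate(divide="ignore", invalid="ignore"):
            out = np.where(t > 0, (t / p) ** a * np.exp(-(t - p) / b), 0.0)
        return out

    h = lobe(peak_s, 1.0) - 0.15 * lobe(peak_s + 10.0, 1.6)
    return h / np.max(h)


def regulation_boxcar(schedule: Schedule, t: np.ndarray) -> np.ndarray:
    """1 during regulation epochs, else 0, on the time grid ``t``."""
    box = np.zeros_like(t, dtype=float)
    for e in schedule.epochs:
        if e.marker_id == MARKER_REGULATION:
            box[(t >= e.start_s) & (t < e.end_s)] = 1.0
    return box


@dataclass(frozen=True)
class SimulationResult:
    """Simulated concentration series plus ground truth.

    ``hbo``/``hbr`` are (n_samples, n_channels) in μmol/L, channels
    ordered long (1..n_long) then short.  ``truth_activation`` is the
    noise-free HbO activation component common to all long channels —
    the oracle for regression-quality tests.
    """

    t: np.ndarray
    hbo: np.ndarray
    hbr: np.ndarray
    truth_activation: np.ndarray
    config: SimulationConfig


def simulate_concentrations(config: SimulationConfig) -> SimulationResult:
    """Synthesize HbO/HbR series for every channel of the session.

    Long channels: activation + shared systemic + white noise.
    Short channels: shared systemic + white noise (no activation).
    HbR: ``hbr_ratio`` × activation on long channels + independent noise.
    """
    fs = config.fs
    n_samples = int(round((config.baseline_lead_in_s + config.schedule.total_s) * fs))
    t = np.arange(n_samples) / fs
    # schedule time starts after the optional quiet lead-in
    t_sched = t - config.baseline_lead_in_s

    box = np.zeros(n_samples)
    valid = t_sched >= 0
    box[valid] = regulation_boxcar(config.schedule, t_sched[valid])
    hrf_t = np.arange(0, 30.0, 1.0 / fs)
    hrf = canonical_hrf(hrf_t, config.hrf_peak_s)
    conv = np.convolve(box, hrf)[:n_samples]
    peak = conv.max() if conv.max() > 0 else 1.0
    truth = config.activation_amp * conv / peak

    ss = np.random.SeedSequence(config.seed)
    children = ss.spawn(config.n_channels + 1)
    rng_global = np.random.default_rng(children[0])

    nz = config.noise
    phases = rng_global.uniform(0, 2 * np.pi, size=3)
    systemic = (
        nz.cardiac_amp * np.sin(2 * np.pi * nz.cardiac_hz * t + phases[0])
        + nz.resp_amp * np.sin(2 * np.pi * nz.resp_hz * t + phases[1])
        + nz.mayer_amp * np.sin(2 * np.pi * nz.mayer_hz * t + phases[2])
        + nz.drift_slope * t
    )
    # per-channel coupling gain to the shared systemic component
    gains = rng_global.uniform(0.8, 1.2, size=config.n_channels)

    hbo = np.empty((n_samples, config.n_channels))
    hbr = np.empty((n_samples, config.n_channels))
    for c in range(config.n_channels):
        rng = np.random.default_rng(children[c + 1])
        activation = truth if c < config.n_long else 0.0
        hbo[:, c] = (
            activation
            + gains[c] * systemic
            + rng.normal(0, nz.white_sd, n_samples)
        )
        hbr[:, c] = (
            config.hbr_ratio * activation
            + rng.normal(0, nz.white_sd, n_samples)
        )
    return SimulationResult(t=t, hbo=hbo, hbr=hbr, truth_activation=truth, config=config)


# ---------------------------------------------------------------------------
# Modified Beer–Lambert law
# ---------------------------------------------------------------------------

def mbll_forward(
    intensity_ratios: np.ndarray,
    coefficients: OpticalCoefficients = DEFAULT_COEFFICIENTS,
) -> tuple[np.ndarray, np.ndarray]:
    """Convert raw-intensity ratios I/I0 (one per wavelength) to
    concentration changes ΔHbO, ΔHbR in μmol/L.

    Solves the 2×2 extinction system per sample from optical-density
    changes ΔOD(λ) = −log10(I/I0) with pathlength distance × DPF(λ).

    ``intensity_ratios`` has shape (2,) or (n, 2) (wavelength order of
    the coefficient set).
    """
    ratios = np.asarray(intensity_ratios, dtype=float)
    if np.any(ratios <= 0):
        raise SignalDomainError("light intensities must be positive")
    a = coefficients.matrix()
    if abs(np.linalg.det(a)) < 1e-12:
        raise SignalDomainError("extinction system is singular")
    dod = -np.log10(ratios)
    conc = np.linalg.solve(a, np.atleast_2d(dod).T).T
    conc = conc.reshape(ratios.shape)
    return conc[..., 0], conc[..., 1]


def mbll_inverse(
    d_hbo: np.ndarray,
    d_hbr: np.ndarray,
    coefficients: OpticalCoefficients = DEFAULT_COEFFICIENTS,
) -> np.ndarray:
    """Exact algebraic inverse of :func:`mbll_forward`: concentration
    changes (μmol/L) to intensity ratios I/I0 per wavelength."""
    conc = np.stack(
        [np.asarray(d_hbo, dtype=float), np.asarray(d_hbr, dtype=float)], axis=-1
    )
    a = coefficients.matrix()
    dod = conc @ a.T
    return 10.0 ** (-dod)


# ---------------------------------------------------------------------------
# Frame stream
# ---------------------------------------------------------------------------

def iter_frames(
    result: SimulationResult, descriptor: DeviceDescriptor
) -> Iterator[Frame]:
    """Yield the simulation as multiplexed frames in descriptor layout:
    counter, raw intensities per wavelength (via the inverse MBLL), HbO,
    HbR.  The counter column increments by exactly 1 per frame."""
    config = result.config
    if descriptor.n_channels != config.n_channels:
        raise LayoutMismatchError(
            f"descriptor has {descriptor.n_channels} channels, simulation "
            f"has {config.n_channels}"
        )
    n_cols = descriptor.n_stream_columns
    counter_col = descriptor.resolve_columns("frame_counter")[0] - 1
    all_ids = list(range(1, config.n_channels + 1))
    hbo_cols = np.array(descriptor.resolve_columns("hbo", all_ids)) - 1
    hbr_cols = np.array(descriptor.resolve_columns("hbr", all_ids)) - 1
    raw_cols = [
        np.array(descriptor.resolve_columns("raw_intensity", all_ids, wavelength=wl)) - 1
        for wl in descriptor.wavelengths
    ]

    ratios = mbll_inverse(result.hbo, result.hbr, config.coefficients)
    intensities = config.i0 * ratios  # (n_samples, n_channels, n_wavelengths)

    for i in range(result.t.shape[0]):
        values = np.zeros(n_cols)
        values[counter_col] = i + 1
        for w, cols in enumerate(raw_cols):
            values[cols] = intensities[i, :, w]
        values[hbo_cols] = result.hbo[i]
        values[hbr_cols] = result.hbr[i]
        yield Frame(timestamp=float(result.t[i]), frame_index=i + 1, values=values)


def stream_simulation(
    config: SimulationConfig,
    descriptor: DeviceDescriptor,
    handle: StreamHandle,
) -> int:
    """Push a full simulated session into an open stream handle
    (accelerated time).  Returns the number of frames pushed."""
    result = simulate_concentrations(config)
    n = 0
    for frame in iter_frames(result, descriptor):
        handle.push_frame(frame)
        n += 1
    return n


class SimulatedTransport:
    """In-process transport advertising a simulated stream.

    Mirrors the live transport contract exactly: :meth:`resolve` reports
    channel count and sample rate, or raises if configured unreachable.
    """

    def __init__(self, config: SimulationConfig, reachable: bool = True):
        self.config = config
        self.reachable = reachable
        self._result: SimulationResult | None = None

    def resolve(self, descriptor: DeviceDescriptor, timeout_s: float) -> StreamInfo:
        from .errors import ConnectionFailedError

        if not self.reachable:
            raise ConnectionFailedError(
                f"no {descriptor.modality} stream found within {timeout_s} s"
            )
        if descriptor.n_channels != self.config.n_channels:
            raise ConnectionFailedError(
                f"simulated stream has {self.config.n_channels} channels, "
                f"descriptor declares {descriptor.n_channels}"
            )
        return StreamInfo(
            name=descriptor.name,
            modality=descriptor.modality,
            n_channels=descriptor.n_stream_columns,
            sample_rate=self.config.fs,
        )

    def frames(self, descriptor: DeviceDescriptor) -> Iterator[Frame]:
        if self._result is None:
            self._result = simulate_concentrations(self.config)
        return iter_frames(self._result, descriptor)

    @property
    def ground_truth(self) -> SimulationResult:
        if self._result is None:
            self._result = simulate_concentrations(self.config)
        return self._result

    def close(self) -> None:
        pass
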