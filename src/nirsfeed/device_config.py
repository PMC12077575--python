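"""Device descriptors: the column layout of a multiplexed sample stream.

An acquisition device streams each sample as one flat vector.  For a
two-wavelength NIRS device with *N* channels the vector has ``4*N + 1``
entries: a frame counter, then N raw light intensities per wavelength,
then N oxygenated-hemoglobin (HbO) and N deoxygenated-hemoglobin (HbR)
concentration changes.  A descriptor (a small JSON file) names the device
and maps every stream column to its role so downstream code can resolve
"HbO of channel 5" to a concrete column index.

Column indices are 1-based throughout the public API, matching the
documentation convention for stream layouts; channel IDs are likewise
1-based.  The JSON schema is documented in ``docs/device_schema.md``.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from .errors import DescriptorError, LayoutMismatchError, UnknownChannelError

logger = logging.getLogger(__name__)

ROLE_KINDS = ("frame_counter", "raw_intensity", "hbo", "hbr")

#: keys a descriptor file must contain
_REQUIRED_KEYS = ("name", "type", "channels")

_KNOWN_KEYS = _REQUIRED_KEYS + ("wavelengths", "units", "columns")


@dataclass(frozen=True)
class ChannelRole:
    """Role of one stream column.

    ``wavelength`` is set only for ``raw_intensity`` columns; ``channel_id``
    is absent (None) only for the frame counter.
    """

    kind: str
    wavelength: float | None = None
    channel_id: int | None = None
    unit: str = ""

    def __post_init__(self):
        if self.kind not in ROLE_KINDS:
            raise DescriptorError(f"unknown column role kind: {self.kind!r}")
        if self.kind == "frame_counter" and self.channel_id is not None:
            raise DescriptorError("frame_counter column carries no channel_id")
        if self.kind != "frame_counter" and (
            self.channel_id is None or self.channel_id < 1
        ):
            raise DescriptorError(
                f"{self.kind} column requires a positive channel_id"
            )
        if self.kind == "raw_intensity" and self.wavelength is None:
            raise DescriptorError("raw_intensity column requires a wavelength")


@dataclass(frozen=True)
class DeviceDescriptor:
    """Validated device descriptor.

    ``column_map`` holds one :class:`ChannelRole` per stream column, in
    stream order.  For the documented two-wavelength NIRS dialect the
    order is: frame counter, raw@λ1 × N, raw@λ2 × N, HbO × N, HbR × N —
    but any order the JSON declares explicitly is legal.
    """

    name: str
    modality: str
    n_channels: int
    wavelengths: tuple[float, ...]
    column_map: tuple[ChannelRole, ...] = field(repr=False)

    @property
    def n_stream_columns(self) -> int:
        return len(self.column_map)

    def resolve_columns(
        self,
        kind: str,
        channel_ids: Sequence[int] | None = None,
        wavelength: float | None = None,
    ) -> list[int]:
        """Resolve stream columns (1-based) for a role kind.

        For ``frame_counter``, ``channel_ids`` is ignored.  For
        ``raw_intensity`` an explicit ``wavelength`` narrows the match.
        Columns are returned in the order the channel IDs were requested.
        """
        if kind not in ROLE_KINDS:
            raise DescriptorError(f"unknown column role kind: {kind!r}")
        if kind == "frame_counter":
            for i, role in enumerate(self.column_map, start=1):
                if role.kind == "frame_counter":
                    return [i]
            raise DescriptorError("descriptor has no frame_counter column")

        if channel_ids is None:
            channel_ids = range(1, self.n_channels + 1)
        out: list[int] = []
        for cid in channel_ids:
            if not 1 <= cid <= self.n_channels:
                raise UnknownChannelError(
                    f"channel {cid} out of range 1..{self.n_channels}"
                )
            matches = [
                i
                for i, role in enumerate(self.column_map, start=1)
                if role.kind == kind
                and role.channel_id == cid
                and (wavelength is None or role.wavelength == wavelength)
            ]
            if not matches:
                raise UnknownChannelError(
                    f"no {kind} column for channel {cid}"
                    + (f" at {wavelength} nm" if wavelength else "")
                )
            out.extend(matches)
        return out

    def to_json(self) -> str:
        """Serialize back to descriptor JSON (explicit column list)."""
        cols = []
        for role in self.column_map:
            entry: dict = {"role": role.kind}
            if role.channel_id is not None:
                entry["channel"] = role.channel_id
            if role.wavelength is not None:
                entry["wavelength"] = role.wavelength
            if role.unit:
                entry["unit"] = role.unit
            cols.append(entry)
        return json.dumps(
            {
                "name": self.name,
                "type": self.modality,
                "channels": self.n_channels,
                "wavelengths": list(self.wavelengths),
                "columns": cols,
            },
            indent=2,
            ensure_ascii=False,
        )


def default_nirs_column_map(
    n_channels: int,
    wavelengths: Sequence[float],
    raw_unit: str = "V",
    conc_unit: str = "μmol/L",
) -> tuple[ChannelRole, ...]:
    """Documented dialect: counter, raw per wavelength, HbO, HbR blocks."""
    cols: list[ChannelRole] = [ChannelRole("frame_counter", unit="count")]
    for wl in wavelengths:
        cols.extend(
            ChannelRole("raw_intensity", wavelength=wl, channel_id=c, unit=raw_unit)
            for c in range(1, n_channels + 1)
        )
    for kind in ("hbo", "hbr"):
        cols.extend(
            ChannelRole(kind, channel_id=c, unit=conc_unit)
            for c in range(1, n_channels + 1)
        )
    return tuple(cols)


def _parse_explicit_columns(raw_cols: Iterable[dict]) -> tuple[ChannelRole, ...]:
    cols = []
    for i, entry in enumerate(raw_cols, start=1):
        if "role" not in entry:
            raise DescriptorError(f"column {i}: missing 'role'")
        cols.append(
            ChannelRole(
                kind=entry["role"],
                wavelength=entry.get("wavelength"),
                channel_id=entry.get("channel"),
                unit=entry.get("unit", ""),
            )
        )
    return tuple(cols)


def load_device_descriptor(descriptor_text: str) -> DeviceDescriptor:
    """Parse and validate a device descriptor from JSON text.

    Required keys: ``name``, ``type`` (NIRS or EEG), ``channels``; NIRS
    descriptors additionally need ``wavelengths``.  Unknown keys are
    ignored with a logged warning.  If no explicit ``columns`` list is
    given, the documented default dialect is constructed.

    Raises
    ------
    DescriptorError
        if a required field is missing or invalid.
    LayoutMismatchError
        if an explicit column list disagrees with the declared channel
        count (for NIRS: ``4*N + 1`` columns with two wavelengths).
    """
    try:
        data = json.loads(descriptor_text)
    except json.JSONDecodeError as e:
        raise DescriptorError(f"descriptor is not valid JSON: {e}") from e
    if not isinstance(data, dict):
        raise DescriptorError("descriptor JSON must be an object")

    for key in _REQUIRED_KEYS:
        if key not in data:
            raise DescriptorError(f"descriptor missing required field {key!r}")
    for key in data:
        if key not in _KNOWN_KEYS:
            logger.warning("device descriptor: ignoring unknown key %r", key)

    modality = str(data["type"]).upper()
    if modality not in ("NIRS", "EEG"):
        raise DescriptorError(f"unsupported device type: {data['type']!r}")
    try:
        n = int(data["channels"])
    except (TypeError, ValueError):
        raise DescriptorError("'channels' must be a positive integer") from None
    if n < 1:
        raise DescriptorError("'channels' must be a positive integer")

    wavelengths = tuple(float(w) for w in data.get("wavelengths", ()))
    if modality == "NIRS" and not wavelengths:
        raise DescriptorError("NIRS descriptor missing required field 'wavelengths'")

    units = data.get("units", {})
    if "columns" in data:
        column_map = _parse_explicit_columns(data["columns"])
    elif modality == "NIRS":
        column_map = default_nirs_column_map(
            n,
            wavelengths,
            raw_unit=units.get("raw", "V"),
            conc_unit=units.get("chromophore", "μmol/L"),
        )
    else:  # EEG: counter + one column per channel
        column_map = (ChannelRole("frame_counter", unit="count"),) + tuple(
            ChannelRole("raw_intensity", wavelength=0.0, channel_id=c,
                        unit=units.get("raw", "μV"))
            for c in range(1, n + 1)
        )

    desc = DeviceDescriptor(
        name=str(data["name"]),
        modality=modality,
        n_channels=n,
        wavelengths=wavelengths,
        column_map=column_map,
    )
    _validate_layout(desc)
    return desc


def _validate_layout(desc: DeviceDescriptor) -> None:
    if desc.modality == "NIRS":
        expected = 2 * len(desc.wavelengths) * desc.n_channels + 1
        if desc.n_stream_columns != expected:
            raise LayoutMismatchError(
                f"descriptor declares {desc.n_channels} channels and "
                f"{len(desc.wavelengths)} wavelengths, expecting "
                f"{expected} stream columns, got {desc.n_stream_columns}"
            )
    for role in desc.column_map:
        if role.channel_id is not None and role.channel_id > desc.n_channels:
            raise LayoutMismatchError(
                f"column channel_id {role.channel_id} exceeds N={desc.n_channels}"
            )
    seen = set()
    for role in desc.column_map:
        key = (role.kind, role.wavelength, role.channel_id)
        if key in seen:
            raise DescriptorError(f"duplicate column role {key}")
        seen.add(key)


def resolve_columns(
    descriptor: DeviceDescriptor,
    kind: str,
    channel_ids: Sequence[int] | None = None,
    wavelength: float | None = None,
) -> list[int]:
    """Module-level alias for :meth:`DeviceDescriptor.resolve_columns`."""
    return descriptor.resolve_columns(kind, channel_ids, wavelength)
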