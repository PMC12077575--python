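"""Exception hierarchy for the neurofeedback engine.

All engine errors derive from :class:`NirsFeedError` so callers can catch
one base class at the CLI boundary.
"""


class NirsFeedError(Exception):
    """Base class for all errors raised by this package."""


class DescriptorError(NirsFeedError):
    """A device descriptor is missing required fields or is inconsistent."""


class LayoutMismatchError(DescriptorError):
    """Declared channel count disagrees with the stream column layout."""


class UnknownChannelError(NirsFeedError):
    """A requested channel ID is not present in the descriptor."""


class ConnectionFailedError(NirsFeedError):
    """No stream matching the descriptor could be opened."""


class StreamStateError(NirsFeedError):
    """Operation attempted on a stream handle in the wrong state."""


class FrameShapeError(NirsFeedError):
    """Pushed frame value vector does not match the stream column count."""


class InvalidWindowError(NirsFeedError):
    """Requested sliding-window length is not positive."""


class InvalidMarkerError(NirsFeedError):
    """Marker IDs must be positive integers."""


class SignalDomainError(NirsFeedError):
    """Signal values outside the physical domain (e.g. non-positive light
    intensity in the optical-density computation)."""


class InvalidScheduleError(NirsFeedError):
    """Epoch schedule specification is structurally invalid."""


class RequirementError(NirsFeedError):
    """Protocol requirements not met; carries the violation list."""

    def __init__(self, violations):
        self.violations = list(violations)
        super().__init__("; ".join(self.violations))


class InsufficientDataError(NirsFeedError):
    """Too few samples for the requested computation."""


class ParameterError(NirsFeedError):
    """Invalid numeric parameter (e.g. band edges out of order)."""


class RecordError(NirsFeedError):
    """Session record violates its invariants or cannot be (de)serialized."""
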