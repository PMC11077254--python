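"""Exception hierarchy.

All package errors derive from :class:`TinnisynthError` so callers can catch
one base class; the concrete subclasses mirror the distinct failure modes of
the protocol (bad input data, a query outside the measured span, an audiogram
without any hearing loss, a protocol precondition that cannot be met).
"""


class TinnisynthError(Exception):
    """Base class for all package errors."""


class AudiogramParseError(TinnisynthError, ValueError):
    """Malformed tabular audiogram input; message names the offending line."""


class ValidationError(TinnisynthError, ValueError):
    """A domain-type invariant is violated (range, ordering, duplicates)."""


class DomainError(TinnisynthError, ValueError):
    """A query frequency lies outside the measured audiogram span."""


class NoHearingLossError(TinnisynthError, ValueError):
    """No audiometric threshold exceeds the normal-hearing cutoff."""


class ConfigurationError(TinnisynthError, ValueError):
    """The audiogram shape does not support the requested protocol step
    (e.g. no measured frequency with a normal threshold adjacent to the
    loss onset, or no normal-hearing range for a placebo sound)."""
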