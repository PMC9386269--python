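"""Exception hierarchy.

All pipeline errors derive from :class:`TremorKitError` so callers (and the
CLI) can distinguish validation problems (exit code 2) from genuine bugs.
"""


class TremorKitError(Exception):
    """Base class for all validation and data errors raised by tremorkit."""


class MetadataError(TremorKitError):
    """Filename or header metadata could not be interpreted."""


class ParseError(TremorKitError):
    """A delimited recording file is malformed."""


class UnitError(TremorKitError):
    """Unknown or inconsistent physical units."""


class DataError(TremorKitError):
    """Signal content violates a precondition (non-finite values, ...)."""


class SegmentationError(TremorKitError):
    """Light markers cannot be reconciled with the protocol definition."""


class ConfigurationError(TremorKitError):
    """Analysis configuration is internally inconsistent."""


class StatsError(TremorKitError):
    """A statistical operation received degenerate input."""
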