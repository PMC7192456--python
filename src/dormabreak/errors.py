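"""Exception hierarchy for dormabreak.

All dormabreak-specific failures derive from :class:`DormabreakError` so
callers can catch the package's errors without swallowing programming
errors from the underlying numerical libraries.
"""


class DormabreakError(Exception):
    """Base class for all dormabreak errors."""


class SchemaError(DormabreakError):
    """An input file does not have the expected columns/layout."""


class ValidationError(DormabreakError):
    """Data violate a domain invariant (e.g. decreasing cumulative counts)."""


class AlignmentError(DormabreakError):
    """Two inputs that must share sample identifiers do not align."""


class IntegrityError(DormabreakError):
    """Stored derived constants disagree with the stored coefficients."""


class UnderdeterminedError(DormabreakError):
    """Too few data points to fit the requested model."""


class NoOptimumError(DormabreakError):
    """A fitted polynomial opens upward: no interior optimum exists."""


class UnachievableTargetError(DormabreakError):
    """A requested sprouting percentage exceeds the model maximum."""


class ConfigError(DormabreakError):
    """A simulation or pipeline configuration is inconsistent."""
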