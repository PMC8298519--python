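"""Exception hierarchy.

Validation/format/parameter errors map to a distinct CLI exit code (3) so
callers can tell bad inputs apart from runtime failures (4).
"""


class SurgforceError(Exception):
    """Base class for all package errors."""


class FormatError(SurgforceError):
    """A file does not conform to one of the documented on-disk formats."""


class ValidationError(SurgforceError):
    """An in-memory object violates a data-model invariant."""


class ParameterError(SurgforceError):
    """A configuration or function parameter is out of its valid range."""


class SchemaError(SurgforceError):
    """Column/feature names do not match what a fitted model expects."""


class FittingError(SurgforceError):
    """A statistical fit cannot proceed (e.g. no expert segments)."""


class ConfigurationError(SurgforceError):
    """The requested analysis is impossible on the given data layout."""
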