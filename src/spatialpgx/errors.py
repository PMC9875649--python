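"""Exception hierarchy shared across the pipeline."""


class SpatialPgxError(Exception):
    """Base class for all package errors."""


class FormatError(SpatialPgxError):
    """An on-disk file does not conform to its expected format."""


class ValidationError(SpatialPgxError):
    """In-memory data violates a contract (invariants, preconditions)."""


class ConfigurationError(SpatialPgxError):
    """A simulation or run configuration is internally inconsistent."""
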