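"""Exception types shared across the package."""


class MsResError(Exception):
    """Base class for package-specific errors."""


class ConfigurationError(MsResError, ValueError):
    """An architectural or pipeline configuration is internally inconsistent
    (e.g. the pooling cascade collapses a stream below length 1)."""


class CannotBalanceError(MsResError, ValueError):
    """Oversampling is impossible (single-class input or too few minority points)."""


class DataFormatError(MsResError, ValueError):
    """An on-disk record or label table violates the expected layout."""


class EmptyRecordError(MsResError, ValueError):
    """An operation would leave a record with no samples."""
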