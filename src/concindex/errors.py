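"""Exception hierarchy shared across the package."""


class ConcindexError(Exception):
    """Base class for all package errors."""


class SchemaError(ConcindexError):
    """An input table violates the declared schema (e.g. missing column)."""


class EmptyInputError(ConcindexError):
    """An input table or vector contains no usable rows."""


class ValidationError(ConcindexError):
    """Values violate a domain invariant (weights, probabilities, shares)."""


class MetadataError(ConcindexError):
    """Country metadata is missing or inconsistent with the microdata."""


class DegenerateIndexError(ConcindexError):
    """The concentration index is undefined for this sample
    (zero-mean indicator, mean at a bound, or a single respondent)."""


class ConfigError(ConcindexError):
    """A run configuration is missing keys or holds invalid values."""
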