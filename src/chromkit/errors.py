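"""Exception hierarchy for chromkit.

Every error raised by the library derives from :class:`ChromkitError`, so
callers (notably the CLI) can catch one type and report the stage that
failed.
"""


class ChromkitError(Exception):
    """Base class for all chromkit errors."""


class ValidationError(ChromkitError):
    """A table, experiment, or parameter violates an invariant."""


class ParseError(ChromkitError):
    """An input file does not conform to its dialect."""


class UnsupportedFormatError(ParseError):
    """No known dialect matches the input file."""


class MetadataError(ChromkitError):
    """Required run metadata (flow rate, channel) could not be resolved."""


class DegenerateTraceError(ChromkitError):
    """A trace is flat (or non-positive) over the normalization range."""


class StoreNotFoundError(ChromkitError):
    """Requested document id is absent from the store."""


class SchemaVersionError(ChromkitError):
    """A stored document carries an unknown schema version."""
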