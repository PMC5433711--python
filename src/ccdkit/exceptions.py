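"""Exception hierarchy shared across the package.

All errors derive from :class:`CCDError` so callers can catch the package's
failures with a single except clause while still distinguishing schema
problems from statistical degeneracies.
"""


class CCDError(Exception):
    """Base class for all ccdkit errors."""


class SchemaError(CCDError):
    """Input table violates the expected column schema or value types."""


class NotFoundError(CCDError, KeyError):
    """A requested endpoint, group or label does not exist."""


class ValidationError(CCDError, ValueError):
    """A value or configuration field is outside its allowed domain."""


class SampleSizeError(ValidationError):
    """A sample is too small for the requested statistical operation."""


class DegenerateDataError(ValidationError):
    """Data has zero spread where a test requires positive variance."""
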