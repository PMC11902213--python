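"""Exception hierarchy shared across the package.

Everything derives from :class:`RhizoqError` so callers can catch one base
class; the subclasses mirror the failure modes of each stage (schema/parse
problems on load, invariant violations, bad configuration, degenerate
numerics).
"""


class RhizoqError(Exception):
    """Base class for all package-specific errors."""


class SchemaError(RhizoqError):
    """A required column or field is missing from an input table."""


class ParseError(RhizoqError):
    """A cell could not be parsed; message carries row and column."""


class ValidationError(RhizoqError):
    """An input violates a structural invariant (duplicates, negatives...)."""


class ConfigError(RhizoqError):
    """A configuration value or key is invalid."""


class AlignmentError(RhizoqError):
    """Two inputs that must share labels/shape do not."""


class DomainError(RhizoqError):
    """A numeric argument is outside the operation's domain."""


class DegenerateDataError(RhizoqError):
    """Data is too degenerate for the requested computation
    (constant indicator, singular correlation matrix, too few samples)."""
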