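"""Exception taxonomy for trial data handling and index computation.

Validation problems (bad labels, negative yields, schema mismatches) and
domain problems (zero mono-crop denominators) raise distinct subclasses so
callers — in particular the CLI — can map them to distinct exit codes.
"""


class IntercropError(Exception):
    """Base class for all package errors."""


class SchemaError(IntercropError):
    """Input table is missing required columns or has unusable ones."""


class ValidationError(IntercropError):
    """A record violates the data model (negative value, bad label, ...)."""


class EmptyDatasetError(ValidationError):
    """Input parsed to zero observations."""


class InvalidConfigurationError(ValidationError):
    """A planting pattern is self-contradictory (e.g. zero rows of both crops)."""


class MissingCellError(IntercropError):
    """A required (year, configuration, crop, trait) cell has no observations."""


class DesignError(IntercropError):
    """Experimental design unsuitable for the requested analysis."""


class DomainError(IntercropError):
    """An index formula was called outside its mathematical domain."""
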