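"""Exception hierarchy for panel ingestion and analysis errors."""


class ElderburdenError(Exception):
    """Base class for all package-specific errors."""


class FormatError(ElderburdenError, ValueError):
    """A file does not conform to the expected CSV dialect."""


class ParseError(ElderburdenError, ValueError):
    """A value in an input file could not be parsed."""


class IntegrityError(ElderburdenError, ValueError):
    """Duplicate or internally inconsistent observations."""


class CompletenessError(ElderburdenError, ValueError):
    """A required stratum, year or metric is missing."""


class DomainError(ElderburdenError, ValueError):
    """A value is outside the mathematical domain of an operation."""


class AggregationError(ElderburdenError, ValueError):
    """A stratum cannot be aggregated (missing metric for reconstruction)."""


class JoinError(ElderburdenError, ValueError):
    """Two panels could not be aligned on their keys."""


class ConfigurationError(ElderburdenError, ValueError):
    """Invalid analysis configuration (windows, periods, parameters)."""


class ValidationError(ElderburdenError, ValueError):
    """A synthetic-data specification violates its invariants."""
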