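"""Exception hierarchy for the multistage-incidence pipeline.

Every error raised by the package derives from :class:`MultistageError`,
so callers (and the CLI) can distinguish pipeline failures from bugs.
"""


class MultistageError(Exception):
    """Base class for all package errors."""


class SchemaError(MultistageError):
    """A table is missing a mandatory column or has an invalid layout."""


class RowParseError(MultistageError):
    """A single row of an input table could not be parsed (strict mode)."""


class UndefinedRateError(MultistageError):
    """Incidence rate requested for a band with zero person-years."""


class InsufficientDataError(MultistageError):
    """Fewer than three usable age bands remain; a line cannot be assessed."""


class DegenerateDesignError(MultistageError):
    """All regression abscissae coincide; the slope is unidentifiable."""


class SlopeDomainError(MultistageError):
    """Slope <= -1 implies a non-positive step count: not a multistage fit."""


class MissingGeneticDataError(MultistageError):
    """APOE alleles or variant dosages required for an operation are absent."""


class DegenerateTertilesError(MultistageError):
    """All risk scores identical; tertile boundaries are undefined."""


class ConfigurationError(MultistageError):
    """A simulation or run configuration is invalid or pathological."""
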