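"""Exception hierarchy for the reliability pipeline.

Every error raised by this package derives from :class:`RetestKitError`
so callers can catch pipeline failures without masking programming errors.
"""


class RetestKitError(Exception):
    """Base class for all package errors."""


class SchemaError(RetestKitError):
    """A required column is missing or cannot be resolved from the input."""


class IntegrityError(RetestKitError):
    """The data violate a structural invariant, e.g. duplicate
    (subject, test, day, trial) keys."""


class InsufficientDataError(RetestKitError):
    """Fewer complete cases than the statistic requires."""


class UndefinedIccError(RetestKitError):
    """The ICC denominator is zero; the coefficient is undefined."""


class DomainError(RetestKitError):
    """An argument lies outside the mathematical domain of the operation
    (e.g. ICC outside [0, 1] passed to the SEM, negative SEM)."""


class DegenerateDataError(RetestKitError):
    """The data are degenerate for the requested test (zero variance with a
    nonzero mean difference, constant vector for a normality check, ...)."""


class UndefinedReferenceError(RetestKitError):
    """A MAPE reference value is zero, making the percentage undefined."""


class ConfigError(RetestKitError):
    """A simulation or analysis configuration is invalid."""
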