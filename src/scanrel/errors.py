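"""Exception hierarchy for the reliability pipeline."""


class ScanrelError(Exception):
    """Base class for all package errors."""


class ConfigurationError(ScanrelError):
    """A config file, column map or pipeline option is malformed."""


class ValidationError(ScanrelError):
    """Input data violates a table invariant (positivity, vocabulary, uniqueness)."""


class StateError(ScanrelError):
    """An operation was applied to a table in the wrong state (e.g. double normalization)."""


class InsufficientDataError(ScanrelError):
    """Too few complete subjects or factor levels to fit the requested statistic."""


class UndefinedICCError(ScanrelError):
    """The ICC denominator vanished; the coefficient is undefined for this matrix."""
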