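"""Exception hierarchy for quitcea."""


class QuitCeaError(Exception):
    """Base class for all package-specific errors."""


class ValidationError(QuitCeaError, ValueError):
    """An input value violates a model invariant (range, sum, sign)."""


class ConfigurationError(QuitCeaError, ValueError):
    """A configuration source is unparsable or missing a required key."""


class InfeasibleMomentsError(ValidationError):
    """(mean, se) cannot be matched by the requested distribution family."""


class CoverageError(ValidationError):
    """An age curve does not cover the ages required by a model run."""


class InsufficientDataError(QuitCeaError, ValueError):
    """Too few records to estimate the requested quantity."""
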