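"""Exception hierarchy for the screening pipeline."""


class SepsisScreenError(Exception):
    """Base class for all package errors."""


class ConfigurationError(SepsisScreenError, ValueError):
    """Invalid configuration value (probability out of range, bad correlation...)."""


class DataError(SepsisScreenError, ValueError):
    """Malformed input data (duplicate ids, negative concentrations, length mismatch)."""


class PreconditionError(SepsisScreenError, ValueError):
    """An operation's stated precondition was violated (e.g. null vital at scoring)."""


class DegenerateInputError(SepsisScreenError, ValueError):
    """Statistically degenerate input (single-class labels for ROC)."""


class UnimputableColumnError(SepsisScreenError, ValueError):
    """A column to impute has no observed values at all."""
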