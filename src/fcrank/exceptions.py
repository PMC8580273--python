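"""Package-wide exception types."""


class FcrankError(Exception):
    """Base class for all fcrank errors."""


class InvalidInputError(FcrankError, ValueError):
    """Raised when an input violates a documented precondition."""


class UndefinedMetricError(FcrankError, ValueError):
    """Raised when a metric is requested outside its domain (e.g. q with r* = 0)."""


class UndefinedBayesFactorError(FcrankError, ValueError):
    """Raised when a Bayes factor is undefined (prior probability of 0 or 1)."""


class EmptyOrthantError(FcrankError, ValueError):
    """Raised when no posterior draw lies in the requested orthant."""


class ConvergenceError(FcrankError, RuntimeError):
    """Raised when MCMC diagnostics exceed their thresholds.

    Attributes
    ----------
    offending : dict
        Map from parameter name to its split-Rhat, for every parameter
        above the configured threshold.
    """

    def __init__(self, message: str, offending: dict | None = None):
        super().__init__(message)
        self.offending = offending or {}
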