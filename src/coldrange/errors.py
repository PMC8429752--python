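"""Exception hierarchy shared across the package."""


class ColdRangeError(Exception):
    """Base class for all package errors."""


class InvalidInputError(ColdRangeError, ValueError):
    """An argument violates a documented precondition."""


class CoverageError(ColdRangeError, ValueError):
    """A temperature series does not cover the requested window.

    Raised when the fraction of missing days inside a window exceeds the
    configured gap tolerance, or when the window extends beyond the record.
    """


class FitFailureError(ColdRangeError, RuntimeError):
    """A model fit failed to converge after all restarts.

    Carries the diagnostics of the best attempt in ``best_attempt``.
    """

    def __init__(self, message: str, best_attempt=None):
        super().__init__(message)
        self.best_attempt = best_attempt
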