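"""Exception hierarchy.

Exit codes (used by the CLI): 2 = validation/config error, 3 = data error,
4 = fit/convergence error, 1 = anything else.
"""


class DropfretError(Exception):
    """Base class for all package errors."""

    exit_code = 1


class InvalidParameterError(DropfretError, ValueError):
    """A parameter violates its documented domain (non-finite, wrong sign...)."""

    exit_code = 2


class ConfigError(DropfretError, ValueError):
    """Pipeline configuration failed schema validation."""

    exit_code = 2


class DataError(DropfretError, ValueError):
    """Input data violate a precondition (shape, emptiness, missing window...)."""

    exit_code = 3


class StitchError(DataError):
    """Window stitching failed (missing window, empty overlap)."""


class FitError(DropfretError, RuntimeError):
    """A nonlinear fit failed to converge.

    Carries the best attempt (if any) in :attr:`best_attempt`.
    """

    exit_code = 4

    def __init__(self, message, best_attempt=None):
        super().__init__(message)
        self.best_attempt = best_attempt


class IntegrationError(DropfretError, RuntimeError):
    """The ODE integrator failed; diagnostics in the message."""

    exit_code = 4
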