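"""Exception hierarchy shared across the package.

The split mirrors how failures are surfaced to a user: bad numbers in
(``DomainError``), bad measured data (``DataError``), bad configuration
(``ConfigurationError``), a regression that could not be carried out
(``EstimationError``) and an integrator breakdown (``SolverError``).
"""


class FiberchromError(Exception):
    """Base class for all package-specific errors."""


class DomainError(FiberchromError, ValueError):
    """An argument violates a mathematical precondition (e.g. negative concentration)."""


class RangeError(FiberchromError, ValueError):
    """A parameter evaluated outside its declared validity range."""


class DataError(FiberchromError, ValueError):
    """Measured/tabulated input is inconsistent or unphysical."""


class ConfigurationError(FiberchromError, ValueError):
    """A configuration block is malformed, incomplete or contradictory."""


class EstimationError(FiberchromError, RuntimeError):
    """A regression or fit failed to converge or is under-determined.

    Carries the last iterate when available so a caller can diagnose.
    """

    def __init__(self, message: str, last_iterate=None):
        super().__init__(message)
        self.last_iterate = last_iterate


class SolverError(FiberchromError, RuntimeError):
    """Time integration of the column model failed.

    ``t_failure`` holds the integrator time at which the failure occurred,
    ``diagnostics`` a free-form dict of state information.
    """

    def __init__(self, message: str, t_failure=None, diagnostics=None):
        super().__init__(message)
        self.t_failure = t_failure
        self.diagnostics = diagnostics or {}
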