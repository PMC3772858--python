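"""Exception hierarchy for cvpop."""


class CvpopError(Exception):
    """Base class for all cvpop errors."""


class ConfigurationError(CvpopError):
    """Invalid parameter or configuration value; names the offending field."""


class DomainError(CvpopError, ValueError):
    """An operation was called with an argument outside its physical domain."""


class SolverError(CvpopError):
    """The circulatory equilibrium solver failed to converge.

    Carries the residual history for post-mortem inspection.
    """

    def __init__(self, message, residuals=None):
        super().__init__(message)
        self.residuals = list(residuals or [])


class SimulationError(CvpopError):
    """Time integration failed (e.g. ECFV driven non-positive); carries the time stamp."""

    def __init__(self, message, t=None):
        super().__init__(message)
        self.t = t


class SteadyStateError(CvpopError):
    """No admissible steady state exists for a parameter set.

    The calibration layer treats this as likelihood zero.
    """


class DataError(CvpopError):
    """Input data are unusable (too few samples, degenerate, missing columns)."""


class ScreenError(CvpopError):
    """The sensitivity screen failed (too many unsolvable draws for a parameter)."""
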