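"""Exception hierarchy for the mgm package."""


class MGMError(Exception):
    """Base class for all model errors raised by this package."""


class DomainError(MGMError, ValueError):
    """An argument lies outside the physical/mathematical domain of an operation."""


class InvalidCompositionError(DomainError):
    """Tissue composition fractions are inconsistent (e.g. f_CP + f_L > 1)."""


class ConfigurationError(MGMError):
    """A parameter set or user-supplied hook violates its contract."""


class SingularMaintenanceError(MGMError):
    """The negotiable-maintenance denominator reached zero or below.

    The defence fraction rho = a_N * W^b_N * phi^delta must stay strictly
    below 1; at rho -> 1 the maintenance cost diverges.  The error message
    names the offending mass so the caller can diagnose the parameter set.
    """


class NoUltimateMassError(MGMError):
    """No positive root of the growth rate exists under the given parameters.

    Raised both for indefinite growth (supply always exceeds expenditure on
    the searched range) and for immediate decline (expenditure already
    exceeds supply at the starting mass).
    """


class IncompleteTrajectoryError(MGMError):
    """A trajectory ends before the quantity of interest (e.g. W95) is reached."""


class IntegrationError(MGMError):
    """The ODE solver failed or terminated abnormally."""


class FitFailureError(MGMError):
    """No optimizer start converged to a usable parameter estimate."""
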