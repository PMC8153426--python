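"""Exception and warning types shared across the package."""


class FormstressError(Exception):
    """Base class for all package-specific errors."""


class ValidationError(FormstressError, ValueError):
    """Input violates a documented precondition."""


class UnitMismatchError(ValidationError):
    """Quantities in different units were combined without conversion."""


class UnresolvableSeriesError(FormstressError):
    """A dilution series has no countable endpoint (TNTC at the highest dilution)."""


class UndefinedBaselineError(FormstressError):
    """The 0 mM (formaldehyde-free) baseline CFU count is zero or censored."""


class CensoredCompetitionError(FormstressError):
    """A competition reached fixation (fraction exactly 0 or 1); W is undefined."""


class DomainError(FormstressError):
    """Parameter combination outside the mathematical domain of a formula."""


class FitConvergenceError(FormstressError):
    """Nonlinear least squares failed to converge."""


class FlatCurveError(FitConvergenceError):
    """A dose-response fit was attempted on a constant (flat) signal."""


class ConfigError(FormstressError):
    """Pipeline configuration is invalid (unknown stage, missing input...)."""


class NearFixationWarning(UserWarning):
    """A competition fraction is very close to 0 or 1; W will be noisy."""


class LowEventCountWarning(UserWarning):
    """Fewer cytometry events than the assay's counting floor (1,000)."""


class DegenerateFitWarning(UserWarning):
    """A slope comparison involved fits with zero standard error."""


class UnidentifiableKdWarning(UserWarning):
    """The binding data do not constrain Kd (flat or saturated isotherm)."""


class NoGrowthWarning(UserWarning):
    """No positive-slope window was found in a growth curve."""
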