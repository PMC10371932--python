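"""Exception hierarchy."""


class SpectriskError(Exception):
    """Base class for all package errors."""


class CohortError(SpectriskError, ValueError):
    """Invalid cohort table: missing columns, missing values, or invariant violations."""


class ModelSpecError(SpectriskError, ValueError):
    """Malformed model specification or unresolvable covariate reference."""


class ValidationInputError(SpectriskError, ValueError):
    """A statistic's preconditions are not met (empty input, bad span, too few bins...)."""


class DegenerateStatisticError(ValidationInputError):
    """The statistic is undefined on this sample (e.g. a single outcome class).

    Bootstrap resampling catches this error and redraws the resample.
    """


class ConvergenceError(SpectriskError, RuntimeError):
    """Maximum-likelihood fit failed to converge or the score equations are unsatisfied."""


class ConfigError(SpectriskError, ValueError):
    """Invalid simulation or run configuration."""
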