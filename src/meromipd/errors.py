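"""Exception hierarchy for meromipd."""


class MeromipdError(Exception):
    """Base class for all package-specific errors."""


class InvalidCovariateError(MeromipdError, ValueError):
    """A covariate value is missing, non-positive, or otherwise unusable."""


class MissingCovariateError(InvalidCovariateError):
    """A model relation requires a covariate the patient record does not carry."""


class ConfigurationError(MeromipdError, ValueError):
    """A model specification or method option is inconsistent."""


class DomainError(MeromipdError, ValueError):
    """An input lies outside the mathematical domain of an operation."""


class DesignError(MeromipdError, ValueError):
    """A cohort or study design is infeasible as configured."""


class InsufficientDataError(MeromipdError, ValueError):
    """Too few observations to compute the requested statistic."""


class NumericalError(MeromipdError, RuntimeError):
    """A numerical routine (integrator, optimizer) failed with diagnostics."""
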