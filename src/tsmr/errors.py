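"""Exception hierarchy shared across the package."""


class TsmrError(Exception):
    """Base class for all package errors."""


class ConfigurationError(TsmrError):
    """A config file, column map, or analysis setting is unusable."""


class ValidationError(TsmrError):
    """Input data violate a documented invariant (bad SE, frequency, ...)."""


class HarmonizationError(TsmrError):
    """Exposure and outcome summary statistics cannot be aligned."""


class EstimationError(TsmrError):
    """An estimator's preconditions are not met (too few SNPs, zero weights)."""
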