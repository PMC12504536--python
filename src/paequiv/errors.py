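"""Exception hierarchy for the equivalence pipeline."""


class PAEquivError(Exception):
    """Base class for all package errors."""


class ConfigurationError(PAEquivError):
    """A scenario or analysis configuration is internally inconsistent."""


class ArgumentError(PAEquivError, ValueError):
    """An operation received an invalid argument."""


class DesignError(PAEquivError):
    """The model design matrix is unusable (e.g. rank deficient)."""


class EstimationError(PAEquivError):
    """A model fit or derived estimate could not be computed."""


class PipelineError(PAEquivError):
    """A pipeline stage produced an unusable state (e.g. empty cohort)."""
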