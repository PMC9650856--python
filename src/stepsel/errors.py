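"""Exception hierarchy shared across the pipeline stages."""


class StepselError(Exception):
    """Base class for all pipeline errors."""


class ConfigurationError(StepselError):
    """A parameter or input file is mis-specified (missing column, bad interval...)."""


class DataError(StepselError):
    """Input data violate an invariant (unparseable timestamps, pre-release fixes...)."""


class DegenerateDataError(DataError):
    """Data carry no information for the requested fit (zero variance, constant column)."""


class CoverageError(DataError):
    """A timestamp or point falls outside the landscape's spatial or temporal coverage."""


class ConvergenceError(StepselError):
    """An iterative fit failed to reach its tolerance within the iteration budget."""


class SeparationError(ConvergenceError):
    """A covariate perfectly predicts the used step; the partial likelihood is unbounded."""
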