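"""Exception hierarchy for the model pipeline."""


class CoilCeaError(Exception):
    """Base class for all package errors."""


class SchemaError(CoilCeaError):
    """A parameter table or config file violates its schema."""


class InfeasibleMomentsError(CoilCeaError):
    """Printed (mean, SE) cannot be matched by the requested family."""


class DegenerateProbabilityError(CoilCeaError):
    """A probability of 1 cannot be rescaled to a different time base."""


class SamplingFailureError(CoilCeaError):
    """Ordered-group rejection sampling exhausted its retry budget."""


class InfeasibleDrawError(CoilCeaError):
    """A sampled parameter set implies negative residual probabilities."""


class UndefinedICERError(CoilCeaError):
    """Incremental QALYs are zero; the ICER is undefined."""


class DegenerateFitError(CoilCeaError):
    """A through-origin fit was requested on points with no x variation."""


class ValidationError(CoilCeaError):
    """A configuration value is out of range or unknown."""
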