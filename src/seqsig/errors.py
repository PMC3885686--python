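"""Exception types shared across the package."""


class SeqsigError(Exception):
    """Base class for package errors."""


class InvalidArgumentError(SeqsigError, ValueError):
    """An argument violates a documented precondition."""


class CalibrationError(SeqsigError, RuntimeError):
    """An iterative calibration (effect size, censoring rate) failed."""


class NormalizationError(SeqsigError, RuntimeError):
    """Median-of-ratios size factors cannot be computed."""


class EmptyMatrixError(SeqsigError, RuntimeError):
    """A filtering step removed every gene."""


class ConstantGeneError(SeqsigError, ValueError):
    """A per-gene operation hit a zero-variance gene."""


class VSTError(SeqsigError, RuntimeError):
    """The mean-variance trend fit for the VST is degenerate."""


class DivergenceError(SeqsigError, RuntimeError):
    """A model fit produced a non-finite likelihood."""


class OptimizationError(SeqsigError, RuntimeError):
    """A convex solver failed to converge or violates KKT conditions."""
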