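"""Exception hierarchy.

Validation errors signal bad user input (exit code 1 in the CLI); the
remaining errors signal runtime/modelling failures (exit code 2).
"""


class RvburdenError(Exception):
    """Base class for all package errors."""


class ValidationError(RvburdenError, ValueError):
    """Invalid parameter or malformed input."""


class ParameterError(ValidationError):
    """A numeric parameter is outside its admissible range."""


class AnnotationError(RvburdenError):
    """A variant annotation is inconsistent with its transcript model."""


class CovariateError(ValidationError):
    """A covariate column is missing, constant, or collinear."""

    def __init__(self, column: str, message: str):
        self.column = column
        super().__init__(f"covariate {column!r}: {message}")


class ZeroCarrierError(RvburdenError):
    """Gene has no carriers; burden tests require at least one carrier."""


class ScanError(RvburdenError):
    """A genome scan restriction left no usable samples."""


class SimulationError(RvburdenError):
    """Cohort sampling could not satisfy the requested quotas."""


class AnchorError(RvburdenError):
    """Anchor gene z-scores do not define valid meta-analysis weights."""


class UndefinedEstimateError(RvburdenError):
    """An estimator's denominator is zero (no information in the data)."""


class DomainError(RvburdenError):
    """A formula was evaluated outside its mathematical domain."""


class FitError(RvburdenError):
    """Numerical optimization failed at every starting point."""


class PipelineError(RvburdenError):
    """A pipeline stage failed; the message names the stage."""
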