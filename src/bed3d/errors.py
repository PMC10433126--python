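"""Exception hierarchy.

Validation-type errors (bad inputs, bad config) and computation-type errors
(a stage failed on valid-looking input) are kept on separate branches so the
CLI can map them to distinct exit codes.
"""


class Bed3dError(Exception):
    """Base class for all package errors."""


class ValidationError(Bed3dError):
    """Invalid input data, parameters, or configuration."""


class ComputationError(Bed3dError):
    """A computation stage failed."""


class InsufficientDataError(ValidationError):
    """Too few samples to support the requested number of fit terms."""


class ProfileShapeError(ComputationError):
    """A profile does not have the expected peaked, two-sided falloff shape."""


class FitFailureError(ComputationError):
    """Curve fitting failed to converge at every term count tried."""

    def __init__(self, message: str, best_rmse: float | None = None):
        super().__init__(message)
        self.best_rmse = best_rmse


class LevelGridError(ComputationError):
    """Per-axis profiles do not share an overlapping range of iso-dose levels."""


class ConfigurationError(ValidationError):
    """Missing or inconsistent configuration (e.g. no model for a collimator)."""


class ZeroDoseError(ComputationError):
    """The interaction factor is undefined for an all-zero dose vector."""


class ShapeMismatchError(ValidationError):
    """Grid and mask (or companion arrays) have different shapes."""


class UndefinedMetricError(ComputationError):
    """A plan-quality metric is undefined (e.g. empty prescription volume)."""


class EmptyMeshError(ComputationError):
    """Requested iso-level lies outside the range of the scalar field."""


class VersionMismatchError(ValidationError):
    """A serialized artifact was written by an incompatible format version."""
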