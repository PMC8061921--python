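"""Exception hierarchy.

All package errors derive from :class:`MPIFlowError` so callers can catch
one base class; most also derive from the closest builtin so that generic
``except ValueError`` code keeps working.
"""


class MPIFlowError(Exception):
    """Base class for all mpiflow errors."""


class InvalidGeometryError(MPIFlowError, ValueError):
    """Non-positive diameter, stenosis wider than the tube, etc."""


class DomainError(MPIFlowError, ValueError):
    """An argument outside the mathematical domain of an operation."""


class EmptyInputError(MPIFlowError, ValueError):
    """A sequence or series that must be non-empty is empty."""


class TruncatedBolusError(MPIFlowError):
    """The record ends before the bolus transit is complete, or the
    half/33%-of-maximum crossings needed by an estimator do not exist."""


class OnsetDetectionError(MPIFlowError):
    """No onset crossing found before the intensity peak."""


class BaselineStateError(MPIFlowError, RuntimeError):
    """An operation requiring baseline state was called before
    :func:`mpiflow.curves.estimate_baseline`."""


class InvalidWindowError(MPIFlowError, ValueError):
    """A baseline window that is empty or overlaps the bolus peak."""


class InsufficientSeriesError(MPIFlowError, ValueError):
    """Leave-one-out calibration needs at least two measurements."""


class CalibrationMismatchError(MPIFlowError, ValueError):
    """A calibration factor applied to raw statistics of another method."""


class FormatError(MPIFlowError, ValueError):
    """A file missing required structure or metadata."""


class ConfigError(MPIFlowError, ValueError):
    """An invalid run configuration."""


class QCFailureError(MPIFlowError):
    """Every bolus in a series failed quality control."""
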