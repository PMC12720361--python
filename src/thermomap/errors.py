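"""Exception and warning types shared across the toolkit."""


class ThermomapError(Exception):
    """Base class for all errors raised by thermomap."""


class InvalidInputError(ThermomapError, ValueError):
    """Input violates a documented precondition (non-finite, empty, out of domain)."""


class InvalidDepthError(InvalidInputError):
    """A working depth that is not strictly positive."""


class ConvergenceError(ThermomapError, RuntimeError):
    """An iterative solver failed to reach its tolerance."""


class ProjectionError(ThermomapError, ValueError):
    """A 3D point cannot be projected (at or behind the camera plane)."""


class InsufficientDataError(ThermomapError, ValueError):
    """Too few observations for the requested estimation."""


class ShapeError(ThermomapError, ValueError):
    """Array dimensions do not match the contract."""


class LabelError(ThermomapError, ValueError):
    """A label code outside the declared class table."""


class EmptyMaskError(ThermomapError, ValueError):
    """A binary mask required to be non-empty has no set pixels."""


class EmptyEvaluationError(ThermomapError, ValueError):
    """A confusion matrix with zero evaluated pixels."""


class EmptyROIError(ThermomapError, ValueError):
    """Every region of an ROISet is empty where at least one is required."""


class UnmappedColorError(ThermomapError, ValueError):
    """A scene color not present in the declared color table."""

    def __init__(self, colors):
        self.colors = list(colors)
        super().__init__(f"colors not in the declared table: {self.colors}")


class PlacementError(ThermomapError, RuntimeError):
    """Failed to place a synthetic checkerboard pose visible in both channels."""


class ConditioningWarning(UserWarning):
    """Near-degenerate pose geometry; calibration result is best-effort."""


class DegenerateContourWarning(UserWarning):
    """A contour with fewer than 3 points cannot be filled."""


class PrincipalPointWarning(UserWarning):
    """Principal point lies outside the image bounds."""


class TemperatureRangeWarning(UserWarning):
    """Temperatures outside the plausible [-20, 80] degC range."""


class RegionOverlapWarning(UserWarning):
    """Generated region templates overlap beyond the configured fraction."""


class EmptyRegionWarning(UserWarning):
    """A region requested for statistics has an empty mask."""
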