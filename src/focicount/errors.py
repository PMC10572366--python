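"""Exception hierarchy for the foci-counting pipeline."""


class FociCountError(Exception):
    """Base class for all package errors."""


class ImageReadError(FociCountError):
    """The input file could not be read or has an unsupported format."""


class UnsupportedDimensionalityError(ImageReadError):
    """The image has more than one z-plane or time point (2-D single-plane only)."""


class MissingCalibrationError(FociCountError):
    """No pixel-size metadata in the file and no override supplied."""


class RoleAssignmentError(FociCountError):
    """No channel could be assigned the nucleus role."""


class RoleConflictError(FociCountError):
    """Two channels claim the same role."""


class DegenerateHistogramError(FociCountError):
    """The histogram spans fewer than two distinct intensities."""


class ShapeMismatchError(FociCountError):
    """Two grids that must share dimensions do not."""


class ValidationError(FociCountError):
    """A run parameter is outside its valid range."""
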