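"""Exception hierarchy for the analysis pipeline.

Every stage raises a subclass of :class:`CorvibError`, so callers (and the
CLI) can distinguish pipeline failures from programming errors.
"""


class CorvibError(Exception):
    """Base class for all pipeline errors."""


class NoFramesError(CorvibError):
    """Input directory or video contains no frames."""


class ShapeMismatchError(CorvibError):
    """Frames in a sequence do not share a common shape."""


class InvalidCalibrationError(CorvibError):
    """Calibration with non-positive row/column counts or field sizes."""


class NoCorneaFoundError(CorvibError):
    """No column of a frame yields a corneal-edge candidate."""


class ContourUnreliableError(CorvibError):
    """Too many columns failed edge detection in a frame."""


class NoDeformationEventError(CorvibError):
    """Deformation never exceeds the binarization threshold p_r."""


class InsufficientFramesError(CorvibError):
    """Series too short for the requested operation."""


class NoHarmonicError(CorvibError):
    """Spectral analysis of an (effectively) constant trace."""
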