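"""Exception hierarchy.

Distinct error identities so callers can react to each failure mode
(missing file, wrong dimensionality, label-code violations, ...) without
string matching.
"""


class SliceFillError(Exception):
    """Base class for all package errors."""


class Non3DImageError(SliceFillError, ValueError):
    """Input image is not a 3D scalar volume."""


class UnsupportedFormatError(SliceFillError, ValueError):
    """File extension not among the supported volume formats."""


class ShapeMismatchError(SliceFillError, ValueError):
    """Two arrays/images that must be aligned have different shapes."""


class UnknownLabelError(SliceFillError, ValueError):
    """A label map contains codes outside the allowed set."""


class GeometryError(SliceFillError, ValueError):
    """Phantom geometry does not fit inside the volume or is degenerate."""


class ScheduleError(SliceFillError, ValueError):
    """Invalid gap-schedule parameters."""


class CalibrationError(SliceFillError, ValueError):
    """Rater-perturbation calibration target unreachable."""


class EmptyEvaluationError(SliceFillError, ValueError):
    """Dice evaluation requested over an empty voxel/slice domain."""
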