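"""Exception hierarchy.

Everything raised intentionally by this package derives from
:class:`PulmoquantError`, so callers (and the CLI) can distinguish bad data
from programming errors.
"""


class PulmoquantError(Exception):
    """Base class for all pulmoquant errors."""


class GridSizingError(PulmoquantError):
    """Phantom grid too small to contain the requested anatomy."""


class CalibrationError(PulmoquantError):
    """Degenerate Hounsfield calibration (air and water references equal)."""


class DegenerateGeometryError(PulmoquantError):
    """Landmark configuration unusable for a rigid fit (< 3 points or collinear)."""


class PairingError(PulmoquantError):
    """Landmark names do not pair up between the moving and fixed sets."""


class RoiError(PulmoquantError):
    """ROI resolves to no voxels, lies outside the grid, or a quadrant is empty."""


class FormatError(PulmoquantError):
    """Malformed input file (missing column, missing spacing, bad header)."""


class StatisticsError(PulmoquantError):
    """Statistical operation undefined for the given input (constant vector, n too small)."""


class DoseModelError(PulmoquantError):
    """Invalid dosimetry parameters."""


class PipelineError(PulmoquantError):
    """A pipeline stage failed; the message names the stage."""
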