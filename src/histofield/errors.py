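"""Exception types shared across the package."""


class HistofieldError(ValueError):
    """Base class for all histofield errors."""


class CoordinateError(HistofieldError):
    """A point coordinate lies outside the image bounds."""


class PlacementError(HistofieldError):
    """Random blob placement could not satisfy the separation constraints."""


class ShapeMismatchError(HistofieldError):
    """Two grids that must share a shape do not."""


class DegenerateFieldError(HistofieldError):
    """A field is constant (or otherwise degenerate) where variation is required."""


class EmptySampleError(HistofieldError):
    """No pixel pairs survived thresholding."""


class UndefinedStatisticError(HistofieldError):
    """A statistic is undefined for the given input (zero variance, all-zero field)."""


class FieldStateError(HistofieldError):
    """A field is in the wrong normalization state for the requested operation."""


class MetadataError(HistofieldError):
    """A field file is missing or has an inconsistent metadata sidecar."""
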