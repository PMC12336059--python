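"""Exception hierarchy used across the package."""


class CvrQuantError(Exception):
    """Base class for all cvrquant errors."""


class ParameterError(CvrQuantError, ValueError):
    """Invalid parameter value (non-positive duration, SD < 0, ...)."""


class ShapeError(CvrQuantError, ValueError):
    """Array shapes or lengths are inconsistent."""


class SignalQualityError(CvrQuantError):
    """Signal too degraded to process (e.g. fewer than 3 detected breaths)."""


class DomainError(CvrQuantError, ValueError):
    """Value outside the admissible domain of a model (e.g. T2 outside the
    range mapped by the oximetry calibration)."""


class AlignmentError(CvrQuantError):
    """Time-shift alignment is undefined (constant or uncorrelated signal)."""


class FitError(CvrQuantError):
    """A nonlinear fit failed to converge."""
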