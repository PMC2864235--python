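"""Exception hierarchy for the pipeline.

Every stage raises a subclass of :class:`SkelopodError` so callers can
distinguish pipeline failures from programming errors.
"""


class SkelopodError(Exception):
    """Base class for all pipeline errors."""


class NoCellFound(SkelopodError):
    """Segmentation produced no foreground component above the minimum area."""


class DegenerateShape(SkelopodError):
    """A mask or contour is too small to support boundary/skeleton analysis."""


class FitDiverged(SkelopodError):
    """The B-spline boundary fit moved away from the data for 3 iterations."""


class NonConvergence(SkelopodError):
    """An iterative routine hit its iteration cap before reaching tolerance."""


class NoIntersection(SkelopodError):
    """A branch extension ray failed to cross the required region/boundary."""


class InsufficientData(SkelopodError):
    """Not enough samples for a statistical fit."""


class DegenerateInput(SkelopodError):
    """An input matrix has zero variance (correlation undefined)."""


class OverlapError(SkelopodError):
    """Two scripted pseudopod events intersect in the synthetic generator."""
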