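"""Exception hierarchy for spatialmargin."""


class SpatialMarginError(Exception):
    """Base class for all package errors."""


class ParameterError(SpatialMarginError, ValueError):
    """Invalid parameter value (counts, fractions, block ranges ...)."""


class SceneError(SpatialMarginError, ValueError):
    """A simulation scene violates its invariants (e.g. edge clearance)."""


class InputError(SpatialMarginError, ValueError):
    """Malformed input data (negative abundances, bad files ...)."""


class GeometryError(SpatialMarginError, ValueError):
    """Degenerate or self-intersecting geometry."""


class NoRegionFound(SpatialMarginError, RuntimeError):
    """Border detection produced no closed tumor region."""
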