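"""Exception hierarchy for ommaquant.

All package-specific failures derive from :class:`OmmaquantError` so callers
can catch the whole family with one clause while argument-validation errors
remain ordinary ``ValueError`` subclasses.
"""


class OmmaquantError(Exception):
    """Base class for all ommaquant-specific errors."""


class SaturationError(OmmaquantError, RuntimeError):
    """Hard-core placement could not reach the requested point count.

    Attributes
    ----------
    requested, achieved : int
        Number of points asked for and number actually placed before the
        attempt budget ran out.
    """

    def __init__(self, requested: int, achieved: int, max_attempts: int):
        self.requested = requested
        self.achieved = achieved
        self.max_attempts = max_attempts
        super().__init__(
            f"hard-core placement saturated: placed {achieved}/{requested} "
            f"points within {max_attempts} attempts"
        )


class InsufficientDataError(OmmaquantError, ValueError):
    """Too few observations for the requested computation."""


class BinningMismatchError(OmmaquantError, ValueError):
    """Two curves do not share identical radial binning."""


class InitializationError(OmmaquantError, ValueError):
    """A curve lacks the structure needed to seed a model fit."""


class UndefinedScoreError(OmmaquantError, ValueError):
    """A score (e.g. R-squared against a constant curve) is undefined."""


class GeometryError(OmmaquantError, ValueError):
    """A polygon is degenerate or self-intersecting."""


class ValidationError(OmmaquantError, ValueError):
    """Tabular input violates its schema (unknown labels, bad counts...)."""
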