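"""Exception hierarchy for vaxdyn."""


class VaxdynError(Exception):
    """Base class for all vaxdyn errors."""


class InvalidAnchorError(VaxdynError, ValueError):
    """Curve anchors out of range or out of order (requires 0 <= p0 <= p1 <= 1)."""


class DegenerateCurveError(VaxdynError, ValueError):
    """Curve parameters make the curve ill-defined (e.g. sigma <= 0)."""


class DegenerateContinuumError(VaxdynError, ValueError):
    """Curve is indistinguishable from the 45-degree line on most of the grid,
    so its fixed points form a continuum rather than isolated points."""


class RegimeOrderingError(VaxdynError, ValueError):
    """Voluntary curve falls below the enforced curve somewhere on the check grid."""


class InvalidConfigError(VaxdynError, ValueError):
    """Configuration failed validation."""


class CalibrationError(VaxdynError, RuntimeError):
    """Cutpoint calibration could not meet its targets."""


class EmptyPanelError(VaxdynError, ValueError):
    """Panel has no usable rows."""


class UnmatchedRespondentError(VaxdynError, ValueError):
    """A respondent is missing one of the two waves."""


class RankDeficiencyError(VaxdynError, ValueError):
    """Design matrix is rank deficient; carries the offending predictor name."""

    def __init__(self, predictor: str, message: str | None = None):
        self.predictor = predictor
        super().__init__(message or f"rank-deficient design: predictor {predictor!r}")


class InsufficientDataError(VaxdynError, ValueError):
    """Too few complete cases to fit the requested model."""
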