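"""Exception hierarchy for relcal.

Every error raised by the package derives from :class:`RelcalError` so callers
can catch calibration problems without also swallowing programming errors.
"""


class RelcalError(Exception):
    """Base class for all relcal errors."""


class InvalidProfileError(RelcalError):
    """A subject profile violates a physiological invariant
    (e.g. HRmax <= HRrest, non-positive VO2max)."""


class StageUnusableError(RelcalError):
    """A calibration stage has too few recorded minutes to summarise."""


class InsufficientCalibrationDataError(RelcalError):
    """Fewer than the required number of usable stages are available."""


class SingularFitError(RelcalError):
    """The regressor has zero variance; the least-squares fit is singular."""


class CalibrationFailureError(RelcalError):
    """The fitted relation is physiologically implausible
    (negative slope used for prediction, or a non-positive cutpoint)."""


class EmptySeriesError(RelcalError):
    """An epoch series with no epochs was supplied."""


class ParseError(RelcalError):
    """A file could not be parsed; carries the offending line number."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


class AlignmentError(RelcalError):
    """Heart-rate and count series share no overlapping minutes."""


class ComparisonError(RelcalError):
    """Too few usable groups for a between-group comparison."""


class UndefinedCorrelationError(RelcalError):
    """A correlation is undefined because one variable has zero variance."""
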