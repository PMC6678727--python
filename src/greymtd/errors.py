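"""Exception hierarchy for grey-model construction and evaluation.

Every failure mode raised by the library derives from :class:`GreyModelError`
so callers (and the CLI) can catch one base class and still discriminate the
cause when they need to.
"""


class GreyModelError(Exception):
    """Base class for all errors raised by this package."""


class EmptySeriesError(GreyModelError):
    """An operation received a series with no observations."""


class DegenerateDataError(GreyModelError):
    """The data admit no diffusion profile (e.g. a constant series, or every
    observation sitting exactly at the central location)."""


class InsufficientDataError(GreyModelError):
    """Fewer observations than the grey-modeling minimum (four) were given."""


class SingularSystemError(GreyModelError):
    """The least-squares design matrix is rank deficient (constant
    background values)."""


class NearZeroDevelopmentError(GreyModelError):
    """|a| is below the numerical threshold; the time-response form divides
    by a and would be meaningless."""


class SeriesParseError(GreyModelError):
    """A delimited input file violated the expected two-column dialect."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)
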