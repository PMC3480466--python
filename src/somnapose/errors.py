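"""Exception hierarchy for somnapose.

All exceptions raised by the package derive from :class:`SomnaposeError`
so that callers (and the CLI) can catch them uniformly.
"""


class SomnaposeError(Exception):
    """Base class for all somnapose errors."""


class FormatError(SomnaposeError):
    """A file does not follow the expected layout (e.g. missing channel)."""


class ParseError(SomnaposeError):
    """A cell or field could not be parsed; carries the offending row."""

    def __init__(self, message: str, row: int | None = None):
        super().__init__(message)
        self.row = row


class ValidationError(SomnaposeError):
    """A domain invariant is violated (lengths, ranges, finiteness)."""


class FittingError(SomnaposeError):
    """Threshold fitting cannot proceed (single class, too few samples)."""


class UndefinedMeanError(SomnaposeError):
    """Circular mean requested for an (anti)podal set with vanishing resultant."""


class UndefinedAngleError(SomnaposeError):
    """Orientation angle ill-conditioned (gravity nearly along the long axis)."""
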