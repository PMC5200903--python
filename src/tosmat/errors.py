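"""Exception hierarchy for tosmat."""


class TosmatError(Exception):
    """Base class for all tosmat errors."""


class InvalidFractionError(TosmatError, ValueError):
    """Selected fraction outside the open interval (0, 1)."""


class DegenerateCellError(TosmatError, ValueError):
    """Cell has fewer than two pixels or otherwise unusable data."""


class IncompatibleSelectionError(TosmatError, ValueError):
    """Two threshold selections do not come from the same pixel population."""


class UndefinedCorrelationError(TosmatError, ValueError):
    """Correlation undefined (zero variance in at least one channel)."""


class UndefinedCoefficientError(TosmatError, ValueError):
    """Manders coefficient undefined (empty denominator set)."""


class InvalidInputError(TosmatError, ValueError):
    """Generic invalid input (empty samples, empty cohorts, ...)."""


class ImageFormatError(TosmatError, ValueError):
    """Unreadable or unsupported image / ROI file."""
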