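"""Exception hierarchy shared across the package."""


class ShesdError(Exception):
    """Base class for all package-specific errors."""


class ParseError(ShesdError):
    """Malformed input row, duplicate date, or otherwise unreadable file."""


class GapError(ShesdError):
    """Series has missing calendar days and gaps were not explicitly allowed."""


class NegativeCountError(ShesdError):
    """Count below zero (or below -0.5 for a jittered series)."""


class OrderError(ShesdError):
    """Date interval given with start after end."""


class EmptyInputError(ShesdError):
    """Operation requires at least one value."""


class DegenerateError(ShesdError):
    """Too few values after trimming, or a zero-spread window."""


class WindowError(ShesdError):
    """Rolling window is even or larger than the series."""


class ShortSeriesError(ShesdError):
    """Series shorter than the minimum length for the operation."""


class ShortInputError(ShesdError):
    """Value sequence shorter than the minimum length for the test."""


class AlignmentError(ShesdError):
    """Decomposition components do not align with the series."""


class DomainError(ShesdError):
    """Parameter outside the mathematical domain of the statistic."""


class ZeroMADError(ShesdError):
    """Median absolute deviation is zero; the studentized test is undefined.

    Arises when more than half of the values are identical, typical of
    low-count discrete series. The jitter extension exists for this case.
    """


class AlreadyJitteredError(ShesdError):
    """Jitter requested on a series that already carries jitter noise."""


class FitError(ShesdError):
    """Regression model failed to converge or produced invalid predictions."""


class SpecError(ShesdError):
    """Synthetic-series specification is internally inconsistent."""


class PlacementError(ShesdError):
    """Anomaly placement constraints cannot be satisfied."""


class RangeMismatchError(ShesdError):
    """Truth dates fall outside the detector report's date range."""
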