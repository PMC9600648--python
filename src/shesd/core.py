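"""Dated count series, calendar arithmetic, and robust summary statistics.

The central container is :class:`DailyCountSeries`: a contiguous run of
calendar days with one non-negative count per day (hospital admissions,
readmissions, or any daily event count).  Counts are stored as floats so that
a jittered series -- integers perturbed by uniform noise strictly inside
(-0.5, 0.5), used to rescue the median absolute deviation on highly discrete
series -- can reuse the same type; the ``jittered`` flag records which kind a
series is.
"""

from __future__ import annotations

import csv
import datetime as dt
import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .errors import (
    DegenerateError,
    EmptyInputError,
    GapError,
    NegativeCountError,
    OrderError,
    ParseError,
    WindowError,
)

__all__ = [
    "DailyCountSeries",
    "RobustScale",
    "date_span_days",
    "read_series",
    "write_series",
    "robust_scale",
    "trimmed_mean_sd",
    "rolling_trimmed_stats",
]

#: consistency constant making the scaled MAD estimate the standard deviation
#: of a normal distribution
MAD_CONSTANT = 1.4826


@dataclass(frozen=True)
class DailyCountSeries:
    """A contiguous sequence of daily counts.

    Parameters
    ----------
    dates
        Strictly increasing daily dates.  Unless ``allow_gaps`` is set the
        dates must be consecutive calendar days.
    values
        One count per date.  Non-negative integers for a raw series; reals
        within +/- 0.5 of the original integers for a jittered series.
    label
        Free-text identifier carried through reports.
    jittered
        Whether uniform smoothing noise has been added to the counts.
    """

    dates: pd.DatetimeIndex
    values: np.ndarray
    label: str = ""
    jittered: bool = False
    allow_gaps: bool = False
    has_gaps: bool = field(init=False, default=False)

    def __post_init__(self) -> None:
        dates = pd.DatetimeIndex(self.dates)
        values = np.asarray(self.values, dtype=float)
        if len(dates) != len(values):
            raise ParseError(
                f"{len(dates)} dates but {len(values)} values"
            )
        if len(dates) == 0:
            raise EmptyInputError("series must contain at least one day")
        object.__setattr__(self, "dates", dates)
        object.__setattr__(self, "values", values)
        diffs = np.diff(dates.values.astype("datetime64[D]").astype(int))
        if len(diffs) and diffs.min() <= 0:
            bad = dates[1:][diffs <= 0][0]
            raise ParseError(f"dates not strictly increasing at {bad.date()}")
        gaps = bool(len(diffs)) and int(diffs.max()) > 1
        if gaps and not self.allow_gaps:
            first = dates[1:][diffs > 1][0]
            raise GapError(f"missing days before {first.date()}")
        object.__setattr__(self, "has_gaps", gaps)
        lo = -0.5 if self.jittered else 0.0
        if values.min() < lo:
            raise NegativeCountError(
                f"count {values.min()} below the minimum {lo}"
            )
        if not self.jittered and np.any(values != np.round(values)):
            raise ParseError("raw (non-jittered) counts must be integers")

    def __len__(self) -> int:
        return len(self.values)

    @property
    def start(self) -> dt.date:
        return self.dates[0].date()

    @property
    def end(self) -> dt.date:
        return self.dates[-1].date()

    def with_values(self, values: np.ndarray, **changes) -> "DailyCountSeries":
        """Copy of the series with replaced values (and optional field changes)."""
        out = replace(self, values=np.asarray(values, dtype=float), **changes)
        return out

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"date": self.dates, "count": self.values})


@dataclass(frozen=True)
class RobustScale:
    """Robust location/dispersion summary: median and scaled MAD."""

    center: float
    scale: float
    constant: float = MAD_CONSTANT


def date_span_days(start: dt.date, end: dt.date) -> int:
    """Inclusive number of calendar days from ``start`` to ``end``.

    Gregorian and leap-aware; the study horizon 1996-07-01 .. 2009-06-30
    spans 4748 days.
    """
    if start > end:
        raise OrderError(f"start {start} after end {end}")
    return (end - start).days + 1


def read_series(
    path,
    delimiter: str = ",",
    label: str | None = None,
    allow_gaps: bool = False,
    jittered: bool = False,
) -> DailyCountSeries:
    """Read a two-column ``date,count`` file into a validated series.

    The file must have an ISO-8601 date and a number per row; a single
    header row is tolerated.  Duplicate dates, calendar gaps (unless
    ``allow_gaps``) and negative counts are rejected.
    """
    rows: list[tuple[dt.date, float]] = []
    seen: set[dt.date] = set()
    with open(path, newline="") as fh:
        for lineno, row in enumerate(csv.reader(fh, delimiter=delimiter), start=1):
            if not row or (len(row) == 1 and not row[0].strip()):
                continue
            if len(row) < 2:
                raise ParseError(f"row {lineno}: expected two columns, got {row!r}")
            cell_date, cell_count = row[0].strip(), row[1].strip()
            if lineno == 1 and not _looks_like_date(cell_date):
                continue  # header
            try:
                d = dt.date.fromisoformat(cell_date)
            except ValueError as exc:
                raise ParseError(f"row {lineno}: bad date {cell_date!r}") from exc
            try:
                v = float(cell_count)
            except ValueError as exc:
                raise ParseError(f"row {lineno}: bad count {cell_count!r}") from exc
            if d in seen:
                raise ParseError(f"row {lineno}: duplicate date {d.isoformat()}")
            seen.add(d)
            if v < (-0.5 if jittered else 0.0):
                raise NegativeCountError(f"row {lineno}: negative count {v}")
            rows.append((d, v))
    if not rows:
        raise ParseError(f"{path}: no data rows")
    rows.sort(key=lambda r: r[0])
    dates = pd.DatetimeIndex([pd.Timestamp(d) for d, _ in rows])
    values = np.array([v for _, v in rows])
    name = label if label is not None else str(path)
    return DailyCountSeries(dates, values, label=name, jittered=jittered,
                            allow_gaps=allow_gaps)


def write_series(series: DailyCountSeries, path) -> None:
    """Write a series as two-column CSV with a ``date,count`` header."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["date", "count"])
        for d, v in zip(series.dates, series.values):
            out = int(v) if float(v).is_integer() else repr(float(v))
            writer.writerow([d.date().isoformat(), out])


def _looks_like_date(text: str) -> bool:
    try:
        dt.date.fromisoformat(text)
        return True
    except ValueError:
        return False


def robust_scale(values, constant: float = MAD_CONSTANT) -> RobustScale:
    """Median and scaled median absolute deviation of ``values``.

    ``scale`` is ``constant * median(|x - median(x)|)``; it is zero exactly
    when more than half of the values coincide with the median, the failure
    mode that motivates jittering low-count series.
    """
    x = np.asarray(values, dtype=float)
    if x.size == 0:
        raise EmptyInputError("robust_scale of empty sequence")
    center = float(np.median(x))
    scale = constant * float(np.median(np.abs(x - center)))
    return RobustScale(center=center, scale=scale, constant=constant)


def trimmed_mean_sd(values, trim_fraction: float) -> tuple[float, float]:
    """Mean and sample SD after symmetric trimming.

    Drops ``floor(trim_fraction * n)`` values from each tail (so a 25% trim
    on n values keeps roughly the middle half) and returns the mean and
    ddof-1 standard deviation of what remains.
    """
    if not 0.0 <= trim_fraction < 0.5:
        raise DegenerateError(f"trim_fraction {trim_fraction} outside [0, 0.5)")
    x = np.sort(np.asarray(values, dtype=float))
    n = x.size
    k = math.floor(trim_fraction * n)
    kept = x[k: n - k]
    if kept.size < 2:
        raise DegenerateError(
            f"only {kept.size} values remain after trimming {k} per tail"
        )
    mean = float(kept.mean())
    sd = float(kept.std(ddof=1))
    return mean, sd


def rolling_trimmed_stats(
    series: DailyCountSeries,
    window: int,
    trim_fraction: float = 0.25,
) -> tuple[np.ndarray, np.ndarray]:
    """Centered rolling trimmed mean and SD, one pair per day.

    Near the edges the window shrinks symmetrically-in-intent (it is clipped
    to the series) but never holds fewer than ``ceil(window / 2)`` points, so
    every day receives a statistic and remains classifiable.
    """
    if window % 2 == 0:
        raise WindowError(f"window must be odd, got {window}")
    n = len(series)
    if window > n:
        raise WindowError(f"window {window} exceeds series length {n}")
    half = window // 2
    means = np.empty(n)
    sds = np.empty(n)
    for i in range(n):
        lo = max(0, i - half)
        hi = min(n, i + half + 1)
        means[i], sds[i] = trimmed_mean_sd(series.values[lo:hi], trim_fraction)
    return means, sds
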