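"""Robust seasonal-trend decomposition of daily count series.

The hybrid detector needs residuals that are clean of annual seasonality and
long-term trend; everything here serves that step.  Two decomposition paths
are offered:

* ``seasonal_window="periodic"`` (default): the seasonal component is the
  bisquare-weighted mean of each cycle-subseries (every day-of-cycle gets one
  value, repeated identically across years) and the trend is a locally
  weighted regression (lowess) of the seasonally adjusted series.  The two
  are alternated, with robustness weights recomputed from the remainder,
  until the components stop changing.  This mirrors the seasonal-trend
  decomposition by loess with a periodic seasonal window and is fast enough
  for Monte-Carlo work.
* integer ``seasonal_window``: delegates to the STL implementation in
  statsmodels with the given seasonal smoother length.

Leap days: with the default 365-day period, February 29 observations are
removed before decomposition; their seasonal and trend values are linearly
interpolated from the neighbouring days and the remainder is re-derived as
``observed - seasonal - trend`` so the additive identity holds on every day.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .core import DailyCountSeries, robust_scale
from .errors import AlignmentError, GapError, ShortSeriesError

__all__ = ["DecompositionResult", "stl_decompose", "extract_residuals"]


@dataclass(frozen=True)
class DecompositionResult:
    """Additive decomposition aligned to the input series.

    ``seasonal + trend + remainder`` reconstructs the observed values to
    numerical tolerance on every day.
    """

    dates: pd.DatetimeIndex
    observed: np.ndarray
    seasonal: np.ndarray
    trend: np.ndarray
    remainder: np.ndarray
    period: int
    method_tag: str

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "date": self.dates,
                "observed": self.observed,
                "seasonal": self.seasonal,
                "trend": self.trend,
                "remainder": self.remainder,
            }
        )

    def to_csv(self, path) -> None:
        df = self.to_frame()
        df["date"] = df["date"].dt.date
        df.to_csv(path, index=False)


def stl_decompose(
    series: DailyCountSeries,
    period: int = 365,
    robust: bool = True,
    seasonal_window: int | str = "periodic",
    trend_frac: float | None = None,
    max_iter: int = 15,
    tol: float = 1e-7,
) -> DecompositionResult:
    """Decompose a daily series into seasonal, trend, and remainder.

    Parameters
    ----------
    period
        Length of the seasonal cycle in days (365 for annual seasonality).
    robust
        Downweight large-remainder points with bisquare weights so isolated
        spikes barely perturb the seasonal and trend estimates.
    seasonal_window
        ``"periodic"`` for one seasonal value per day-of-cycle, or an odd
        integer loess length passed to the statsmodels STL implementation.
    trend_frac
        Lowess span for the trend as a fraction of the series; defaults to
        roughly 1.5 periods.
    """
    if series.has_gaps:
        raise GapError("decomposition requires a gap-free series")
    if len(series) < 2 * period:
        raise ShortSeriesError(
            f"need at least {2 * period} days for period {period}, got {len(series)}"
        )
    dates = series.dates
    y_full = series.values

    leap = (dates.month == 2) & (dates.day == 29) if period == 365 else np.zeros(
        len(series), dtype=bool
    )
    y = y_full[~leap]

    if seasonal_window == "periodic":
        seasonal, trend = _periodic_robust_fit(
            y, period, robust, trend_frac, max_iter, tol
        )
        tag = f"periodic-robust({robust})"
    else:
        res = sm.tsa.STL(
            y, period=period, seasonal=_to_odd(int(seasonal_window)), robust=robust
        ).fit()
        seasonal, trend = np.asarray(res.seasonal), np.asarray(res.trend)
        tag = f"stl(seasonal={seasonal_window},robust={robust})"

    if leap.any():
        seasonal = _reinsert(seasonal, leap)
        trend = _reinsert(trend, leap)
    remainder = y_full - seasonal - trend
    return DecompositionResult(
        dates=dates,
        observed=y_full.copy(),
        seasonal=seasonal,
        trend=trend,
        remainder=remainder,
        period=period,
        method_tag=tag,
    )


def extract_residuals(
    series: DailyCountSeries,
    result: DecompositionResult,
    mode: str = "remainder",
) -> np.ndarray:
    """Residual sequence handed to the studentized-deviate test.

    ``mode="remainder"`` is ``observed - seasonal - trend`` (the decomposition
    remainder).  ``mode="seasonal_minus_median"`` replaces the trend with the
    series median, the variant used by the originating detector:
    ``observed - seasonal - median(observed)``.
    """
    if len(result.observed) != len(series) or not result.dates.equals(series.dates):
        raise AlignmentError("decomposition does not align with the series")
    if mode == "remainder":
        return result.remainder.copy()
    if mode == "seasonal_minus_median":
        return series.values - result.seasonal - np.median(series.values)
    raise ValueError(f"unknown residual mode {mode!r}")


def _periodic_robust_fit(
    y: np.ndarray,
    period: int,
    robust: bool,
    trend_frac: float | None,
    max_iter: int,
    tol: float,
) -> tuple[np.ndarray, np.ndarray]:
    n = len(y)
    t = np.arange(n, dtype=float)
    if trend_frac is None:
        trend_frac = min(1.0, (1.5 * period + 1) / n)
    cycle = np.arange(n) % period
    seasonal = np.zeros(n)
    trend = np.zeros(n)
    weights = np.ones(n)
    lowess_it = 2 if robust else 0
    for _ in range(max_iter):
        prev_seasonal, prev_trend = seasonal, trend
        trend = sm.nonparametric.lowess(
            y - seasonal,
            t,
            frac=trend_frac,
            it=lowess_it,
            delta=period / 50,
            return_sorted=False,
        )
        detrended = y - trend
        num = np.bincount(cycle, weights=weights * detrended, minlength=period)
        den = np.bincount(cycle, weights=weights, minlength=period)
        sub = np.divide(num, den, out=np.zeros(period), where=den > 1e-8)
        # a spike can transiently zero the weights of its whole cycle
        # position; fall back to the robust subseries median there
        for pos in np.flatnonzero(den <= 1e-8):
            sub[pos] = np.median(detrended[cycle == pos])
        sub -= sub.mean()
        seasonal = sub[cycle]
        if robust:
            remainder = y - trend - seasonal
            rs = robust_scale(remainder)
            eps = 1e-9 * max(1.0, float(np.abs(y).max()))
            if rs.scale > eps:
                u = np.clip(np.abs(remainder - rs.center) / (6.0 * rs.scale), 0.0, 1.0)
                weights = (1.0 - u**2) ** 2
            else:
                # numerically exact fit: keep conforming points, drop spikes
                weights = (np.abs(remainder - rs.center) <= eps).astype(float)
        change = max(
            np.max(np.abs(seasonal - prev_seasonal)),
            np.max(np.abs(trend - prev_trend)),
        )
        if change < tol:
            break
    return seasonal, trend


def _reinsert(component: np.ndarray, leap_mask: np.ndarray) -> np.ndarray:
    """Re-insert removed leap days by linear interpolation of neighbours."""
    n = len(leap_mask)
    out = np.empty(n)
    out[~leap_mask] = component
    idx = np.arange(n, dtype=float)
    out[leap_mask] = np.interp(idx[leap_mask], idx[~leap_mask], component)
    return out


def _to_odd(k: int) -> int:
    return k if k % 2 == 1 else k + 1
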