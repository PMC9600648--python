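"""Seasonal hybrid ESD detection of anomalously high (or low) count days.

The detector decomposes the series (robust seasonal + trend), standardizes
the residuals with the median and scaled MAD instead of the mean and SD, and
applies Rosner's generalized extreme studentized deviate (ESD) test
iteratively: the most deviant residual is tested against a Student-t based
critical value, removed, and the test repeated up to ``k`` times.  The
declared outlier count is the largest removal rank whose statistic exceeded
its critical value, which embeds a Bonferroni-style division of the
significance level across the remaining candidates at every step.

Low-count discrete series (e.g. daily readmissions dominated by zeros) make
the MAD collapse to zero and the test undefined.  The jitter extension adds
uniform noise strictly inside (-0.5, 0.5) to every count -- rounding recovers
the original integers exactly -- which restores a positive MAD while leaving
the ranking of genuinely high days intact.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .core import DailyCountSeries, robust_scale
from .decomposition import extract_residuals, stl_decompose
from .errors import (
    AlreadyJitteredError,
    DomainError,
    ShortInputError,
    ZeroMADError,
)

__all__ = [
    "DetectorConfig",
    "AnomalyRecord",
    "AnomalyReport",
    "esd_critical_value",
    "robust_esd",
    "EsdCandidate",
    "EsdResult",
    "jitter_series",
    "shesd_detect",
]


@dataclass(frozen=True)
class DetectorConfig:
    """Tunables of a seasonal-hybrid-ESD run.

    ``k_max=None`` selects the auto policy: start at ``max(10, 1% of n)``
    and double whenever the test declares exactly ``k`` outliers (meaning the
    cap may have truncated the search), up to a hard cap of 10% of the
    series length.
    """

    alpha: float = 0.05
    k_max: int | None = None
    direction: str = "high"  # high | low | both
    period: int = 365
    residual_mode: str = "remainder"  # remainder | seasonal_minus_median
    seasonal_window: int | str = "periodic"
    robust: bool = True
    jitter: str = "auto"  # off | auto | on
    jitter_seed: int = 1729
    jitter_replicates: int = 1

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha < 1.0:
            raise DomainError(f"alpha {self.alpha} outside (0, 1)")
        if self.k_max is not None and self.k_max < 1:
            raise DomainError("k_max must be >= 1")
        if self.jitter_replicates < 1:
            raise DomainError("jitter_replicates must be >= 1")
        if self.direction not in ("high", "low", "both"):
            raise ValueError(f"unknown direction {self.direction!r}")
        if self.jitter not in ("off", "auto", "on"):
            raise ValueError(f"unknown jitter policy {self.jitter!r}")


@dataclass(frozen=True)
class AnomalyRecord:
    date: pd.Timestamp
    observed: float
    residual: float
    statistic: float
    critical_value: float
    rank: int
    significant: bool


@dataclass(frozen=True)
class AnomalyReport:
    """Outcome of one detector run, shared by all three detectors."""

    records: tuple[AnomalyRecord, ...]
    k_used: int
    alpha: float | None
    method: str
    jitter_applied: bool
    series_start: pd.Timestamp
    series_end: pd.Timestamp
    statistical_test: bool = True
    degenerate_dates: tuple[pd.Timestamp, ...] = field(default_factory=tuple)

    @property
    def flagged_dates(self) -> list[pd.Timestamp]:
        """Dates of significant records, in calendar order."""
        return sorted(r.date for r in self.records if r.significant)

    @property
    def adjusted_alpha(self) -> float | None:
        """Per-outlier Bonferroni share of alpha (alpha / declared count)."""
        n_sig = sum(r.significant for r in self.records)
        if self.alpha is None or n_sig == 0:
            return None
        return self.alpha / n_sig

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for r in sorted(self.records, key=lambda r: r.rank):
            if self.statistical_test:
                sig = f"p<{self.alpha}" if r.significant else "ns"
            else:
                sig = "flagged" if r.significant else "not_tested"
            rows.append(
                {
                    "date": r.date.date(),
                    "count": r.observed,
                    "statistic": r.statistic,
                    "critical_value": r.critical_value,
                    "rank": r.rank,
                    "method": self.method,
                    "significance": sig,
                }
            )
        return pd.DataFrame(
            rows,
            columns=[
                "date", "count", "statistic", "critical_value",
                "rank", "method", "significance",
            ],
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def esd_critical_value(
    n: int, i: int, alpha: float, direction: str = "high"
) -> float:
    """Critical value for the i-th removal step of the generalized ESD test.

    With p = 1 - alpha/(n - i + 1) one-sided (or alpha/(2(n - i + 1))
    two-sided) and t the p-quantile of Student-t with n - i - 1 degrees of
    freedom:

        lambda_i = (n - i) * t / sqrt((n - i - 1 + t^2) * (n - i + 1))
    """
    if not 0.0 < alpha < 1.0:
        raise DomainError(f"alpha {alpha} outside (0, 1)")
    if n - i - 1 < 1:
        raise DomainError(f"rank i={i} too large for n={n}")
    denom = n - i + 1
    p = 1.0 - alpha / (2.0 * denom) if direction == "both" else 1.0 - alpha / denom
    t = stats.t.ppf(p, df=n - i - 1)
    return float((n - i) * t / math.sqrt((n - i - 1 + t * t) * denom))


@dataclass(frozen=True)
class EsdCandidate:
    index: int
    statistic: float
    critical_value: float
    rank: int


@dataclass(frozen=True)
class EsdResult:
    candidates: tuple[EsdCandidate, ...]
    num_outliers: int

    def significant(self, rank: int) -> bool:
        return rank <= self.num_outliers


def robust_esd(
    values,
    k_max: int,
    alpha: float = 0.05,
    direction: str = "high",
) -> EsdResult:
    """Generalized ESD test with median/scaled-MAD studentization.

    At every step the median and scaled MAD are recomputed over the values
    still in play, the most deviant value (in the requested direction) is
    tested and removed, and after ``k_max`` steps the outlier count is the
    largest rank whose statistic exceeded its critical value.
    """
    x = np.asarray(values, dtype=float)
    n = x.size
    if n < k_max + 3:
        raise ShortInputError(f"need at least k_max + 3 = {k_max + 3} values, got {n}")
    remaining = np.ones(n, dtype=bool)
    candidates: list[EsdCandidate] = []
    num_outliers = 0
    for rank in range(1, k_max + 1):
        current = x[remaining]
        rs = robust_scale(current)
        if rs.scale == 0.0:
            raise ZeroMADError(
                "scaled MAD is zero (more than half of the values tie); "
                "consider the jitter extension"
            )
        dev = current - rs.center
        if direction == "high":
            scores = dev
        elif direction == "low":
            scores = -dev
        else:
            scores = np.abs(dev)
        local = int(np.argmax(scores))
        statistic = float(scores[local] / rs.scale)
        index = int(np.flatnonzero(remaining)[local])
        critical = esd_critical_value(n, rank, alpha, direction)
        candidates.append(EsdCandidate(index, statistic, critical, rank))
        if statistic > critical:
            num_outliers = rank
        remaining[index] = False
    return EsdResult(candidates=tuple(candidates), num_outliers=num_outliers)


def jitter_series(series: DailyCountSeries, seed: int) -> DailyCountSeries:
    """Add uniform noise strictly inside (-0.5, 0.5) to an integer series.

    Rounding the jittered values to the nearest integer recovers the input
    exactly, so no ordering information between distinct counts is lost while
    ties are broken and the MAD becomes positive.  Deterministic given seed.
    """
    if series.jittered:
        raise AlreadyJitteredError(f"series {series.label!r} is already jittered")
    rng = np.random.default_rng(seed)
    u = rng.uniform(-0.5, 0.5, size=len(series))
    while np.any(u == -0.5):  # keep the interval open on both sides
        redo = u == -0.5
        u[redo] = rng.uniform(-0.5, 0.5, size=int(redo.sum()))
    return series.with_values(series.values + u, jittered=True)


def _needs_jitter(values: np.ndarray) -> bool:
    """True when more than half of the values tie (zero MAD guaranteed)."""
    _, counts = np.unique(values, return_counts=True)
    return counts.max() > values.size / 2


def _auto_k(n: int) -> int:
    return max(10, round(0.01 * n))


def _run_once(
    series: DailyCountSeries, config: DetectorConfig
) -> tuple[np.ndarray, EsdResult, int]:
    decomp = stl_decompose(
        series,
        period=config.period,
        robust=config.robust,
        seasonal_window=config.seasonal_window,
    )
    residuals = extract_residuals(series, decomp, mode=config.residual_mode)
    n = len(residuals)
    hard_cap = max(1, math.floor(0.10 * n))
    k = config.k_max if config.k_max is not None else min(_auto_k(n), hard_cap)
    while True:
        result = robust_esd(residuals, k, alpha=config.alpha, direction=config.direction)
        auto = config.k_max is None
        if auto and result.num_outliers == k and k < hard_cap:
            k = min(2 * k, hard_cap)
            continue
        return residuals, result, k


def shesd_detect(
    series: DailyCountSeries, config: DetectorConfig | None = None
) -> AnomalyReport:
    """Run the full seasonal hybrid ESD pipeline on a daily count series.

    Decomposes, extracts residuals, and applies the robust ESD test.  Under
    ``jitter="auto"`` a zero-MAD failure (or a series where more than half
    the counts tie) triggers the jitter extension transparently; with
    ``jitter_replicates > 1`` the test is repeated over independent jitter
    draws and a day is reported anomalous when a majority of draws flag it.
    Reported counts are always the original integers.
    """
    config = config or DetectorConfig()
    original = series.values.copy()

    degenerate = not series.jittered and _needs_jitter(series.values)
    if degenerate and config.jitter == "off":
        raise ZeroMADError(
            "more than half of the counts tie (raw scaled MAD is zero); the "
            "test breaks down on such discrete series — enable the jitter "
            "extension"
        )
    use_jitter = config.jitter == "on" or (config.jitter == "auto" and degenerate)
    if not use_jitter:
        try:
            residuals, result, k_used = _run_once(series, config)
        except ZeroMADError:
            if config.jitter != "auto" or series.jittered:
                raise
            use_jitter = True
    if not use_jitter:
        records = _records_from_run(series, original, residuals, result)
        return _report(series, config, records, k_used, jitter=False)

    n_rep = config.jitter_replicates
    rep_seeds = np.random.SeedSequence(config.jitter_seed).generate_state(n_rep)
    votes: dict[pd.Timestamp, int] = {}
    first_flag: dict[pd.Timestamp, AnomalyRecord] = {}
    k_used = 0
    for rep in range(n_rep):
        jit = jitter_series(series, int(rep_seeds[rep]))
        residuals, result, k_rep = _run_once(jit, config)
        k_used = max(k_used, k_rep)
        for rec in _records_from_run(series, original, residuals, result):
            if not rec.significant:
                continue
            votes[rec.date] = votes.get(rec.date, 0) + 1
            first_flag.setdefault(rec.date, rec)
    majority = [d for d, v in votes.items() if v > n_rep / 2]
    if n_rep == 1:
        # single draw: keep the full candidate trace of that run
        records = _records_from_run(series, original, residuals, result)
    else:
        kept = sorted(majority, key=lambda d: first_flag[d].rank)
        records = [
            AnomalyRecord(
                date=d,
                observed=first_flag[d].observed,
                residual=first_flag[d].residual,
                statistic=first_flag[d].statistic,
                critical_value=first_flag[d].critical_value,
                rank=rank,
                significant=True,
            )
            for rank, d in enumerate(kept, start=1)
        ]
    return _report(series, config, records, k_used, jitter=True)


def _records_from_run(
    series: DailyCountSeries,
    original: np.ndarray,
    residuals: np.ndarray,
    result: EsdResult,
) -> list[AnomalyRecord]:
    return [
        AnomalyRecord(
            date=series.dates[c.index],
            observed=float(original[c.index]),
            residual=float(residuals[c.index]),
            statistic=c.statistic,
            critical_value=c.critical_value,
            rank=c.rank,
            significant=result.significant(c.rank),
        )
        for c in result.candidates
    ]


def _report(
    series: DailyCountSeries,
    config: DetectorConfig,
    records: list[AnomalyRecord],
    k_used: int,
    jitter: bool,
) -> AnomalyReport:
    method = "shesd"
    if jitter and config.jitter_replicates > 1:
        method = f"shesd(jitter-vote x{config.jitter_replicates})"
    elif jitter:
        method = "shesd(jitter)"
    return AnomalyReport(
        records=tuple(sorted(records, key=lambda r: r.rank)),
        k_used=k_used,
        alpha=config.alpha,
        method=method,
        jitter_applied=jitter,
        series_start=series.dates[0],
        series_end=series.dates[-1],
        statistical_test=True,
    )
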