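"""Scoring against ground truth, summary tables, and method comparison.

Detector-agnostic: everything consumes the shared report schema, so the
hybrid detector and both comparators can be scored, tabulated, and compared
with the same code.  Includes the Monte-Carlo validation experiment that
estimates a detector's sensitivity and positive predictive value on
synthetic series with injected ground-truth anomalies.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .comparators import M4sdConfig, TmqqConfig, m4sd_detect, tmqq_detect
from .core import DailyCountSeries
from .decomposition import stl_decompose
from .detector import AnomalyReport, DetectorConfig, shesd_detect
from .errors import RangeMismatchError, ShesdError
from .synthetic import InjectionSpec, SyntheticSpec, default_admissions_spec, generate, inject_anomalies

__all__ = [
    "DetectionMetrics",
    "score",
    "month_table",
    "period_split_table",
    "compare_methods",
    "ValidationResult",
    "run_validation_experiment",
]

# month display order for seasonal tables: December first (southern-hemisphere
# summer start), matching how the admissions seasonality is usually presented
_MONTH_ORDER = [12, 1, 2, 3, 4, 5, 6, 7, 8, 9, 10, 11]


@dataclass(frozen=True)
class DetectionMetrics:
    """Confusion summary of a detector run against truth dates.

    ``ppv`` is ``None`` (undefined) when nothing was detected, rather than
    zero: an empty report carries no precision information.
    """

    true_positives: int
    false_positives: int
    false_negatives: int
    n_truth: int
    n_detected: int

    @property
    def sensitivity(self) -> float:
        if self.n_truth == 0:
            return float("nan")
        return self.true_positives / (self.true_positives + self.false_negatives)

    @property
    def ppv(self) -> float | None:
        denom = self.true_positives + self.false_positives
        return self.true_positives / denom if denom > 0 else None


def score(
    report: AnomalyReport,
    truth,
    tolerance_days: int = 0,
) -> DetectionMetrics:
    """Match detections to truth dates one-to-one and count TP/FP/FN.

    A detection matches a truth date when they differ by at most
    ``tolerance_days``; matching is greedy by date distance, each truth date
    and each detection used at most once.
    """
    truth_dates = sorted(_as_date(d) for d in truth)
    lo, hi = report.series_start.date(), report.series_end.date()
    out_of_range = [d for d in truth_dates if d < lo or d > hi]
    if out_of_range:
        raise RangeMismatchError(
            f"truth dates outside report range {lo}..{hi}: {out_of_range}"
        )
    detected = [d.date() for d in report.flagged_dates]

    pairs = [
        (abs((det - tru).days), i, j)
        for i, det in enumerate(detected)
        for j, tru in enumerate(truth_dates)
        if abs((det - tru).days) <= tolerance_days
    ]
    pairs.sort()
    used_det: set[int] = set()
    used_truth: set[int] = set()
    tp = 0
    for _, i, j in pairs:
        if i in used_det or j in used_truth:
            continue
        used_det.add(i)
        used_truth.add(j)
        tp += 1
    return DetectionMetrics(
        true_positives=tp,
        false_positives=len(detected) - tp,
        false_negatives=len(truth_dates) - tp,
        n_truth=len(truth_dates),
        n_detected=len(detected),
    )


def month_table(report: AnomalyReport) -> pd.DataFrame:
    """Flagged-day counts and percentages by calendar month (December first)."""
    flagged = report.flagged_dates
    counts = {m: 0 for m in _MONTH_ORDER}
    for d in flagged:
        counts[d.month] += 1
    total = len(flagged)
    rows = [
        {
            "month": dt.date(2000, m, 1).strftime("%B"),
            "n": counts[m],
            "percent": 100.0 * counts[m] / total if total else 0.0,
        }
        for m in _MONTH_ORDER
    ]
    return pd.DataFrame(rows)


def period_split_table(
    report: AnomalyReport, split: dt.date = dt.date(2002, 12, 31)
) -> pd.DataFrame:
    """Flagged-day counts up to and after a split date (default end of 2002)."""
    flagged = [d.date() for d in report.flagged_dates]
    pre = sum(d <= split for d in flagged)
    post = len(flagged) - pre
    total = len(flagged)
    return pd.DataFrame(
        [
            {"period": f"<= {split.year}", "n": pre,
             "percent": 100.0 * pre / total if total else 0.0},
            {"period": f"> {split.year}", "n": post,
             "percent": 100.0 * post / total if total else 0.0},
        ]
    )


def _detect(series: DailyCountSeries, config) -> tuple[str, AnomalyReport]:
    if isinstance(config, DetectorConfig):
        return "shesd", shesd_detect(series, config)
    if isinstance(config, TmqqConfig):
        return "tmqq", tmqq_detect(series, config)
    if isinstance(config, M4sdConfig):
        return "m4sd", m4sd_detect(series, config)
    raise TypeError(f"unrecognized detector config {type(config).__name__}")


def compare_methods(
    series: DailyCountSeries, configs
) -> tuple[pd.DataFrame, dict[int, int]]:
    """Run several detectors and tabulate the overlap of their flagged days.

    Returns a frame indexed by every flagged date with one boolean column per
    method, plus a summary mapping ``{m: number of days flagged by exactly m
    methods}``.
    """
    if len(configs) < 2:
        raise ValueError("need at least two detector configs to compare")
    flagged: dict[str, set[dt.date]] = {}
    for config in configs:
        name, report = None, None
        try:
            name, report = _detect(series, config)
        except ShesdError as exc:
            kind = type(config).__name__
            raise type(exc)(f"[{kind}] {exc}") from exc
        column = name
        suffix = 2
        while column in flagged:  # same method run with different settings
            column = f"{name}_{suffix}"
            suffix += 1
        flagged[column] = {d.date() for d in report.flagged_dates}
    all_days = sorted(set().union(*flagged.values()))
    table = pd.DataFrame(
        {name: [d in days for d in all_days] for name, days in flagged.items()},
        index=pd.Index(all_days, name="date"),
    )
    by_count = table.sum(axis=1)
    overlap = {
        m: int((by_count == m).sum()) for m in range(1, len(flagged) + 1)
    }
    return table, overlap


@dataclass(frozen=True)
class ValidationResult:
    """Aggregate of a Monte-Carlo sensitivity / PPV experiment."""

    per_replicate: pd.DataFrame
    mean_sensitivity: float
    mean_ppv: float | None
    se_sensitivity: float
    se_ppv: float | None
    n_replicates: int
    n_with_detection: int


def run_validation_experiment(
    n_replicates: int,
    injection: InjectionSpec,
    config: DetectorConfig,
    master_seed: int,
    series_spec: SyntheticSpec | None = None,
    tolerance_days: int = 0,
) -> ValidationResult:
    """Estimate detector sensitivity and PPV on synthetic ground truth.

    Each replicate draws a fresh synthetic series, measures the scaled MAD of
    its decomposition remainders as the reference residual scale, injects
    anomalies of the requested magnitude, runs the detector, and scores the
    report.  Sensitivity averages over all replicates; PPV averages over
    replicates with at least one detection (it is undefined otherwise).
    Fully reproducible given ``master_seed``.
    """
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    base_spec = series_spec if series_spec is not None else default_admissions_spec()
    seed_rng = np.random.default_rng(master_seed)
    rows = []
    for rep in range(n_replicates):
        series_seed, inject_seed = (int(s) for s in seed_rng.integers(0, 2**31 - 1, 2))
        series = generate(replace(base_spec, seed=series_seed))
        decomp = stl_decompose(
            series,
            period=config.period,
            robust=config.robust,
            seasonal_window=config.seasonal_window,
        )
        from .core import robust_scale  # local import avoids a cycle at module load

        ref_scale = robust_scale(decomp.remainder).scale
        spiked, truth = inject_anomalies(
            series, replace(injection, seed=inject_seed), ref_scale
        )
        report = shesd_detect(spiked, config)
        metrics = score(report, truth, tolerance_days=tolerance_days)
        rows.append(
            {
                "replicate": rep,
                "sensitivity": metrics.sensitivity,
                "ppv": metrics.ppv,
                "tp": metrics.true_positives,
                "fp": metrics.false_positives,
                "fn": metrics.false_negatives,
                "n_detected": metrics.n_detected,
            }
        )
    table = pd.DataFrame(rows)
    sens = table["sensitivity"].to_numpy(float)
    with_det = table["n_detected"] > 0
    ppv_vals = table.loc[with_det, "ppv"].to_numpy(float)
    mean_ppv = float(ppv_vals.mean()) if ppv_vals.size else None
    se_ppv = (
        float(ppv_vals.std(ddof=1) / np.sqrt(ppv_vals.size))
        if ppv_vals.size > 1
        else None
    )
    return ValidationResult(
        per_replicate=table,
        mean_sensitivity=float(sens.mean()),
        mean_ppv=mean_ppv,
        se_sensitivity=float(sens.std(ddof=1) / np.sqrt(len(sens))) if len(sens) > 1 else 0.0,
        se_ppv=se_ppv,
        n_replicates=n_replicates,
        n_with_detection=int(with_det.sum()),
    )


def _as_date(d) -> dt.date:
    if isinstance(d, pd.Timestamp):
        return d.date()
    if isinstance(d, dt.datetime):
        return d.date()
    if isinstance(d, dt.date):
        return d
    return pd.Timestamp(d).date()
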