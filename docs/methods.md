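# Methods

## Problem

Daily counts of hospital admissions for a seasonal disease (the motivating
case is paediatric asthma) mix four sources of variation: annual
seasonality, a slow multi-year trend, a day-of-week usage pattern, and
day-to-day count noise.  "High admission days" are days anomalously high
*relative to what seasonality and trend predict*, not merely days with large
absolute counts: 30 admissions may be unremarkable in late summer yet
extreme in mid-December.  Classifying such days with fixed count cutoffs or
global z-scores misclassifies in both directions, which is why this package
centres on a seasonal, robust, formally tested detector.

## The seasonal hybrid ESD detector

The pipeline is decompose → standardize robustly → test iteratively.

**Decomposition.**  The series is split additively into seasonal, trend and
remainder.  With the default `seasonal_window="periodic"`, the seasonal
component assigns one value per day-of-cycle (period 365), estimated as the
bisquare-weighted mean of that day's values across years after detrending;
the trend is a locally weighted regression (lowess, span ≈ 1.5 periods, with
robustifying iterations); the two steps alternate until the components
change by less than 1e-7 (cap 15 iterations).  Robustness weights are
bisquare in the remainder scaled by 6 × (1.4826 × MAD), so an isolated
spike is effectively excluded from both components.  Two numerical
safeguards matter in the degenerate limits: when a spike transiently zeroes
the weights of its whole cycle position, that position's seasonal value
falls back to the subseries median; when the remainder MAD is numerically
zero (an exact fit), points at the median keep weight 1 and outliers get 0.
An integer `seasonal_window` instead delegates to the STL implementation in
statsmodels with that seasonal loess length.

February 29 observations are removed before decomposition (keeping the
period a fixed 365 days) and re-inserted afterwards with seasonal and trend
linearly interpolated from neighbouring days; the remainder is then defined
as `observed − seasonal − trend`, so the additive identity holds exactly on
every day, including leap days, and a leap day can itself be flagged.

A known limitation of the robust seasonal estimate: when a spiked day is
downweighted, the other days sharing its cycle position lose that day's
clean information, shifting their seasonal value by O(σ_noise / n_years).
This is intrinsic to any robust estimator, is small for multi-year series,
and is distinct from contamination (which the weighting suppresses below 2%
of the series SD elsewhere).

**Robust ESD test.**  The remainder is passed to a generalized extreme
studentized deviate test with the mean and SD replaced by the median and
scaled MAD (constant 1.4826).  At step i (i = 1..k), the statistic is

    C_i = max over remaining days of (r − median) / (1.4826 · MAD)

(for direction `high`; deviations are negated for `low`, absolute for
`both`), the maximizing day is removed, and C_i is compared with

    λ_i = (n − i) · t_{p, n−i−1} / sqrt((n − i − 1 + t²)(n − i + 1)),
    p = 1 − α/(n − i + 1)  one-sided,  1 − α/(2(n − i + 1))  two-sided.

The declared outlier count is the largest i with C_i > λ_i, and every rank
up to it is flagged (the decision set is prefix-closed by construction).
The division of α across the n − i + 1 remaining candidates is the
Bonferroni-style multiplicity control of the procedure; reports additionally
expose `adjusted_alpha = α / k_detected` for auditability.  Median and MAD
are recomputed from scratch over the remaining values at every step.

Defaults: α = 0.05; direction `high` (high-admission days are the target;
`both` retains parity with the originating two-sided test); residuals from
the decomposition remainder (`seasonal_minus_median`, the originating
method's median-replaced-trend variant, is available but not default); k
chosen automatically — start at max(10, 1% of n) and double whenever the
test declares exactly k outliers, capped at 10% of n, so the search is
exhaustive without a user-supplied k.

**Jitter extension for discrete low-count series.**  When more than half of
the counts tie (e.g. a readmissions series at ~60% zeros), the raw MAD is
zero and the test is undefined; near that regime it is unstable.  The
extension adds independent uniform noise drawn strictly inside (−0.5, 0.5)
to every count before decomposition.  Rounding recovers the original
integers exactly, so the ordering of distinct counts is untouched while ties
are broken smoothly.  Under `jitter="auto"` (default) the extension engages
exactly when the tie condition holds or a ZeroMAD failure arises;
`jitter="off"` raises instead.  Because a single draw makes borderline days
seed-dependent, `jitter_replicates > 1` repeats the test over independent
draws and flags a day when a majority of draws flag it.  The vote is
bit-reproducible given `jitter_seed`, and clearly high days (4–5 counts) are
stable across master seeds, but days whose per-draw flag probability is near
0.5 (typically 3-count days) necessarily remain master-seed-dependent — no
finite vote removes that; reports carry the original integer counts either
way.

## Comparator detectors

**TMQQ** standardizes each day by a centered rolling 25% trimmed mean and
trimmed SD (window default 15 days; the source analyses never state their
window, so this is a documented reproduction unknown) and flags days above a
threshold in SD units.  Edge windows shrink but never below ⌈window/2⌉
points, so every day is classifiable.  Windows whose trimmed SD is zero
(common in zero-dominated series) yield +inf/0/−inf standardized residuals
and are listed on the report as degenerate rather than raising.  The
threshold is either supplied (10.2 and 7.5 SD are the published admissions
and readmissions choices) or derived by an automated stand-in for reading a
quantile-quantile departure point: among consecutive-order-statistic gaps in
the upper decile exceeding `gap_factor` (default 3) times the decile's
median gap, the threshold is the midpoint of the widest; with no qualifying
gap the threshold is +inf with a warning.  The widest-gap rule (rather than
the first qualifying gap) is deliberate: order-statistic gaps grow steadily
through a well-behaved tail, so a first-gap rule would fire inside the clean
tail rather than at the departure point an analyst would read off the plot.

**M.4SD** fits a semiparametric count regression — cyclic annual
seasonality as Fourier pairs in day-of-year (3 harmonics), a smooth
long-term trend as a penalized B-spline in time (8 df), and a day-of-week
categorical effect — and flags days whose response residual (observed −
fitted mean) exceeds 4 × the global SD of response residuals.  The default
family is Poisson with free dispersion (quasi-Poisson; the mean fit is
identical), with negative-binomial and Gaussian-on-log1p alternatives.  The
exact specification of the precedent model is not recoverable, so the basis
dimensions and family are explicit configuration with these defaults.

All three detectors emit one report schema (date, count, statistic,
critical value, rank, significance), so scoring and tabulation are
detector-agnostic.  TMQQ and M.4SD attach no significance test — their
thresholds are conventions, which is precisely the contrast with the hybrid
detector.

## Synthetic test bed

The real 13-year Victorian series is access-restricted, so validation runs
on synthetic stand-ins generated per day from a negative binomial with mean
= base level × seasonal(day-of-year) × day-of-week × trend(date),
normalized over the horizon so the base level is the expected daily mean.
The defaults emulate the published summaries and were calibrated once
against them, then frozen:

* **Admissions** (1996-07-01..2009-06-30, 4748 days): mean 11.3, SD ≈ 5.9
  (target 6.0), max ≈ 40–56 (reported range 0–51).  Log-seasonal curve = two
  annual harmonics plus two Gaussian day-of-year pulses: a February
  "return-to-school" pulse (centre day 46) and a late-autumn May pulse
  (centre day 136), giving daily-curve peaks on ≈ Feb 17 and ≈ May 13 and a
  December–January trough (southern-hemisphere seasons).  Day-of-week
  multipliers 1.10..0.94 (Monday high, Saturday low).  Piecewise-linear
  trend 1.48 → 0.815 (mid-2002) → 0.845, the published
  declining-then-roughly-flat shape.  Negative-binomial size 20
  (variance/mean ≈ 1.6 at the mean level, typical of daily admission counts
  once seasonal structure is accounted for).
* **Readmissions**: mean 0.5, SD ≈ 0.74, ≈ 62% zeros (so the raw scaled MAD
  is exactly zero — the jitter regime), max ≈ 5–6, winter (June–August)
  peak via one dominant annual harmonic, trend 1.20 → 0.80 (mid-2002) →
  1.15 (decline then rise), near-Poisson dispersion (size 60).

What the generator does *not* emulate: day-to-day autocorrelation (epidemic
waves), year-to-year variation in seasonal shape, and any patient-level
structure.  Days are exchangeable given the mean surface, which is the
regime the detectors assume after decomposition; passing tests therefore
demonstrate correctness of the machinery under the published marginal
structure, not performance under serially correlated outbreaks.

**Anomaly injection** adds `round(magnitude × reference_scale)` counts to
chosen days, where the reference scale is conventionally the scaled MAD of
the clean series' decomposition remainders, and returns the truth dates.
Placement is uniform-random, listed dates, or "seasonal-local": low-season
days (bottom quartile of the day-of-year mean profile) chosen so the spiked
count stays below the clean global maximum — the construction that probes
detection of days high only for their season.

## Validation experiment and its honest operating characteristics

`run_validation_experiment` repeats: generate a fresh admissions series →
measure the remainder MAD → inject anomalies → detect → score against the
injected truth (exact-day, one-to-one greedy matching; PPV is undefined,
not zero, on replicates with no detections, and the aggregate reports how
many were skipped).  Everything chains off one master seed.

At the reference setting (12 injections of +8 remainder-MADs per 4748-day
series, α = 0.05, direction high) sensitivity is essentially 1.0: a +8-MAD
spike sits far above the largest critical value (λ₁ ≈ 4.25 at n = 4748).
Mean PPV against injected-only truth is ≈ 0.4–0.5, not ≈ 1, and this is a
property of the data regime, not a defect of the detector: a count series
calibrated to mean 11.3 with SD ≈ 6 necessarily produces ~0.4% natural days
whose remainders exceed 4.25 scaled-MADs.  The detector flags them — they
are genuinely the extreme days of the series, with counts in the low 30s to
50s, mirroring the published real-data analysis that classified 17/4748
days (0.4%, counts 33–51) — but an injection experiment labels them false
positives.  Near-perfect PPV figures for this method originate from data
whose residuals are close to homoscedastic normal, where the ESD's
family-wise error control at α makes non-injected flags rare.  Both numbers
are computed and reported as measured; the test suite asserts the
sensitivity bound and states the PPV expectation explicitly so the gap is
visible rather than tuned away.

## Evaluation tables and comparison

`month_table` (December first, the southern-hemisphere seasonal year) and
`period_split_table` (default split: end of 2002, the published trend
change-point) summarize any report as counts with exact percentages —
rounding artifacts in published totals (e.g. "101%") are not reproduced.
`compare_methods` runs several detectors and tabulates per-day overlap and
the number of days flagged by exactly m methods.

## Numerical and interface choices

* Trimming drops ⌊trim_fraction × n⌋ values from *each* tail (symmetric;
  the sources do not state their rounding convention); the trimmed SD uses
  ddof = 1.
* MAD consistency constant 1.4826 (normal consistency), configurable.
* Counts are stored as floats with a `jittered` flag so raw and jittered
  series share one type; raw series must be non-negative integers, jittered
  values may dip to −0.5.
* Detection is invariant under adding a constant to all counts and under
  positive scaling (decomposition equivariance plus MAD standardization),
  and enlarging a flagged day's count never un-flags it.
* Problem sizes in the test suite are scaled to keep it quick: generic
  decomposition properties run at a 50-day period over 10 cycles,
  spike-robustness at the annual period over 8–10 years, and the Monte-Carlo
  validation at 20 replicates in the suite versus 100 in the acceptance
  script; the properties tested are size-agnostic.
* I/O is two-column CSV (`date,count`, ISO-8601); reports and decomposition
  dumps are CSV; the `shesd` CLI exposes detect / simulate / evaluate /
  compare / validate over these files.
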