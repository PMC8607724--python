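"""TG-218 statistical process control for gamma passing rates.

A QA programme tracks GP% on an individuals/moving-range control chart.
The clinic-specific limits are

    AL_cs = 100 - 3 * sqrt(sigma^2 + (x_bar - 100)^2)
    TL_cs = x_bar - 2.660 * mR_bar

with x_bar and sigma the mean and standard deviation of GP% over the
investigation period and mR_bar the mean moving range (mean absolute
difference between consecutive deliveries; 2.660 = 3/d2 with d2 = 1.128,
the standard individuals-chart constant).  Limits are established on the
first 40 deliveries and re-evaluated on ~6-month periods; only clinically
deliverable plans — GP%(3% global, 2 mm) strictly above 90% — enter the
computation.  95% confidence intervals come from a percentile bootstrap
with 10,000 resamples; for the order-dependent TL statistic, each resample
is used in its drawn order.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "QARecord",
    "SPCLimits",
    "SPCError",
    "DELIVERABILITY_CUT",
    "filter_deliverable",
    "action_limit",
    "moving_range_mean",
    "tolerance_limit",
    "bootstrap_ci",
    "evaluate_period",
    "monitor",
]

#: GP%(3%G, 2 mm) must strictly exceed this to count as clinically deliverable.
DELIVERABILITY_CUT = 90.0
#: Individuals-chart constant 3/d2, d2 = 1.128.
MR_CONSTANT = 2.660
#: Baseline period size: the first 40 collected measurements.
BASELINE_SIZE = 40


class SPCError(RuntimeError):
    """Raised for ill-posed SPC computations (too few records, missing GP%)."""


@dataclass
class QARecord:
    """One measured QA delivery: GP% under each criteria label."""

    plan_id: str
    date: _dt.date
    gp: dict[str, float]
    clinical: bool = True

    def __post_init__(self) -> None:
        for label, value in self.gp.items():
            if not (0.0 <= value <= 100.0):
                raise ValueError(f"{self.plan_id}: GP%({label}) = {value} outside [0, 100]")


@dataclass(frozen=True)
class SPCLimits:
    """Control-chart summary of one monitoring period."""

    n: int
    x_bar: float
    sigma: float
    mr_bar: float
    al_cs: float
    tl_cs: float
    ci_al: tuple[float, float]
    ci_tl: tuple[float, float]
    in_control: bool
    period: tuple[str, str] | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        if self.al_cs > 100.0 + 1e-9:
            raise ValueError("AL_cs cannot exceed 100")
        if self.tl_cs > self.x_bar + 1e-9:
            raise ValueError("TL_cs cannot exceed the period mean")
        for lo, hi in (self.ci_al, self.ci_tl):
            if lo > hi:
                raise ValueError("confidence interval bounds out of order")


def filter_deliverable(records: list[QARecord], label: str = "3G2") -> list[QARecord]:
    """Keep records with GP%(3%G, 2 mm) strictly above the 90% cut.

    Records failing the cut stay in the caller's dataset (they are re-planned
    clinically) but are excluded from SPC limit computation.
    """
    kept = []
    for rec in records:
        if label not in rec.gp:
            raise SPCError(f"record {rec.plan_id!r} is missing the {label!r} GP% value")
        if rec.gp[label] > DELIVERABILITY_CUT:
            kept.append(rec)
    return kept


def action_limit(x_bar: float, sigma: float) -> float:
    """Clinic-specific action limit: 100 - 3*sqrt(sigma^2 + (x_bar - 100)^2)."""
    if sigma < 0:
        raise ValueError("sigma must be non-negative")
    if x_bar > 100.0:
        raise ValueError("mean GP% cannot exceed 100")
    return 100.0 - 3.0 * float(np.hypot(sigma, x_bar - 100.0))


def moving_range_mean(series: np.ndarray) -> float:
    """Mean absolute difference between consecutive observations."""
    x = np.asarray(series, dtype=float).ravel()
    if x.size < 2:
        raise SPCError("moving range needs at least 2 observations in delivery order")
    return float(np.abs(np.diff(x)).mean())


def tolerance_limit(series: np.ndarray) -> float:
    """Clinic-specific tolerance limit: mean - 2.660 * mean moving range."""
    x = np.asarray(series, dtype=float).ravel()
    return float(x.mean()) - MR_CONSTANT * moving_range_mean(x)


def _stat_matrix(resamples: np.ndarray, statistic: str) -> np.ndarray:
    """Statistic of each bootstrap resample (rows, used in drawn order)."""
    if statistic == "action":
        m = resamples.mean(axis=1)
        s = resamples.std(axis=1, ddof=1)
        return 100.0 - 3.0 * np.hypot(s, m - 100.0)
    if statistic == "tolerance":
        mr = np.abs(np.diff(resamples, axis=1)).mean(axis=1)
        return resamples.mean(axis=1) - MR_CONSTANT * mr
    raise ValueError("statistic must be 'action' or 'tolerance'")


def bootstrap_ci(
    series: np.ndarray,
    statistic: str,
    n_boot: int = 10000,
    level: float = 0.95,
    seed: int | np.random.SeedSequence | None = None,
) -> tuple[float, float]:
    """Percentile bootstrap confidence interval for AL_cs or TL_cs.

    Resamples are drawn with replacement; the TL statistic consumes each
    resampled sequence in its drawn order.  Reproducible given ``seed``.
    """
    x = np.asarray(series, dtype=float).ravel()
    if x.size < 2:
        raise SPCError("bootstrap needs a series of length >= 2")
    if seed is None:
        raise SPCError("bootstrap requires an explicit seed for reproducibility")
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, x.size, size=(n_boot, x.size))
    stats = _stat_matrix(x[idx], statistic)
    alpha = 100.0 * (1.0 - level) / 2.0
    lo, hi = np.percentile(stats, [alpha, 100.0 - alpha])
    return float(lo), float(hi)


def _series_of(records: list[QARecord], label: str) -> tuple[list[QARecord], np.ndarray]:
    recs = sorted(records, key=lambda r: (r.date, r.plan_id))
    for rec in recs:
        if label not in rec.gp:
            raise SPCError(f"record {rec.plan_id!r} is missing the {label!r} GP% value")
    return recs, np.asarray([r.gp[label] for r in recs], dtype=float)


def evaluate_period(
    records: list[QARecord],
    baseline: bool = False,
    seed: int | np.random.SeedSequence | None = None,
    label: str = "3G2",
    n_boot: int = 10000,
) -> SPCLimits:
    """Control limits for one monitoring period.

    Records must already be deliverability-filtered.  A baseline period uses
    the first 40 records in date order and requires at least 40.  The period
    is in control iff no record lies below its AL_cs.
    """
    recs, x = _series_of(records, label)
    if baseline:
        if x.size < BASELINE_SIZE:
            raise SPCError(
                f"baseline period needs >= {BASELINE_SIZE} records, got {x.size}"
            )
        recs, x = recs[:BASELINE_SIZE], x[:BASELINE_SIZE]
    if x.size < 2:
        raise SPCError("a period needs at least 2 records")
    x_bar = float(x.mean())
    sigma = float(x.std(ddof=1))
    mr_bar = moving_range_mean(x)
    al = action_limit(x_bar, sigma)
    tl = tolerance_limit(x)
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    s_al, s_tl = ss.spawn(2)
    ci_al = bootstrap_ci(x, "action", n_boot=n_boot, seed=s_al)
    ci_tl = bootstrap_ci(x, "tolerance", n_boot=n_boot, seed=s_tl)
    return SPCLimits(
        n=int(x.size),
        x_bar=x_bar,
        sigma=sigma,
        mr_bar=mr_bar,
        al_cs=al,
        tl_cs=tl,
        ci_al=ci_al,
        ci_tl=ci_tl,
        in_control=bool(np.all(x >= al)),
        period=(recs[0].date.isoformat(), recs[-1].date.isoformat()),
    )


def monitor(
    records: list[QARecord],
    period_boundaries: list[_dt.date],
    seed: int | np.random.SeedSequence | None = None,
    label: str = "3G2",
    n_boot: int = 10000,
) -> tuple[list[SPCLimits], list[bool]]:
    """Periodic re-evaluation of the control limits with drift detection.

    ``period_boundaries`` are the interior cut dates partitioning the date
    range into consecutive periods (a record belongs to the first period
    whose boundary is strictly after its date).  The first period is the
    baseline.  A drift flag is raised between consecutive periods when
    their bootstrap confidence intervals for AL_cs or TL_cs are disjoint.
    """
    recs, _ = _series_of(records, label)
    boundaries = sorted(period_boundaries)
    periods: list[list[QARecord]] = [[] for _ in range(len(boundaries) + 1)]
    for rec in recs:
        k = sum(rec.date >= b for b in boundaries)
        periods[k].append(rec)
    for k, chunk in enumerate(periods):
        if not chunk:
            lo = boundaries[k - 1].isoformat() if k > 0 else "-inf"
            hi = boundaries[k].isoformat() if k < len(boundaries) else "+inf"
            raise SPCError(f"period {k + 1} [{lo}, {hi}) contains no records")
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    child_seeds = ss.spawn(len(periods))
    limits = [
        evaluate_period(chunk, baseline=(k == 0), seed=child_seeds[k], label=label, n_boot=n_boot)
        for k, chunk in enumerate(periods)
    ]

    def _disjoint(a: tuple[float, float], b: tuple[float, float]) -> bool:
        return a[1] < b[0] or b[1] < a[0]

    drift = [
        _disjoint(p.ci_al, q.ci_al) or _disjoint(p.ci_tl, q.ci_tl)
        for p, q in zip(limits[:-1], limits[1:])
    ]
    return limits, drift
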