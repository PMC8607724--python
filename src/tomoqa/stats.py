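"""Cohort statistics: site-wise GP% comparison and planning-parameter screening.

Treatment sites are compared with a Kruskal-Wallis test followed by
pairwise two-sided rank-sum tests with Bonferroni correction.  Planning
parameters enter a main-effects n-way ANOVA on GP% only after a collinearity
screen: a parameter is dropped when its Pearson |r| against an
already-included parameter reaches 0.8 (the correlation-test p-value is
logged alongside).  Continuous parameters are discretized into tertiles for
the ANOVA; sums of squares are Type II, so factor order does not matter.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats as sps
import statsmodels.api as sm
import statsmodels.formula.api as smf

__all__ = [
    "TestReport",
    "StatsError",
    "kruskal_wallis",
    "posthoc_bonferroni",
    "screen_predictors",
    "nway_anova",
    "ANOVA_FACTORS",
]


class StatsError(RuntimeError):
    """Raised for ill-posed statistical designs."""


@dataclass
class TestReport:
    """Outcome of one statistical test (plus optional post-hoc table)."""

    name: str
    statistic: float
    p_value: float | None
    group_labels: list[str] = field(default_factory=list)
    posthoc: pd.DataFrame | None = None
    factor_p_values: dict[str, float] = field(default_factory=dict)
    included: list[str] = field(default_factory=list)
    excluded: list[dict] = field(default_factory=list)

    def __post_init__(self) -> None:
        ps = list(self.factor_p_values.values())
        if self.p_value is not None:
            ps.append(self.p_value)
        for p in ps:
            if not (0.0 <= p <= 1.0):
                raise ValueError(f"p-value {p} outside [0, 1]")


def _validate_groups(groups: dict[str, np.ndarray], min_size: int = 2) -> dict[str, np.ndarray]:
    if len(groups) < 2:
        raise StatsError("need at least 2 groups")
    out = {}
    for label, values in groups.items():
        x = np.asarray(values, dtype=float).ravel()
        if x.size < min_size:
            raise StatsError(f"group {label!r} has fewer than {min_size} values")
        out[label] = x
    return out


def kruskal_wallis(groups: dict[str, np.ndarray]) -> TestReport:
    """Rank-based H test (tie-corrected) that the groups share a distribution.

    Degenerate input where every observation is identical yields H = 0,
    p = 1 rather than an error.
    """
    groups = _validate_groups(groups)
    pooled = np.concatenate(list(groups.values()))
    if np.all(pooled == pooled[0]):
        return TestReport("kruskal-wallis", 0.0, 1.0, group_labels=list(groups))
    h, p = sps.kruskal(*groups.values())
    return TestReport("kruskal-wallis", float(h), float(p), group_labels=list(groups))


def posthoc_bonferroni(groups: dict[str, np.ndarray]) -> pd.DataFrame:
    """Pairwise two-sided rank-sum tests, Bonferroni-adjusted.

    Adjusted p = min(1, m * p_raw) with m = k(k-1)/2 comparisons.  Returns a
    symmetric DataFrame of adjusted p-values (NaN on the diagonal).  Meant
    to follow a significant Kruskal-Wallis test; that gate is the caller's.
    """
    groups = _validate_groups(groups)
    labels = list(groups)
    m = len(labels) * (len(labels) - 1) // 2
    table = pd.DataFrame(np.nan, index=labels, columns=labels)
    for a, b in combinations(labels, 2):
        _, p_raw = sps.ranksums(groups[a], groups[b])
        p_adj = min(1.0, m * float(p_raw))
        table.loc[a, b] = table.loc[b, a] = p_adj
    return table


def screen_predictors(
    table: pd.DataFrame,
    parameters: list[str] | None = None,
    r_threshold: float = 0.8,
) -> TestReport:
    """Greedy collinearity screen over numeric planning parameters.

    Parameters are visited in the given (documented, fixed) order; one is
    excluded when its Pearson |r| against any already-included parameter is
    >= ``r_threshold``.  Zero-variance parameters are excluded with a
    reason, not an error.  The exclusion log records the culprit pair, r and
    the correlation-test p-value.
    """
    if len(table) < 3:
        raise StatsError("screening needs at least 3 records")
    parameters = list(parameters) if parameters is not None else list(table.columns)
    included: list[str] = []
    excluded: list[dict] = []
    for name in parameters:
        x = table[name].to_numpy(dtype=float)
        if np.ptp(x) == 0:
            excluded.append({"parameter": name, "reason": "zero variance", "vs": None, "r": None})
            continue
        culprit = None
        for other in included:
            r, p = sps.pearsonr(x, table[other].to_numpy(dtype=float))
            if abs(r) >= r_threshold:
                culprit = {"parameter": name, "reason": "collinear", "vs": other,
                           "r": float(r), "p": float(p)}
                break
        if culprit is None:
            included.append(name)
        else:
            excluded.append(culprit)
    return TestReport(
        "predictor-screen", float("nan"), None, included=included, excluded=excluded
    )


#: Factor order of the default influence analysis.
ANOVA_FACTORS = (
    "site",
    "mf",
    "ttdf_s_per_cGy",
    "mean_lot_ms",
    "max_lot_ms",
    "pitch",
    "gantry_period_s",
    "couch_speed_mm_s",
)


def _tertile(x: pd.Series, name: str) -> pd.Series:
    binned = pd.qcut(x, 3, labels=False, duplicates="drop")
    if binned.nunique() < 2:
        raise StatsError(f"factor {name!r} has fewer than 2 levels after tertile binning")
    return binned.astype("category")


def nway_anova(
    response: np.ndarray,
    factors: pd.DataFrame,
    continuous_bins: int = 3,
) -> TestReport:
    """Main-effects n-way ANOVA of GP% on the given factors.

    Non-numeric columns (e.g. treatment site) are used as-is; numeric
    columns are discretized into tertiles.  Type II sums of squares give
    order-invariant per-factor p-values.  A singular (aliased) design is an
    error listing the offending factors.
    """
    y = np.asarray(response, dtype=float).ravel()
    if len(factors) != y.size:
        raise StatsError("response and factor table lengths differ")
    if y.size <= len(factors.columns) + 1:
        raise StatsError("need more observations than model parameters")
    design = pd.DataFrame(index=factors.index)
    for name in factors.columns:
        col = factors[name]
        if pd.api.types.is_numeric_dtype(col):
            design[name] = _tertile(col.astype(float), name)
        else:
            if col.nunique() < 2:
                raise StatsError(f"factor {name!r} has fewer than 2 levels")
            design[name] = col.astype("category")
    data = design.copy()
    data["gp"] = y
    terms = [f"C(Q('{name}'))" for name in design.columns]
    model = smf.ols("gp ~ " + " + ".join(terms), data=data).fit()
    rank = np.linalg.matrix_rank(model.model.exog)
    if rank < model.model.exog.shape[1]:
        aliased = _find_aliased(design)
        raise StatsError(f"singular design; aliased factors: {aliased}")
    table = sm.stats.anova_lm(model, typ=2)
    p_values = {
        name: float(table.loc[f"C(Q('{name}'))", "PR(>F)"]) for name in design.columns
    }
    return TestReport(
        "nway-anova",
        float(model.fvalue),
        None,
        group_labels=list(design.columns),
        factor_p_values=p_values,
    )


def _find_aliased(design: pd.DataFrame) -> list[str]:
    """Factors whose dummy block is linearly dependent on the others."""
    blocks = {c: pd.get_dummies(design[c], drop_first=True).to_numpy(float) for c in design}
    aliased = []
    for name in design.columns:
        others = [blocks[c] for c in design.columns if c != name]
        X = np.column_stack([np.ones(len(design))] + others)
        full = np.column_stack([X, blocks[name]])
        if np.linalg.matrix_rank(full) < np.linalg.matrix_rank(X) + blocks[name].shape[1]:
            aliased.append(name)
    return aliased
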