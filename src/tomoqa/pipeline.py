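"""End-to-end QA analysis pipeline and its JSON report.

The pipeline mirrors the clinical QA programme: ingest (or simulate) GP%
results and plan parameters, apply the deliverability filter, run the
TG-218 control-limit monitoring over ~6-month periods, compare treatment
sites, screen planning parameters for collinearity and test their influence
on GP% with an n-way ANOVA.  The report is a versioned JSON document whose
numbers are recomputable from its own record list.
"""

from __future__ import annotations

import datetime as _dt
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import spc as _spc
from . import stats as _stats
from .plans import PlanRecord, records_to_frame, summarize_cohort
from .spc import QARecord
from .synthetic import CohortSpec, make_plan_cohort

__all__ = ["PipelineConfig", "PipelineError", "run_pipeline", "validate_report", "report_json"]

SCHEMA_VERSION = 1


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage and record."""


@dataclass
class PipelineConfig:
    """Protocol settings.  Defaults are the QA programme's stated settings:
    four criteria sets, 10% dose threshold, GP%(3G2) > 90% deliverability
    cut, 40-delivery baseline, 10,000 bootstrap resamples."""

    criteria_labels: tuple[str, ...] = ("3G2", "3L2", "3G3", "3L3")
    threshold_percent: float = 10.0
    deliverability_cut: float = 90.0
    baseline_size: int = 40
    n_boot: int = 10000
    period_boundaries: list[_dt.date] | None = None
    seed: int = 0
    cohort_spec: CohortSpec | None = None
    anova_criteria: tuple[str, ...] = ("3G2", "3L2")

    def __post_init__(self) -> None:
        if self.deliverability_cut != _spc.DELIVERABILITY_CUT:
            raise ValueError("deliverability cut is fixed at 90% by the protocol")
        if self.baseline_size != _spc.BASELINE_SIZE:
            raise ValueError("baseline size is fixed at 40 by the protocol")


def _default_boundaries(dates: list[_dt.date], n_periods: int = 4) -> list[_dt.date]:
    lo, hi = min(dates), max(dates)
    span = (hi - lo).days + 1
    return [lo + _dt.timedelta(days=round(k * span / n_periods)) for k in range(1, n_periods)]


def _limits_dict(lim: _spc.SPCLimits) -> dict:
    return {
        "n": lim.n,
        "x_bar": lim.x_bar,
        "sigma": lim.sigma,
        "mr_bar": lim.mr_bar,
        "al_cs": lim.al_cs,
        "tl_cs": lim.tl_cs,
        "ci_al": list(lim.ci_al),
        "ci_tl": list(lim.ci_tl),
        "in_control": lim.in_control,
        "period": list(lim.period) if lim.period else None,
    }


def run_pipeline(
    config: PipelineConfig,
    qa_records: list[QARecord] | None = None,
    plan_records: list[PlanRecord] | None = None,
) -> dict:
    """Execute the full analysis and return the JSON-serializable report."""
    if qa_records is None:
        if config.cohort_spec is None:
            raise PipelineError("input: no QA records and no simulation spec given")
        plan_records, qa_records = make_plan_cohort(config.cohort_spec, seed=config.seed)
    if not qa_records:
        raise PipelineError("input: empty QA record list")

    report: dict = {
        "schema_version": SCHEMA_VERSION,
        "seed": config.seed,
        "settings": {
            "criteria_labels": list(config.criteria_labels),
            "threshold_percent": config.threshold_percent,
            "deliverability_cut": config.deliverability_cut,
            "baseline_size": config.baseline_size,
            "n_boot": config.n_boot,
        },
        "log": [],
    }
    log = report["log"]
    log.append("defaults in force: DTA search radius 3*dta, search step dta/10, "
               "gamma = 1.0 passes, SD with n-1 denominator, mR = successive "
               "absolute differences, strict > 90% deliverability cut")

    # --- deliverability filter -------------------------------------------
    try:
        deliverable = _spc.filter_deliverable(qa_records)
    except _spc.SPCError as exc:
        raise PipelineError(f"filter: {exc}") from exc
    excluded_ids = sorted(
        {r.plan_id for r in qa_records} - {r.plan_id for r in deliverable}
    )
    for pid in excluded_ids:
        log.append(f"excluded from SPC (GP% 3G2 <= 90): {pid}")
    report["n_records"] = len(qa_records)
    report["n_deliverable"] = len(deliverable)
    report["excluded_plan_ids"] = excluded_ids

    # --- SPC monitoring ---------------------------------------------------
    boundaries = config.period_boundaries
    if boundaries is None:
        boundaries = _default_boundaries([r.date for r in deliverable])
    try:
        limits, drift = _spc.monitor(
            deliverable, boundaries, seed=config.seed, n_boot=config.n_boot
        )
    except _spc.SPCError as exc:
        raise PipelineError(f"spc: {exc}") from exc
    report["spc"] = {
        "boundaries": [b.isoformat() for b in boundaries],
        "periods": [_limits_dict(l) for l in limits],
        "drift_flags": list(drift),
    }

    # --- site comparison --------------------------------------------------
    site_block: dict = {}
    if plan_records is not None:
        site_of = {p.plan_id: p.site for p in plan_records}
        for label in config.anova_criteria:
            groups: dict[str, list[float]] = {}
            for r in qa_records:
                if r.plan_id in site_of and label in r.gp:
                    groups.setdefault(site_of[r.plan_id], []).append(r.gp[label])
            groups = {s: v for s, v in groups.items() if len(v) >= 2}
            if len(groups) < 2:
                log.append(f"site comparison skipped for {label}: fewer than 2 groups")
                continue
            kw = _stats.kruskal_wallis({s: np.asarray(v) for s, v in groups.items()})
            entry = {"h": kw.statistic, "p": kw.p_value, "groups": kw.group_labels}
            if kw.p_value is not None and kw.p_value < 0.05:
                ph = _stats.posthoc_bonferroni({s: np.asarray(v) for s, v in groups.items()})
                entry["posthoc_adjusted_p"] = {
                    f"{a}|{b}": ph.loc[a, b]
                    for a in ph.index
                    for b in ph.columns
                    if a < b
                }
            site_block[label] = entry
    report["site_comparison"] = site_block

    # --- cohort summary, screening, ANOVA --------------------------------
    if plan_records is not None and len(plan_records) >= 2:
        summary = summarize_cohort(plan_records)
        report["cohort_summary"] = {
            "parameters": {
                idx: {k: float(row[k]) for k in ("mean", "sd", "min", "max")}
                for idx, row in summary.iterrows()
            },
            "fw_split_percent": summary.attrs["fw_split_percent"],
        }
        frame = records_to_frame(plan_records).set_index("plan_id")
        gp_by_plan = {label: {} for label in config.anova_criteria}
        for r in qa_records:
            for label in config.anova_criteria:
                if label in r.gp:
                    gp_by_plan[label][r.plan_id] = r.gp[label]
        numeric = [f for f in _stats.ANOVA_FACTORS if f != "site"]
        screen = _stats.screen_predictors(frame[numeric], parameters=numeric)
        report["screening"] = {
            "included": screen.included,
            "excluded": screen.excluded,
        }
        for entry in screen.excluded:
            log.append(f"screened out {entry['parameter']}: {entry['reason']}"
                       + (f" vs {entry['vs']} (r={entry['r']:.3f})" if entry.get("vs") else ""))
        anova_block = {}
        for label in config.anova_criteria:
            ids = [pid for pid in frame.index if pid in gp_by_plan[label]]
            if len(ids) < 20:
                log.append(f"anova skipped for {label}: too few linked records")
                continue
            y = np.asarray([gp_by_plan[label][pid] for pid in ids])
            factors = frame.loc[ids, ["site"] + screen.included]
            try:
                rep = _stats.nway_anova(y, factors)
            except _stats.StatsError as exc:
                raise PipelineError(f"anova[{label}]: {exc}") from exc
            anova_block[label] = rep.factor_p_values
        report["anova_p_values"] = anova_block

    return report


_REQUIRED_KEYS = {
    "schema_version": int,
    "seed": int,
    "settings": dict,
    "n_records": int,
    "n_deliverable": int,
    "excluded_plan_ids": list,
    "spc": dict,
    "site_comparison": dict,
    "log": list,
}


def validate_report(report: dict) -> None:
    """Structural check of a pipeline report; raises ValueError on mismatch."""
    for key, typ in _REQUIRED_KEYS.items():
        if key not in report:
            raise ValueError(f"report missing key {key!r}")
        if not isinstance(report[key], typ):
            raise ValueError(f"report key {key!r} has type {type(report[key]).__name__}, expected {typ.__name__}")
    spc = report["spc"]
    for key in ("boundaries", "periods", "drift_flags"):
        if key not in spc:
            raise ValueError(f"report['spc'] missing key {key!r}")
    if len(spc["drift_flags"]) != max(0, len(spc["periods"]) - 1):
        raise ValueError("drift flag count must be one less than period count")
    for period in spc["periods"]:
        for key in ("n", "x_bar", "sigma", "mr_bar", "al_cs", "tl_cs", "ci_al", "ci_tl", "in_control"):
            if key not in period:
                raise ValueError(f"period entry missing key {key!r}")


def report_json(report: dict) -> str:
    """Canonical (byte-stable) JSON rendering of a report."""
    return json.dumps(report, sort_keys=True, indent=2)


def write_report(report: dict, path: str | Path) -> None:
    Path(path).write_text(report_json(report) + "\n")
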