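"""Per-plan complexity descriptors correlated with QA passing rates.

Helical tomotherapy delivers with a binary multileaf collimator whose
per-projection leaf open times (LOT, ms) define the modulation of the plan.
Alongside the machine parameters (pitch, field width, gantry period, couch
motion) the pipeline derives:

* TTDF — total treatment time divided by the prescribed dose per fraction
  (s/cGy), a simple complexity surrogate tied to target length and pitch;
* LOT descriptors — min, mean, max and standard deviation of the LOT
  distribution, treated as one flat array per plan.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "SITES",
    "FIELD_WIDTHS_MM",
    "PlanRecord",
    "PlanMetrics",
    "compute_ttdf",
    "lot_descriptors",
    "summarize_cohort",
]

SITES = ("abdomen", "brain", "head_and_neck", "lungs", "pelvis", "prostate", "others")
FIELD_WIDTHS_MM = (10.0, 25.0, 50.0)


@dataclass
class PlanRecord:
    """Planning parameters of one treatment plan (one QA delivery)."""

    plan_id: str
    site: str
    dose_per_fraction_cGy: float
    mf: float
    pitch: float
    field_width_mm: float
    gantry_period_s: float
    total_treatment_time_s: float
    couch_speed_mm_s: float
    couch_travel_mm: float
    lot_ms: np.ndarray
    date: _dt.date

    def __post_init__(self) -> None:
        if self.site not in SITES:
            raise ValueError(f"unknown site {self.site!r}; expected one of {SITES}")
        if float(self.field_width_mm) not in FIELD_WIDTHS_MM:
            raise ValueError(f"field width must be one of {FIELD_WIDTHS_MM} mm")
        for name in (
            "dose_per_fraction_cGy",
            "mf",
            "pitch",
            "gantry_period_s",
            "total_treatment_time_s",
            "couch_speed_mm_s",
            "couch_travel_mm",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        lot = np.asarray(self.lot_ms, dtype=float).ravel()
        if lot.size == 0 or np.any(lot <= 0):
            raise ValueError("lot_ms must be a non-empty array of positive times")
        self.lot_ms = lot

    @property
    def ttdf_s_per_cGy(self) -> float:
        return compute_ttdf(self.total_treatment_time_s, self.dose_per_fraction_cGy)

    def metrics(self) -> "PlanMetrics":
        return lot_descriptors(self.lot_ms, ttdf_s_per_cGy=self.ttdf_s_per_cGy)


@dataclass(frozen=True)
class PlanMetrics:
    """Derived complexity metrics of a plan."""

    ttdf_s_per_cGy: float
    min_lot_ms: float
    mean_lot_ms: float
    max_lot_ms: float
    sd_lot_ms: float

    def __post_init__(self) -> None:
        if not (self.min_lot_ms <= self.mean_lot_ms <= self.max_lot_ms):
            raise ValueError("LOT descriptors must satisfy min <= mean <= max")
        if self.sd_lot_ms < 0:
            raise ValueError("sd_lot_ms must be non-negative")
        if self.ttdf_s_per_cGy <= 0:
            raise ValueError("ttdf must be positive")


def compute_ttdf(total_treatment_time_s: float, dose_per_fraction_cGy: float) -> float:
    """Treatment time over prescribed dose per fraction, in s/cGy."""
    if total_treatment_time_s <= 0 or dose_per_fraction_cGy <= 0:
        raise ValueError("treatment time and dose per fraction must be strictly positive")
    return total_treatment_time_s / dose_per_fraction_cGy


def lot_descriptors(lot_ms: np.ndarray, ttdf_s_per_cGy: float = 1.0) -> PlanMetrics:
    """Min/mean/max/SD of the leaf-open-time distribution.

    SD uses the sample (n-1) denominator; a singleton array gets sd = 0 by
    convention so degenerate plans stay processable.
    """
    lot = np.asarray(lot_ms, dtype=float).ravel()
    if lot.size == 0:
        raise ValueError("LOT array is empty")
    sd = float(np.std(lot, ddof=1)) if lot.size > 1 else 0.0
    return PlanMetrics(
        ttdf_s_per_cGy=float(ttdf_s_per_cGy),
        min_lot_ms=float(lot.min()),
        mean_lot_ms=float(lot.mean()),
        max_lot_ms=float(lot.max()),
        sd_lot_ms=sd,
    )


_SUMMARY_FIELDS = (
    ("dose_per_fraction_cGy", "Dose/Fraction [cGy]"),
    ("mf", "MF"),
    ("pitch", "Pitch"),
    ("gantry_period_s", "Gantry Period [s]"),
    ("total_treatment_time_s", "Total Treatment Time [s]"),
    ("ttdf_s_per_cGy", "TTDF [s/cGy]"),
    ("min_lot_ms", "min-LOT [ms]"),
    ("mean_lot_ms", "mean-LOT [ms]"),
    ("max_lot_ms", "max-LOT [ms]"),
    ("sd_lot_ms", "SD-LOT [ms]"),
    ("couch_speed_mm_s", "Couch speed [mm/s]"),
    ("couch_travel_mm", "Couch travel distance [mm]"),
)


def summarize_cohort(records: list[PlanRecord]) -> pd.DataFrame:
    """Cohort summary: mean, SD, min, max per planning parameter.

    Returns one row per parameter plus a field-width row carrying the
    percentage split over the 10/25/50 mm classes.  SD uses the n-1
    denominator.
    """
    if len(records) < 2:
        raise ValueError("cohort summary needs at least 2 records")
    table = records_to_frame(records)
    rows = []
    for col, label in _SUMMARY_FIELDS:
        x = table[col].to_numpy(dtype=float)
        rows.append(
            {
                "parameter": label,
                "mean": x.mean(),
                "sd": x.std(ddof=1),
                "min": x.min(),
                "max": x.max(),
            }
        )
    out = pd.DataFrame(rows).set_index("parameter")
    fw = table["field_width_mm"].to_numpy(dtype=float)
    split = {
        f"fw_{int(w)}mm_percent": 100.0 * float(np.count_nonzero(fw == w)) / fw.size
        for w in FIELD_WIDTHS_MM
    }
    out.attrs["fw_split_percent"] = split
    return out


def records_to_frame(records: list[PlanRecord]) -> pd.DataFrame:
    """Flatten plan records (with derived metrics) into a DataFrame."""
    rows = []
    for r in records:
        m = r.metrics()
        rows.append(
            {
                "plan_id": r.plan_id,
                "site": r.site,
                "date": r.date,
                "dose_per_fraction_cGy": r.dose_per_fraction_cGy,
                "mf": r.mf,
                "pitch": r.pitch,
                "field_width_mm": r.field_width_mm,
                "gantry_period_s": r.gantry_period_s,
                "total_treatment_time_s": r.total_treatment_time_s,
                "couch_speed_mm_s": r.couch_speed_mm_s,
                "couch_travel_mm": r.couch_travel_mm,
                "ttdf_s_per_cGy": m.ttdf_s_per_cGy,
                "min_lot_ms": m.min_lot_ms,
                "mean_lot_ms": m.mean_lot_ms,
                "max_lot_ms": m.max_lot_ms,
                "sd_lot_ms": m.sd_lot_ms,
            }
        )
    return pd.DataFrame(rows)
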