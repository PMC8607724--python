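"""Tabular I/O for QA records, plan records and monitoring periods.

File dialects
-------------
* qa.csv — columns ``plan_id, date, gp_3G2, gp_3L2, gp_3G3, gp_3L3``
  (any subset of the gp_* columns; dates ISO).
* plans.csv — one row per plan, columns named as the plan-record fields.
* LOT sidecar CSV — long format ``plan_id, lot_ms``, one leaf-open time
  per row, keyed by plan_id.
* periods.yaml — mapping with key ``boundaries``: list of ISO dates
  (interior period cut points).
"""

from __future__ import annotations

import datetime as _dt
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .plans import PlanRecord
from .spc import QARecord

__all__ = [
    "read_qa_csv",
    "write_qa_csv",
    "read_plans_csv",
    "write_plans_csv",
    "read_period_boundaries",
]

_PLAN_COLUMNS = [
    "plan_id",
    "site",
    "date",
    "dose_per_fraction_cGy",
    "mf",
    "pitch",
    "field_width_mm",
    "gantry_period_s",
    "total_treatment_time_s",
    "couch_speed_mm_s",
    "couch_travel_mm",
]


def _parse_date(value) -> _dt.date:
    if isinstance(value, _dt.date):
        return value
    return _dt.date.fromisoformat(str(value))


def read_qa_csv(path: str | Path) -> list[QARecord]:
    df = pd.read_csv(path)
    gp_cols = [c for c in df.columns if c.startswith("gp_")]
    if "plan_id" not in df.columns or "date" not in df.columns or not gp_cols:
        raise ValueError(f"{path}: expected columns plan_id, date and gp_* GP%% values")
    records = []
    for _, row in df.iterrows():
        gp = {c[3:]: float(row[c]) for c in gp_cols if pd.notna(row[c])}
        records.append(
            QARecord(
                plan_id=str(row["plan_id"]),
                date=_parse_date(row["date"]),
                gp=gp,
                clinical=bool(row.get("clinical", True)),
            )
        )
    return records


def write_qa_csv(records: list[QARecord], path: str | Path) -> None:
    labels = sorted({label for r in records for label in r.gp})
    rows = []
    for r in records:
        row = {"plan_id": r.plan_id, "date": r.date.isoformat()}
        row.update({f"gp_{label}": r.gp.get(label) for label in labels})
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


def read_plans_csv(path: str | Path, lot_path: str | Path) -> list[PlanRecord]:
    """Read plan records; LOT arrays come from the long-format sidecar."""
    df = pd.read_csv(path)
    missing = [c for c in _PLAN_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    lot_df = pd.read_csv(lot_path)
    if not {"plan_id", "lot_ms"} <= set(lot_df.columns):
        raise ValueError(f"{lot_path}: expected columns plan_id, lot_ms")
    lots = {pid: g["lot_ms"].to_numpy(float) for pid, g in lot_df.groupby("plan_id")}
    records = []
    for _, row in df.iterrows():
        pid = str(row["plan_id"])
        if pid not in lots:
            raise ValueError(f"{lot_path}: no LOT values for plan {pid!r}")
        records.append(
            PlanRecord(
                plan_id=pid,
                site=str(row["site"]),
                dose_per_fraction_cGy=float(row["dose_per_fraction_cGy"]),
                mf=float(row["mf"]),
                pitch=float(row["pitch"]),
                field_width_mm=float(row["field_width_mm"]),
                gantry_period_s=float(row["gantry_period_s"]),
                total_treatment_time_s=float(row["total_treatment_time_s"]),
                couch_speed_mm_s=float(row["couch_speed_mm_s"]),
                couch_travel_mm=float(row["couch_travel_mm"]),
                lot_ms=lots[pid],
                date=_parse_date(row["date"]),
            )
        )
    return records


def write_plans_csv(records: list[PlanRecord], path: str | Path, lot_path: str | Path) -> None:
    rows = []
    lot_rows = []
    for r in records:
        rows.append(
            {
                "plan_id": r.plan_id,
                "site": r.site,
                "date": r.date.isoformat(),
                "dose_per_fraction_cGy": r.dose_per_fraction_cGy,
                "mf": r.mf,
                "pitch": r.pitch,
                "field_width_mm": r.field_width_mm,
                "gantry_period_s": r.gantry_period_s,
                "total_treatment_time_s": r.total_treatment_time_s,
                "couch_speed_mm_s": r.couch_speed_mm_s,
                "couch_travel_mm": r.couch_travel_mm,
            }
        )
        for lot in np.asarray(r.lot_ms, float):
            lot_rows.append({"plan_id": r.plan_id, "lot_ms": lot})
    pd.DataFrame(rows, columns=_PLAN_COLUMNS).to_csv(path, index=False)
    pd.DataFrame(lot_rows).to_csv(lot_path, index=False)


def read_period_boundaries(path: str | Path) -> list[_dt.date]:
    with Path(path).open() as fh:
        payload = yaml.safe_load(fh)
    if not isinstance(payload, dict) or "boundaries" not in payload:
        raise ValueError(f"{path}: expected a mapping with key 'boundaries'")
    return [_parse_date(d) for d in payload["boundaries"]]
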