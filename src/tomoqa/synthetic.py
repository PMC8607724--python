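"""Synthetic QA data with the statistical structure the analysis assumes.

Three generators make every pipeline stage testable without clinical data:

* :func:`make_dose_pair` — a smooth planned dose field (mixture of Gaussian
  blobs on the unwrapped detector plane, 1.87 mm grid) and a "measured"
  detector point set obtained by sampling a perturbed copy of that field.
  Perturbations apply in a fixed order: global scale, rigid shift, local
  hotspot, then per-point noise.
* :func:`make_plan_cohort` — planning parameters drawn from truncated
  normals matching the clinical cohort's published mean/SD/range, site
  labels from the published case mix, and GP% values per criteria set from
  truncated normals capped at 100.
* :func:`make_gp_series` — an ordered GP% series with an optional level
  shift at a known changepoint, spanning four ~6-month monitoring periods.

All generators are reproducible given (spec, seed).
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass, field

import numpy as np

from .dose import DoseGrid, DosePointSet, DetectorGeometry, DEFAULT_GRID_SPACING_MM
from .plans import PlanRecord, SITES
from .spc import QARecord

__all__ = [
    "Hotspot",
    "PerturbationSpec",
    "GaussianBlobSpec",
    "CohortSpec",
    "make_dose_pair",
    "make_plan_cohort",
    "make_gp_series",
    "TABLE_PARAMS",
    "SITE_COUNTS",
    "FW_SPLIT_PERCENT",
    "GP_MODEL_DEFAULTS",
]

#: Cohort parameter distributions: name -> (mean, sd, min, max).
#: Treatment time and couch travel are drawn; TTDF and couch speed are
#: recomputed from them so derived fields stay internally consistent.
TABLE_PARAMS: dict[str, tuple[float, float, float, float]] = {
    "dose_per_fraction_cGy": (219.8, 62.6, 160.0, 500.0),
    "mf": (1.68, 0.28, 1.10, 2.79),
    "pitch": (0.39, 0.06, 0.12, 0.48),
    "gantry_period_s": (20.1, 7.3, 11.8, 52.8),
    "total_treatment_time_s": (299.7, 141.0, 66.3, 1241.3),
    "couch_travel_mm": (160.2, 88.9, 31.1, 895.2),
    "mean_lot_ms": (236.3, 82.7, 57.8, 617.1),
    "sd_lot_ms": (107.9, 44.2, 21.1, 316.1),
}

#: Case mix of the clinical cohort (site -> count, n = 385 planned).
SITE_COUNTS: dict[str, int] = {
    "abdomen": 28,
    "brain": 32,
    "head_and_neck": 77,
    "lungs": 71,
    "pelvis": 84,
    "prostate": 52,
    "others": 41,
}

#: Field-width class split (10/25/50 mm), percent.
FW_SPLIT_PERCENT: tuple[float, float, float] = (2.1, 92.0, 5.9)

#: GP% model per criteria label: (mean, sd).  The global-normalization
#: moments are the published cohort values; no SD is published for local
#: normalization, so those are free parameters chosen once for realism.
GP_MODEL_DEFAULTS: dict[str, tuple[float, float]] = {
    "3G2": (97.6, 2.6),
    "3L2": (90.9, 5.0),
    "3G3": (99.2, 1.3),
    "3L3": (94.5, 3.5),
}

#: Binary-MLC latency floor: leaf open times cannot fall below ~18 ms.
LOT_FLOOR_MS = 18.0

COHORT_START_DATE = _dt.date(2018, 6, 1)
COHORT_SPAN_DAYS = 730  # four ~6-month monitoring periods


def truncated_normal(
    rng: np.random.Generator,
    mean: float,
    sd: float,
    lo: float,
    hi: float,
    size: int,
) -> np.ndarray:
    """Rejection sampling from Normal(mean, sd) truncated to [lo, hi]."""
    if lo >= hi:
        raise ValueError(f"infeasible truncation bounds [{lo}, {hi}]")
    if sd < 0:
        raise ValueError("sd must be non-negative")
    if sd == 0:
        if not (lo <= mean <= hi):
            raise ValueError("degenerate distribution outside bounds")
        return np.full(size, mean)
    out = np.empty(size)
    n_have = 0
    while n_have < size:
        draw = rng.normal(mean, sd, size=2 * (size - n_have) + 16)
        draw = draw[(draw >= lo) & (draw <= hi)]
        take = min(draw.size, size - n_have)
        out[n_have : n_have + take] = draw[:take]
        n_have += take
    return out


# ---------------------------------------------------------------------------
# Dose pairs
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Hotspot:
    """Localized Gaussian dose excess on the measured side."""

    center_u_mm: float
    center_v_mm: float
    radius_mm: float
    amplitude_percent: float

    def __post_init__(self) -> None:
        if self.radius_mm <= 0:
            raise ValueError("hotspot radius must be positive")


@dataclass(frozen=True)
class PerturbationSpec:
    """Plan-vs-measurement discrepancy model, applied in order:
    scale -> shift -> hotspot -> noise."""

    global_scale: float = 1.0
    shift_mm: tuple[float, float] = (0.0, 0.0)  # (du, dv)
    noise_percent: float = 0.0
    hotspot: Hotspot | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_percent < 0:
            raise ValueError("noise_percent must be non-negative")
        if self.global_scale <= 0:
            raise ValueError("global_scale must be positive")


@dataclass(frozen=True)
class GaussianBlobSpec:
    """Smooth planned-dose field: a mixture of Gaussian blobs."""

    extent_u_mm: float = 120.0
    extent_v_mm: float = 120.0
    n_blobs: int | None = None  # drawn uniformly in [2, 5] when None
    peak_dose_gy: float = 2.0
    width_range_mm: tuple[float, float] = (12.0, 35.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.extent_u_mm <= 0 or self.extent_v_mm <= 0:
            raise ValueError("field extent must be positive")
        if self.peak_dose_gy <= 0:
            raise ValueError("peak dose must be positive")
        if self.n_blobs is not None and not (2 <= self.n_blobs <= 5):
            raise ValueError("n_blobs must lie in [2, 5]")

    def blobs(self) -> list[tuple[float, float, float, float]]:
        """(cu, cv, width, amplitude) for each blob, reproducible by seed."""
        rng = np.random.default_rng(self.seed)
        n = self.n_blobs if self.n_blobs is not None else int(rng.integers(2, 6))
        out = []
        for _ in range(n):
            cu = rng.uniform(0.25, 0.75) * self.extent_u_mm
            cv = rng.uniform(0.25, 0.75) * self.extent_v_mm
            w = rng.uniform(*self.width_range_mm)
            a = rng.uniform(0.4, 1.0) * self.peak_dose_gy
            out.append((cu, cv, w, a))
        return out

    def evaluate(self, u: np.ndarray, v: np.ndarray) -> np.ndarray:
        dose = np.zeros(np.broadcast(u, v).shape)
        for cu, cv, w, a in self.blobs():
            dose += a * np.exp(-((u - cu) ** 2 + (v - cv) ** 2) / (2.0 * w**2))
        return dose


def make_dose_pair(
    base: GaussianBlobSpec,
    perturbation: PerturbationSpec,
    geometry: DetectorGeometry | None = None,
    spacing_mm: float = DEFAULT_GRID_SPACING_MM,
    edge_margin_mm: float = 10.0,
) -> tuple[DoseGrid, DosePointSet]:
    """Planned grid plus measured detector points from a perturbed copy.

    The measured dose at each diode is the *bilinear* sample of the
    perturbed grid, so an identity perturbation reproduces the evaluation
    dose exactly (gamma = 0 at every diode).  Diodes closer than
    ``edge_margin_mm`` to the grid edge are dropped so the DTA search stays
    inside the grid.  Doses pushed negative by noise are clipped at zero
    and counted in ``meta["n_clipped_negative"]``.
    """
    geometry = geometry or DetectorGeometry()
    nu = int(np.floor(base.extent_u_mm / spacing_mm)) + 1
    nv = int(np.floor(base.extent_v_mm / spacing_mm)) + 1
    ug = spacing_mm * np.arange(nu)
    vg = spacing_mm * np.arange(nv)
    uu, vv = np.meshgrid(ug, vg)  # axis order (v, u) = (y, x)
    plan_values = base.evaluate(uu, vv)
    plan = DoseGrid(plan_values, (spacing_mm, spacing_mm), (0.0, 0.0))
    d_norm = float(plan_values.max())

    du, dv = perturbation.shift_mm
    measured_values = perturbation.global_scale * base.evaluate(uu - du, vv - dv)
    if perturbation.hotspot is not None:
        hs = perturbation.hotspot
        bump = (hs.amplitude_percent / 100.0) * d_norm * np.exp(
            -((uu - hs.center_u_mm) ** 2 + (vv - hs.center_v_mm) ** 2)
            / (2.0 * hs.radius_mm**2)
        )
        measured_values = measured_values + bump
    measured_grid = DoseGrid(
        np.clip(measured_values, 0.0, None), (spacing_mm, spacing_mm), (0.0, 0.0)
    )

    pu, pv = geometry.diode_positions_unwrapped()
    inside = (
        (pu >= edge_margin_mm)
        & (pu <= base.extent_u_mm - edge_margin_mm)
        & (pv >= edge_margin_mm)
        & (pv <= base.extent_v_mm - edge_margin_mm)
    )
    pu, pv = pu[inside], pv[inside]
    if pu.size == 0:
        raise ValueError("no diode positions fall inside the field; enlarge the extent")
    doses = measured_grid.interpolator()(np.column_stack([pv, pu]))
    rng = np.random.default_rng(perturbation.seed)
    if perturbation.noise_percent > 0:
        doses = doses * (1.0 + perturbation.noise_percent / 100.0 * rng.standard_normal(doses.size))
    n_clipped = int(np.count_nonzero(doses < 0))
    doses = np.clip(doses, 0.0, None)
    points = DosePointSet(
        pu, pv, doses, meta={"source": "synthetic", "n_clipped_negative": n_clipped}
    )
    return plan, points


# ---------------------------------------------------------------------------
# Plan cohorts and GP% series
# ---------------------------------------------------------------------------


@dataclass
class CohortSpec:
    """Statistical description of a synthetic QA cohort."""

    n_plans: int = 395
    site_probs: dict[str, float] = field(
        default_factory=lambda: {
            s: c / sum(SITE_COUNTS.values()) for s, c in SITE_COUNTS.items()
        }
    )
    params: dict[str, tuple[float, float, float, float]] = field(
        default_factory=lambda: dict(TABLE_PARAMS)
    )
    fw_split_percent: tuple[float, float, float] = FW_SPLIT_PERCENT
    gp_model: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(GP_MODEL_DEFAULTS)
    )
    site_effects: dict[str, dict[str, float]] = field(default_factory=dict)
    changepoint: tuple[int, float] | None = None  # (record index, GP% delta)
    n_lot: int = 400
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_plans < 0:
            raise ValueError("n_plans must be non-negative")
        total = sum(self.site_probs.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"site probabilities must sum to 1 (got {total})")
        for name, (mean, sd, lo, hi) in self.params.items():
            if sd < 0:
                raise ValueError(f"{name}: sd must be non-negative")
            if lo >= hi:
                raise ValueError(f"{name}: infeasible range [{lo}, {hi}]")
        for _, (mean, sd) in self.gp_model.items():
            if sd < 0:
                raise ValueError("GP% sd must be non-negative")


def _dates(n: int) -> list[_dt.date]:
    if n == 0:
        return []
    step = COHORT_SPAN_DAYS / n
    return [COHORT_START_DATE + _dt.timedelta(days=round(i * step)) for i in range(n)]


def make_plan_cohort(
    spec: CohortSpec, seed: int | None = None
) -> tuple[list[PlanRecord], list[QARecord]]:
    """Draw a full synthetic cohort of plan parameters and QA outcomes.

    Parameters come from truncated normals honoring the published
    mean/SD/range; TTDF and couch speed are recomputed from drawn time,
    dose and travel so derived fields are internally consistent.  GP% per
    criteria is a truncated normal capped at 100, with optional per-site
    offsets and a level shift after ``spec.changepoint``.
    """
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    n = spec.n_plans
    sites = rng.choice(list(spec.site_probs), size=n, p=list(spec.site_probs.values()))
    fw = rng.choice(
        [10.0, 25.0, 50.0], size=n, p=np.asarray(spec.fw_split_percent) / 100.0
    )
    draws = {
        name: truncated_normal(rng, *spec.params[name], size=n) for name in spec.params
    }
    dates = _dates(n)

    plan_records: list[PlanRecord] = []
    qa_records: list[QARecord] = []
    for i in range(n):
        # LOT: normal draw clamped at the binary-MLC latency floor
        lot = np.maximum(
            rng.normal(draws["mean_lot_ms"][i], draws["sd_lot_ms"][i], size=spec.n_lot),
            LOT_FLOOR_MS,
        )
        time_s = draws["total_treatment_time_s"][i]
        travel = draws["couch_travel_mm"][i]
        plan_records.append(
            PlanRecord(
                plan_id=f"plan-{i:04d}",
                site=str(sites[i]),
                dose_per_fraction_cGy=draws["dose_per_fraction_cGy"][i],
                mf=draws["mf"][i],
                pitch=draws["pitch"][i],
                field_width_mm=float(fw[i]),
                gantry_period_s=draws["gantry_period_s"][i],
                total_treatment_time_s=time_s,
                couch_speed_mm_s=travel / time_s,
                couch_travel_mm=travel,
                lot_ms=lot,
                date=dates[i],
            )
        )
        gp = {}
        for label, (mean, sd) in spec.gp_model.items():
            mu = mean
            mu += spec.site_effects.get(label, {}).get(str(sites[i]), 0.0)
            if spec.changepoint is not None and i >= spec.changepoint[0]:
                mu += spec.changepoint[1]
            gp[label] = float(truncated_normal(rng, mu, sd, 0.0, 100.0, size=1)[0])
        qa_records.append(
            QARecord(plan_id=f"plan-{i:04d}", date=dates[i], gp=gp, clinical=True)
        )
    return plan_records, qa_records


def make_gp_series(
    n: int,
    mean: float,
    sd: float,
    changepoint_index: int = 0,
    delta: float = 0.0,
    seed: int = 0,
) -> list[QARecord]:
    """Ordered GP%(3G2) series with a level shift after the changepoint.

    Dates are spaced to span four ~6-month monitoring periods.  ``n = 0``
    returns an empty series.
    """
    if sd < 0:
        raise ValueError("sd must be non-negative")
    if not (0 <= changepoint_index <= n):
        raise ValueError("changepoint_index must lie in [0, n]")
    rng = np.random.default_rng(seed)
    dates = _dates(n)
    out = []
    for i in range(n):
        mu = mean + (delta if i >= changepoint_index else 0.0)
        gp = float(truncated_normal(rng, mu, sd, 0.0, 100.0, size=1)[0])
        out.append(QARecord(plan_id=f"qa-{i:04d}", date=dates[i], gp={"3G2": gp}))
    return out
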