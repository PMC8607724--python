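"""Independent brute-force gamma oracle for cross-checking the engine.

Deliberately a different algorithm from the production search: an
exhaustive dense lattice scan over the *whole* evaluation grid (no search
radius cap) at half the engine's starting step, followed by a bounded
scipy Powell polish of every lattice candidate that could still contain
the global minimum.  Near-duplicate candidates are thinned to cluster
representatives before polishing.
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import minimize

from tomoqa.dose import DoseGrid, DosePointSet
from tomoqa.gamma import GammaCriteria, _bilinear, _max_gradient


def brute_force_gamma(
    reference: DosePointSet,
    evaluation: DoseGrid,
    criteria: GammaCriteria,
) -> np.ndarray:
    """Gamma for every reference point (NaN where threshold-excluded)."""
    d_norm = float(evaluation.values.max())
    cutoff = criteria.threshold_percent / 100.0 * d_norm
    dta = criteria.dta_mm
    (ylo, yhi), (xlo, xhi) = evaluation.extent_mm(0), evaluation.extent_mm(1)
    step = criteria.step_mm / 2.0
    xs = np.arange(xlo, xhi + step / 2, step)
    ys = np.arange(ylo, yhi + step / 2, step)
    gx, gy = np.meshgrid(xs, ys)
    gx = gx.ravel()
    gy = gy.ravel()
    dose_lattice = _bilinear(evaluation, gx, gy)
    g_max = _max_gradient(evaluation)

    out = np.full(len(reference), np.nan)
    for i, (u, v, d_ref) in enumerate(reference.points):
        if d_ref < cutoff:
            continue
        delta_d = (
            criteria.dd_percent / 100.0 * d_norm
            if criteria.normalization == "global"
            else criteria.dd_percent / 100.0 * d_ref
        )

        def gamma_of(p: np.ndarray) -> float:
            de = _bilinear(evaluation, np.atleast_1d(p[0]), np.atleast_1d(p[1]))[0]
            return float(
                np.sqrt(((p[0] - u) ** 2 + (p[1] - v) ** 2) / dta**2 + ((de - d_ref) / delta_d) ** 2)
            )

        g_lattice = np.sqrt(
            ((gx - u) ** 2 + (gy - v) ** 2) / dta**2 + ((dose_lattice - d_ref) / delta_d) ** 2
        )
        g_best = float(g_lattice.min())
        lipschitz = np.sqrt((1.0 / dta) ** 2 + (g_max / delta_d) ** 2)
        margin = lipschitz * step * 0.7072
        cand = np.flatnonzero(g_lattice <= g_best + margin)
        cand = cand[np.argsort(g_lattice[cand])][:4000]
        # thin to cluster representatives: best-first, separated by half a
        # grid cell so distinct basins are covered even when one long
        # near-minimum valley dominates the candidate list
        sep2 = max(step, 0.5 * min(evaluation.spacing_mm)) ** 2
        kept: list[int] = []
        for j in cand:
            if all((gx[j] - gx[q]) ** 2 + (gy[j] - gy[q]) ** 2 > sep2 for q in kept):
                kept.append(int(j))
                if len(kept) >= 48:
                    break
        best = g_best
        for j in kept:
            x0 = np.array([gx[j], gy[j]])
            res = minimize(
                gamma_of,
                x0=x0,
                method="Nelder-Mead",
                bounds=[(xlo, xhi), (ylo, yhi)],
                options={
                    "xatol": 1e-10,
                    "fatol": 1e-13,
                    "maxiter": 600,
                    "initial_simplex": np.array(
                        [x0, x0 + [0.5 * step, 0.0], x0 + [0.0, 0.5 * step]]
                    ),
                },
            )
            best = min(best, float(res.fun))
        out[i] = best
    return out
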