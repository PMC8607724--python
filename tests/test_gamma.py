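"""Gamma engine: analytic cases, threshold handling, invariants, oracle check."""

import numpy as np
import pytest

from tomoqa.dose import DoseGrid, DosePointSet
from tomoqa.gamma import (
    DEFAULT_CRITERIA_SETS,
    GammaCriteria,
    GammaError,
    GammaResult,
    batch_analyze,
    compute_gamma,
    passing_rate,
)

from oracle_gamma import brute_force_gamma


def _result_from_gammas(gammas, excluded=None):
    g = np.asarray(gammas, dtype=float)
    ex = np.zeros(g.size, bool) if excluded is None else np.asarray(excluded, bool)
    n_eval = int((~ex).sum())
    n_pass = int(np.count_nonzero(g[~ex] <= 1.0))
    return GammaResult(
        gamma_values=np.where(ex, np.nan, g),
        excluded=ex,
        normalization_dose_gy=2.0,
        n_evaluated=n_eval,
        n_passing=n_pass,
        gp_percent=100.0 * n_pass / n_eval,
    )


class TestCriteriaValidation:
    def test_defaults_are_protocol(self):
        c = GammaCriteria()
        assert (c.dd_percent, c.dta_mm, c.threshold_percent) == (3.0, 2.0, 10.0)
        assert c.search_radius_mm == 6.0 and c.step_mm == pytest.approx(0.2)
        assert c.label == "3G2"

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"dd_percent": 0},
            {"dta_mm": -1},
            {"threshold_percent": 100},
            {"normalization": "local", "threshold_percent": 0},
            {"max_search_radius_mm": 1.0},
            {"interp_step_mm": 0.5},
        ],
    )
    def test_invalid_settings(self, kwargs):
        with pytest.raises(ValueError):
            GammaCriteria(**kwargs)


class TestComputeGamma:
    def test_identity_pair_all_zero(self, uniform_grid, interior_points_factory):
        ref = interior_points_factory(uniform_grid, n=8, dose_jitter=0.0, seed=1)
        res = compute_gamma(ref, uniform_grid, GammaCriteria())
        assert np.nanmax(res.gamma_values) < 1e-10
        assert res.gp_percent == 100.0

    def test_uniform_field_dose_difference_boundary(self, uniform_grid):
        # on a flat field the DTA term cannot help: gamma = |dd| / (3% of D)
        ref_at = lambda f: DosePointSet([20.0], [20.0], [f * 2.0])
        crit = GammaCriteria(3.0, 2.0)
        g_at = lambda f: compute_gamma(ref_at(f), uniform_grid, crit).gamma_values[0]
        assert g_at(1.03) == pytest.approx(1.0, abs=1e-9)
        assert g_at(1.031) > 1.0
        assert compute_gamma(ref_at(1.031), uniform_grid, crit).gp_percent == 0.0

    def test_local_vs_global_denominator_ratio(self, uniform_grid):
        # reference dose at 50% of D_norm with a 3%-of-D_norm discrepancy:
        # local gamma doubles the global one (denominator halves)
        ref = DosePointSet([20.0], [20.0], [0.5 * 2.0 + 0.03 * 2.0])
        g_global = compute_gamma(ref, uniform_grid, GammaCriteria(3, 2, 10, "global"))
        g_local = compute_gamma(ref, uniform_grid, GammaCriteria(3, 2, 10, "local"))
        ratio = g_local.gamma_values[0] / g_global.gamma_values[0]
        # denominators: 0.03*D vs 0.03*0.53*D
        assert ratio == pytest.approx(1.0 / 0.53, rel=1e-6)

    def test_shifted_ramp_within_dta(self):
        # steep 1D ramp shifted by 2 mm: DTA absorbs the shift at 3%/2mm,
        # but not at 1 mm DTA for interior points
        x = np.arange(41) * 1.0
        vals = np.tile(0.1 + 0.045 * x, (41, 1))  # 4.5%/mm of max ~ steep
        grid = DoseGrid(vals, (1.0, 1.0), (0.0, 0.0))
        u = np.arange(12.0, 30.0)
        v = np.full(u.size, 20.0)
        shifted_dose = 0.1 + 0.045 * (u - 2.0)
        ref = DosePointSet(u, v, shifted_dose)
        res2 = compute_gamma(ref, grid, GammaCriteria(3, 2))
        assert np.nanmax(res2.gamma_values) <= 1.0 + 1e-9
        res1 = compute_gamma(ref, grid, GammaCriteria(3, 1, 10, "global"))
        assert np.nanmax(res1.gamma_values) > 1.0

    def test_threshold_excludes_points(self, uniform_grid):
        # two points below 10% of D_norm never enter GP%
        ref = DosePointSet([10, 12, 20, 22], [20, 20, 20, 20], [0.05, 0.1, 2.0, 2.0])
        res = compute_gamma(ref, uniform_grid, GammaCriteria())
        assert res.excluded.tolist() == [True, True, False, False]
        assert res.n_evaluated == 2
        assert res.gp_percent == 100.0

    def test_all_below_threshold_is_error_not_zero(self, uniform_grid):
        ref = DosePointSet([10, 20], [20, 20], [0.01, 0.02])
        with pytest.raises(GammaError, match="undefined"):
            compute_gamma(ref, uniform_grid, GammaCriteria())

    def test_reference_outside_grid(self, uniform_grid):
        ref = DosePointSet([200.0], [20.0], [1.0])
        with pytest.raises(ValueError, match="outside"):
            compute_gamma(ref, uniform_grid, GammaCriteria())


class TestPassingRate:
    def test_boundary_counts_as_pass(self):
        res = _result_from_gammas([0.2, 0.8, 1.0, 1.2])
        assert passing_rate(res) == 75.0

    def test_all_zero(self):
        assert passing_rate(_result_from_gammas([0.0, 0.0])) == 100.0

    def test_excluded_points_never_counted(self):
        res = _result_from_gammas([9.0, 9.0, 0.5, 0.5], excluded=[True, True, False, False])
        assert passing_rate(res) == 100.0


class TestInvariants:
    def test_oracle_equivalence_small_pairs(self, interior_points_factory):
        from tomoqa.synthetic import GaussianBlobSpec, PerturbationSpec, make_dose_pair

        for seed in (11, 12):
            base = GaussianBlobSpec(extent_u_mm=36, extent_v_mm=36, seed=seed, width_range_mm=(8, 18))
            grid, _ = make_dose_pair(base, PerturbationSpec())
            ref = interior_points_factory(grid, n=4, dose_jitter=0.04, seed=seed)
            for crit in (GammaCriteria(3, 2), GammaCriteria(3, 2, 10, "local")):
                engine = compute_gamma(ref, grid, crit).gamma_values
                oracle = brute_force_gamma(ref, grid, crit)
                mask = ~np.isnan(oracle)
                assert np.abs(engine[mask] - oracle[mask]).max() < 1e-6

    def test_monotone_in_dta_and_dd(self, blob_pair_factory):
        grid, pts = blob_pair_factory(seed=3, global_scale=0.985, shift_mm=(1.5, 0.5), noise_percent=1.0)
        g_22 = compute_gamma(pts, grid, GammaCriteria(3, 2)).gamma_values
        g_33 = compute_gamma(pts, grid, GammaCriteria(3, 3)).gamma_values
        g_42 = compute_gamma(pts, grid, GammaCriteria(4, 2)).gamma_values
        m = ~np.isnan(g_22)
        assert np.all(g_33[m] <= g_22[m] + 1e-6)
        assert np.all(g_42[m] <= g_22[m] + 1e-6)

    def test_scale_invariance_global(self, blob_pair_factory):
        grid, pts = blob_pair_factory(seed=4, shift_mm=(1.0, -1.0), noise_percent=0.5)
        res = compute_gamma(pts, grid, GammaCriteria())
        scaled_grid = DoseGrid(grid.values * 3.7, grid.spacing_mm, grid.origin_mm)
        scaled_pts = DosePointSet(pts.u_mm, pts.v_mm, pts.dose_gy * 3.7)
        res_s = compute_gamma(scaled_pts, scaled_grid, GammaCriteria())
        np.testing.assert_allclose(res_s.gamma_values, res.gamma_values, atol=1e-7)

    def test_translation_equivariance(self, blob_pair_factory):
        grid, pts = blob_pair_factory(seed=5, shift_mm=(1.0, 0.0), noise_percent=0.5)
        res = compute_gamma(pts, grid, GammaCriteria())
        moved_grid = DoseGrid(
            grid.values,
            grid.spacing_mm,
            (grid.origin_mm[0] + 13.0, grid.origin_mm[1] - 7.0),
        )
        moved_pts = DosePointSet(pts.u_mm - 7.0, pts.v_mm + 13.0, pts.dose_gy)
        res_m = compute_gamma(moved_pts, moved_grid, GammaCriteria())
        assert res_m.gp_percent == res.gp_percent

    def test_convergence_in_search_step(self, blob_pair_factory):
        grid, pts = blob_pair_factory(seed=6, global_scale=0.97, shift_mm=(2.0, 1.0), noise_percent=1.0)
        gp_default = compute_gamma(pts, grid, GammaCriteria(3, 2)).gp_percent
        gp_fine = compute_gamma(pts, grid, GammaCriteria(3, 2, interp_step_mm=0.1)).gp_percent
        assert abs(gp_default - gp_fine) < 0.1


class TestBatchAnalyze:
    def test_identical_pair_row(self, uniform_grid, interior_points_factory):
        ref = interior_points_factory(uniform_grid, n=6, dose_jitter=0.0, seed=2)
        table = batch_analyze({"case": (ref, uniform_grid)}, DEFAULT_CRITERIA_SETS)
        assert table.shape == (1, 4)
        assert (table.loc["case"] == 100.0).all()
        assert list(table.columns) == ["3G2", "3L2", "3G3", "3L3"]

    def test_orderings_on_perturbed_case(self, blob_pair_factory):
        grid, pts = blob_pair_factory(seed=7, global_scale=0.975, shift_mm=(2.2, 0.0), noise_percent=1.2)
        table = batch_analyze([(pts, grid)], DEFAULT_CRITERIA_SETS)
        row = table.iloc[0]
        assert row["3G3"] >= row["3G2"]
        assert row["3L3"] >= row["3L2"]
        assert row["3L2"] <= row["3G2"]
        assert row["3L3"] <= row["3G3"]

    def test_failing_case_names_identifier(self, uniform_grid):
        bad_ref = DosePointSet([20.0], [20.0], [0.01])  # below threshold
        with pytest.raises(GammaError, match="case-7"):
            batch_analyze({"case-7": (bad_ref, uniform_grid)}, [GammaCriteria()])
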