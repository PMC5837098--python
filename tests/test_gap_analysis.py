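import numpy as np
import pytest

from maizesim import (
    EmergenceGrid,
    FieldLayout,
    fit_exponential,
    fit_quadratic,
    label_spots,
    simulate_emergence,
    simulate_replicates,
    spot_rate_sweep,
    spot_statistics,
    sweep_to_frame,
)
from conftest import bfs_spot_count


def _grid(cells, rate=0.5):
    cells = np.asarray(cells)
    layout = FieldLayout(cells.shape[0], cells.shape[1], 0.6, 0.3)
    return EmergenceGrid(layout, cells, rate=rate)


class TestLabeling:
    def test_full_grid_has_no_spots(self):
        assert label_spots(_grid(np.ones((4, 4)))).n_spots == 0

    def test_single_missing_cell_is_one_spot(self):
        cells = np.ones((3, 3))
        cells[1, 1] = 0
        lab = label_spots(_grid(cells))
        assert lab.n_spots == 1
        assert (lab.labels == 1).sum() == 1

    def test_diagonal_adjacency_definition(self):
        grid = _grid([[0, 1], [1, 0]])
        assert label_spots(grid, connectivity=4).n_spots == 2
        assert label_spots(grid, connectivity=8).n_spots == 1

    def test_label_ids_are_contiguous(self, rng):
        grid = _grid(rng.random((10, 10)) < 0.6)
        lab = label_spots(grid)
        assert sorted(np.unique(lab.labels[lab.labels > 0])) == list(range(1, lab.n_spots + 1))

    @pytest.mark.parametrize("connectivity", [0, 6, "eight"])
    def test_invalid_connectivity_rejected(self, connectivity):
        with pytest.raises(ValueError):
            label_spots(_grid(np.ones((2, 2))), connectivity=connectivity)

    @pytest.mark.parametrize("connectivity", [4, 8])
    def test_matches_flood_fill_oracle(self, rng, connectivity):
        for _ in range(500):
            cells = rng.random((8, 8)) < rng.uniform(0.2, 0.95)
            assert label_spots(_grid(cells), connectivity).n_spots == bfs_spot_count(
                cells, connectivity
            )


class TestSpotStatistics:
    def test_full_emergence_record(self):
        grids = [_grid(np.ones((5, 5)), rate=1.0)] * 3
        rec = spot_statistics(grids)
        assert rec.mean_missing == 0
        assert rec.mean_spots == 0
        assert rec.hundred_dot_spot == 0
        assert np.isnan(rec.spot_missing_seedling)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            spot_statistics([])

    def test_mixed_layouts_rejected(self):
        with pytest.raises(ValueError):
            spot_statistics([_grid(np.ones((2, 2))), _grid(np.ones((3, 3)))])

    def test_derived_column_identities(self, rng):
        layout = FieldLayout(9, 13, 0.6, 0.3)
        grids = list(simulate_replicates(layout, 0.7, 20, base_seed=11))
        rec = spot_statistics(grids)
        assert rec.hundred_dot_spot == pytest.approx(
            100 * rec.mean_spots / layout.n_positions, rel=1e-9
        )
        assert rec.spot_missing_seedling == pytest.approx(
            rec.mean_missing / rec.mean_spots, rel=1e-9
        )


class TestRateSweep:
    layout = FieldLayout(12, 24, 0.6, 0.3)

    def test_single_rate_single_replicate_equals_direct_statistics(self):
        [rec] = spot_rate_sweep(self.layout, [0.8], n_replicates=1, seed=5)
        [grid] = list(simulate_replicates(self.layout, 0.8, 1, base_seed=(5, 0)))
        direct = spot_statistics([grid])
        assert rec == direct

    def test_sweep_is_deterministic(self):
        a = spot_rate_sweep(self.layout, [0.9, 0.7], n_replicates=10, seed=3)
        b = spot_rate_sweep(self.layout, [0.9, 0.7], n_replicates=10, seed=3)
        assert a == b

    def test_invalid_rate_rejected(self):
        with pytest.raises(ValueError):
            spot_rate_sweep(self.layout, [1.5], n_replicates=2, seed=0)

    def test_standard_error_scales_inverse_root_n(self):
        # SE of the mean missing count should halve from 500 to 2000 replicates
        def est_se(n):
            missing = [
                (g.cells == 0).sum()
                for g in simulate_replicates(self.layout, 0.8, n, base_seed=9)
            ]
            return np.std(missing, ddof=1) / np.sqrt(n)

        ratio = est_se(500) / est_se(2000)
        assert ratio == pytest.approx(2.0, rel=0.15)

    def test_mean_missing_decreasing_and_unbiased(self, table3_layout):
        rates = (0.95, 0.9, 0.85, 0.8, 0.75, 0.7)
        records = spot_rate_sweep(table3_layout, rates, n_replicates=200, seed=2)
        missing = [r.mean_missing for r in records]
        assert all(b > a for a, b in zip(missing, missing[1:]))
        n = table3_layout.n_positions
        for rec in records:
            se = np.sqrt(n * rec.rate * (1 - rec.rate)) / np.sqrt(rec.n_replicates)
            assert abs(rec.mean_missing - n * (1 - rec.rate)) < 4 * se

    def test_hundred_dot_unimodal_with_interior_peak(self, table3_layout):
        rates = (0.95, 0.9, 0.85, 0.8, 0.75, 0.7)
        records = spot_rate_sweep(table3_layout, rates, n_replicates=300, seed=4)
        hd = np.array([r.hundred_dot_spot for r in records])
        peak = int(np.argmax(hd))
        assert rates[peak] in (0.75, 0.8, 0.85)
        # unimodal over the sweep: rises to the peak, falls after (rates descend)
        assert all(np.diff(hd[: peak + 1]) > 0)
        assert all(np.diff(hd[peak:]) < 0)

    def test_spot_count_matches_euler_characteristic(self, table3_layout):
        # expected 8-connected components ~ V - E + T for sparse zeros
        rho = 0.95
        q = 1 - rho
        nr, nc = table3_layout.n_rows, table3_layout.n_cols
        v = nr * nc * q
        e = (nr * (nc - 1) + (nr - 1) * nc + 2 * (nr - 1) * (nc - 1)) * q**2
        t = 4 * (nr - 1) * (nc - 1) * q**3
        [rec] = spot_rate_sweep(table3_layout, [rho], n_replicates=300, seed=6)
        assert rec.mean_spots == pytest.approx(v - e + t, rel=0.03)

    def test_frame_has_table_shape(self):
        records = spot_rate_sweep(self.layout, [0.9, 0.8, 0.7], n_replicates=5, seed=0)
        frame = sweep_to_frame(records)
        assert list(frame.columns) == [
            "rate", "mean_missing", "mean_spots", "hundred_dot_spot", "spot_missing_seedling",
        ]
        assert len(frame) == 3


class TestQuadraticFit:
    def test_exact_interpolation(self):
        x = np.array([0.0, 1.0, 2.0, 3.0])
        fit = fit_quadratic(x, 2 * x**2 - x + 3)
        assert fit.coefficients == pytest.approx((2, -1, 3))
        assert fit.r_squared == pytest.approx(1.0)

    def test_vertex_consistent_with_coefficients(self):
        x = np.linspace(0, 1, 7)
        fit = fit_quadratic(x, -2 * (x - 0.4) ** 2 + 5 + 0.01 * np.sin(9 * x))
        a, b, c = fit.coefficients
        vx, vy = fit.vertex
        assert vx == pytest.approx(-b / (2 * a), rel=1e-9)
        assert vy == pytest.approx(c - b**2 / (4 * a), rel=1e-9)

    def test_matches_normal_equations_oracle(self, rng):
        x = rng.uniform(0, 2, 12)
        y = rng.normal(size=12)
        design = np.column_stack([x**2, x, np.ones_like(x)])
        oracle = np.linalg.solve(design.T @ design, design.T @ y)
        assert fit_quadratic(x, y).coefficients == pytest.approx(tuple(oracle), rel=1e-9)

    def test_rank_deficient_design_rejected(self):
        with pytest.raises(ValueError):
            fit_quadratic([1.0, 1.0, 1.0, 1.0], [1.0, 2.0, 3.0, 4.0])

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            fit_quadratic([1.0, 2.0], [1.0, 2.0])


class TestExponentialFit:
    def test_exact_interpolation(self):
        x = np.linspace(0, 2, 6)
        for method in ("log-linear", "nonlinear"):
            fit = fit_exponential(x, 5 * np.exp(-2 * x), method=method)
            assert fit.coefficients == pytest.approx((5, -2), rel=1e-6)
            assert fit.r_squared == pytest.approx(1.0)

    def test_log_linear_matches_ols_on_logs_oracle(self, rng):
        x = rng.uniform(0, 1, 9)
        y = np.exp(rng.normal(size=9))
        design = np.column_stack([np.ones_like(x), x])
        intercept, slope = np.linalg.solve(design.T @ design, design.T @ np.log(y))
        alpha, beta = fit_exponential(x, y).coefficients
        assert alpha == pytest.approx(np.exp(intercept), rel=1e-9)
        assert beta == pytest.approx(slope, rel=1e-9)

    def test_nonpositive_y_rejected(self):
        with pytest.raises(ValueError):
            fit_exponential([1.0, 2.0, 3.0], [1.0, 0.0, 2.0])

    def test_unknown_method_rejected(self):
        with pytest.raises(ValueError):
            fit_exponential([1.0, 2.0], [1.0, 2.0], method="spline")

    def test_prediction_uses_fitted_curve(self):
        fit = fit_exponential([0.0, 1.0], [3.0, 3.0 * np.e])
        assert fit.predict(2.0) == pytest.approx(3.0 * np.e**2, rel=1e-9)
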