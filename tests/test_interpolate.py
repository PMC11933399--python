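import numpy as np
import pandas as pd
import pytest

from aquahazard.grids import GridSpec, InterpMethod, ParameterGrid
from aquahazard.interpolate import (
    VariogramKind,
    VariogramModel,
    fit_variogram,
    grid_to_district_values,
    idw,
    idw_points,
    interpolate_parameter,
    krige,
    krige_points,
    loo_standardized_rmse,
    ok_weights,
)
from conftest import make_strip_districts


def points_frame(coords, values, parameter="Chloride"):
    return pd.DataFrame(
        {"x": coords[:, 0], "y": coords[:, 1], parameter: values}
    )


def brute_force_ok(coords, values, variogram, query):
    """Independent dense solve of the augmented OK system."""
    n = len(coords)
    A = np.ones((n + 1, n + 1))
    A[n, n] = 0.0
    for i in range(n):
        for j in range(n):
            A[i, j] = variogram(np.linalg.norm(coords[i] - coords[j]))
    b = np.ones(n + 1)
    for i in range(n):
        b[i] = variogram(np.linalg.norm(coords[i] - query))
    sol = np.linalg.lstsq(A, b, rcond=None)[0]
    w = sol[:n]
    pred = w @ values
    var = w @ b[:n] + sol[n]
    return pred, var


def simulate_from_variogram(vm, n, rng, extent=100.0):
    """Gaussian field values at random points with covariance sill - gamma."""
    coords = rng.uniform(0, extent, size=(n, 2))
    d = np.linalg.norm(coords[:, None, :] - coords[None, :, :], axis=-1)
    cov = vm.covariance(d)
    np.fill_diagonal(cov, vm.sill)
    L = np.linalg.cholesky(cov + 1e-10 * np.eye(n))
    values = L @ rng.standard_normal(n)
    return coords, values


class TestVariogramFit:
    def test_iid_noise_sill_matches_variance(self, rng):
        coords = rng.uniform(0, 100, size=(500, 2))
        values = rng.standard_normal(500)
        vm = fit_variogram(points_frame(coords, values), "Chloride")
        assert vm.sill == pytest.approx(values.var(), rel=0.2)

    def test_constant_data_flagged_degenerate(self, rng):
        coords = rng.uniform(0, 100, size=(30, 2))
        vm = fit_variogram(points_frame(coords, np.full(30, 5.0)), "Chloride")
        assert vm.degenerate
        assert vm.sill == 0.0

    def test_known_spherical_model_range_recovered(self, rng):
        true = VariogramModel(VariogramKind.SPHERICAL, 0.0, 1.0, 30.0)
        coords, values = simulate_from_variogram(true, 1000, rng)
        vm = fit_variogram(points_frame(coords, values), "Chloride", "spherical")
        assert vm.range == pytest.approx(true.range, rel=0.3)

    def test_too_few_points_rejected(self, rng):
        coords = rng.uniform(0, 10, size=(9, 2))
        with pytest.raises(ValueError):
            fit_variogram(points_frame(coords, np.arange(9.0)), "Chloride")


class TestOrdinaryKriging:
    vm = VariogramModel(VariogramKind.SPHERICAL, 0.0, 2.0, 25.0)

    def test_matches_brute_force_oracle_on_random_configs(self, rng):
        """OK predictions equal a dense linear-solve oracle on 100 random
        <= 8-point configurations."""
        for _ in range(100):
            n = rng.integers(3, 9)
            coords = rng.uniform(0, 50, size=(n, 2))
            values = rng.normal(10, 3, n)
            query = rng.uniform(0, 50, size=2)
            pred, var = krige_points(
                points_frame(coords, values), "Chloride", self.vm,
                np.array([query[0]]), np.array([query[1]]),
            )
            exp_pred, exp_var = brute_force_ok(coords, values, self.vm, query)
            assert pred[0] == pytest.approx(exp_pred, abs=1e-8)
            assert var[0] == pytest.approx(max(exp_var, 0.0), abs=1e-8)

    def test_weights_sum_to_one(self, rng):
        coords = rng.uniform(0, 50, size=(12, 2))
        for _ in range(20):
            w, _ = ok_weights(coords, self.vm, rng.uniform(0, 50, size=2))
            assert w.sum() == pytest.approx(1.0, abs=1e-10)

    def test_exact_at_data_points_with_zero_nugget(self, rng):
        coords = rng.uniform(0, 50, size=(15, 2))
        values = rng.normal(0, 1, 15)
        pred, var = krige_points(
            points_frame(coords, values), "Chloride", self.vm,
            coords[:, 0], coords[:, 1],
        )
        np.testing.assert_allclose(pred, values, atol=1e-8)
        np.testing.assert_allclose(var, 0.0, atol=1e-8)

    def test_moving_neighborhood_close_to_global(self, rng):
        coords = rng.uniform(0, 100, size=(60, 2))
        values = rng.normal(5, 2, 60)
        qx, qy = rng.uniform(0, 100, 40), rng.uniform(0, 100, 40)
        frame = points_frame(coords, values)
        p_global, _ = krige_points(frame, "Chloride", self.vm, qx, qy, max_neighbors=None)
        p_moving, _ = krige_points(frame, "Chloride", self.vm, qx, qy, max_neighbors=40)
        np.testing.assert_allclose(p_moving, p_global, atol=0.3)

    def test_duplicate_points_averaged_with_warning(self, rng):
        coords = np.vstack([rng.uniform(0, 50, size=(5, 2))] * 2)
        values = np.concatenate([np.full(5, 1.0), np.full(5, 3.0)])
        with pytest.warns(UserWarning, match="duplicate"):
            pred, _ = krige_points(
                points_frame(coords, values), "Chloride", self.vm,
                coords[:1, 0], coords[:1, 1],
            )
        assert pred[0] == pytest.approx(2.0, abs=1e-8)

    def test_too_few_points_rejected(self):
        frame = points_frame(np.array([[0.0, 0.0], [0.0, 0.0]]), np.array([1.0, 1.0]))
        with pytest.raises(ValueError), pytest.warns(UserWarning):
            krige_points(frame, "Chloride", self.vm, np.array([1.0]), np.array([1.0]))


class TestIdw:
    def test_single_point_gives_constant_grid(self):
        frame = points_frame(np.array([[5.0, 5.0]]), np.array([7.0]))
        g = idw(frame, "Chloride", GridSpec(0, 0, 10, 10, 2.0))
        np.testing.assert_allclose(g.values, 7.0)

    def test_equidistant_midpoint_is_average(self):
        frame = points_frame(np.array([[0.0, 0.0], [10.0, 0.0]]), np.array([0.0, 10.0]))
        for power in (1.0, 2.0, 3.5):
            pred = idw_points(frame, "Chloride", np.array([5.0]), np.array([0.0]), power)
            assert pred[0] == pytest.approx(5.0)

    def test_matches_all_pairs_recomputation(self, rng):
        coords = rng.uniform(0, 20, size=(20, 2))
        values = rng.normal(3, 1, 20)
        qx, qy = rng.uniform(0, 20, 15), rng.uniform(0, 20, 15)
        pred = idw_points(points_frame(coords, values), "Chloride", qx, qy,
                          power=2.0, max_neighbors=20)
        for k in range(15):
            d = np.hypot(coords[:, 0] - qx[k], coords[:, 1] - qy[k])
            w = d**-2.0
            assert pred[k] == pytest.approx((w * values).sum() / w.sum(), abs=1e-10)

    def test_exact_at_data_point(self, rng):
        coords = rng.uniform(0, 20, size=(10, 2))
        values = rng.normal(0, 1, 10)
        pred = idw_points(points_frame(coords, values), "Chloride",
                          coords[:3, 0], coords[:3, 1])
        np.testing.assert_allclose(pred, values[:3])

    def test_bounded_by_neighbor_values(self, rng):
        coords = rng.uniform(0, 20, size=(30, 2))
        values = rng.normal(0, 1, 30)
        g = idw(points_frame(coords, values), "Chloride", GridSpec(0, 0, 20, 20, 1.0),
                max_neighbors=30)
        assert g.values.min() >= values.min() - 1e-12
        assert g.values.max() <= values.max() + 1e-12

    def test_nonpositive_power_rejected(self):
        frame = points_frame(np.array([[0.0, 0.0]]), np.array([1.0]))
        with pytest.raises(ValueError):
            idw_points(frame, "Chloride", np.array([1.0]), np.array([1.0]), power=0.0)


class TestLooStandardizedRmse:
    def test_calibrated_on_data_from_fitted_model(self, rng):
        """Data simulated exactly from a known variogram: the LOO
        standardized RMSE sits near 1 (honest kriging variances)."""
        true = VariogramModel(VariogramKind.EXPONENTIAL, 0.05, 1.0, 40.0)
        coords, values = simulate_from_variogram(true, 500, rng, extent=200.0)
        frame = points_frame(coords, values)
        vm = fit_variogram(frame, "Chloride", "exponential")
        assert loo_standardized_rmse(frame, "Chloride", vm) == pytest.approx(1.0, abs=0.15)

    def test_inflated_sill_halves_the_statistic(self, rng):
        true = VariogramModel(VariogramKind.EXPONENTIAL, 0.05, 1.0, 40.0)
        coords, values = simulate_from_variogram(true, 300, rng, extent=200.0)
        frame = points_frame(coords, values)
        vm = fit_variogram(frame, "Chloride", "exponential")
        inflated = VariogramModel(vm.model, 4 * vm.nugget, 4 * vm.sill, vm.range)
        ratio = loo_standardized_rmse(frame, "Chloride", inflated) / loo_standardized_rmse(
            frame, "Chloride", vm
        )
        assert ratio == pytest.approx(0.5, abs=0.1)

    def test_too_few_points_rejected(self, rng):
        coords = rng.uniform(0, 10, size=(9, 2))
        frame = points_frame(coords, np.arange(9.0))
        with pytest.raises(ValueError):
            loo_standardized_rmse(frame, "Chloride",
                                  VariogramModel(VariogramKind.SPHERICAL, 0, 1, 10))


class TestGridToDistricts:
    def test_single_district_takes_all_cells(self):
        districts = make_strip_districts(1)
        spec = GridSpec(0, 0, 40, 60, 2.0)
        g = ParameterGrid("Chloride", spec, np.ones(spec.shape))
        pooled = grid_to_district_values(g, districts)
        assert len(pooled["D01"]) == spec.n_rows * spec.n_cols

    def test_equal_halves_get_equal_counts(self):
        districts = make_strip_districts(2)
        spec = GridSpec(0, 0, 40, 60, 2.0)
        g = ParameterGrid("Chloride", spec, np.ones(spec.shape))
        pooled = grid_to_district_values(g, districts)
        assert len(pooled["D01"]) == len(pooled["D02"])

    def test_partition_no_double_counting(self):
        districts = make_strip_districts(3)
        spec = GridSpec(0, 0, 40, 60, 2.0)
        g = ParameterGrid("Chloride", spec, np.ones(spec.shape))
        pooled = grid_to_district_values(g, districts)
        assert sum(len(v) for v in pooled.values()) == spec.n_rows * spec.n_cols


class TestRouting:
    def test_nitrate_goes_to_idw(self, rng):
        coords = rng.uniform(0, 40, size=(30, 2))
        frame = pd.DataFrame({"x": coords[:, 0], "y": coords[:, 1],
                              "Nitrate": rng.lognormal(0, 0.3, 30)})
        g = interpolate_parameter(frame, "Nitrate", GridSpec(0, 0, 40, 40, 5.0))
        assert g.method == InterpMethod.IDW

    def test_others_kriged_positive_after_log_backtransform(self, rng):
        coords = rng.uniform(0, 40, size=(40, 2))
        frame = pd.DataFrame({"x": coords[:, 0], "y": coords[:, 1],
                              "Chloride": rng.lognormal(4, 0.5, 40)})
        g = interpolate_parameter(frame, "Chloride", GridSpec(0, 0, 40, 40, 5.0))
        assert g.method == InterpMethod.ORDINARY_KRIGING
        assert (g.values > 0).all()
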