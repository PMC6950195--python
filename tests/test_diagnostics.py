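import numpy as np
import pandas as pd
import pytest

from stwreg import (
    KernelConfig,
    Location,
    PanelDataset,
    SimConfig,
    compare_models,
    corr_matrix,
    fit_lmm,
    fit_ols,
    fit_stwr,
    knn_binary_weights,
    moran_curve,
    morans_i,
    simulate,
    z_scores,
)
from stwreg.diagnostics import DiagnosticsError, KnnWeights, fit_metrics


class TestFitMetrics:
    def test_perfect_fit(self, rng):
        y = rng.standard_normal(30)
        ra2, rmse, mae = fit_metrics(y, y, 3.0)
        assert (ra2, rmse, mae) == (1.0, 0.0, 0.0)

    def test_adjusted_r2_formula(self, rng):
        # construct a fit with known R², then check the n/p adjustment
        y = rng.standard_normal(100)
        yhat = y.mean() + 0.5 * (y - y.mean())  # R² = 1 − 0.25·SST/SST... computed below
        e = y - yhat
        r2 = 1 - (e @ e) / np.sum((y - y.mean()) ** 2)
        ra2, _, _ = fit_metrics(y, yhat, 6.0)
        assert ra2 == pytest.approx(1 - 99 * (1 - r2) / 94)

    def test_hand_computed_rmse_mae(self):
        y = np.array([3.0, -4.0, 0.0])
        ra2, rmse, mae = fit_metrics(y, np.zeros(3), 1.0)
        assert rmse == pytest.approx(np.sqrt(25 / 3))
        assert mae == pytest.approx(7 / 3)

    def test_constant_response_rejected(self):
        with pytest.raises(DiagnosticsError):
            fit_metrics(np.ones(10), np.zeros(10), 1.0)


class TestZScores:
    def test_hand_computed_two_point_case(self):
        z = z_scores(np.array([1.0, 1.0]), np.array([0.0, 2.0]))
        assert np.allclose(z, [1 / np.sqrt(2), -1 / np.sqrt(2)])

    def test_zero_for_exact_fit(self, rng):
        y = rng.standard_normal(20)
        assert np.allclose(z_scores(y, y), 0.0)

    def test_ols_z_scores_average_zero(self, default_panel):
        ds, _ = default_panel
        fit = fit_ols(ds)
        assert abs(np.mean(z_scores(ds.y, fit.fitted))) < 1e-10

    def test_constant_fitted_rejected(self):
        with pytest.raises(DiagnosticsError):
            z_scores(np.arange(5.0), np.ones(5))


def _point_panel(coords, response=None):
    """Panel with one record per coordinate, constant predictors."""
    rows = []
    locations = []
    for i, (x, y) in enumerate(coords):
        locations.append(Location(i, f"p{i}", float(x), float(y)))
        rows.append(
            {"location_id": i, "t": 1, "SO2": 1.0, "NO2": 1.0, "PM10": 1.0,
             "CO": 1.0, "O3": 1.0,
             "PM25": 0.0 if response is None else float(response[i])}
        )
    return PanelDataset(locations=locations, records=pd.DataFrame(rows))


class TestKnnWeights:
    def test_equidistant_points_tie_broken_by_record_order(self):
        coords = [(0.5, 0.5)] * 3  # exactly coincident: all pairs tied
        w = knn_binary_weights(_point_panel(coords), 1)
        # ties at the single neighbour distance resolve to the earliest record
        assert w.indices.ravel().tolist() == [1, 0, 0]

    def test_k_equals_n_minus_one_is_complete(self):
        coords = [(0, 0), (1, 0), (2, 0), (3, 1)]
        w = knn_binary_weights(_point_panel(coords), 3)
        assert w.total == 12
        dense = w.to_sparse().toarray()
        assert np.all(dense + np.eye(4) == 1)

    def test_coincident_city_records_neighbor_within_city(self, small_varying_panel):
        # 13-style panel: every record's spatial distance to its own
        # city's other records is 0, so k < per-city count stays inside
        ds, _ = small_varying_panel  # 5 cities × 30 weeks
        w = knn_binary_weights(ds, 12)
        own_city = ds.records["location_id"].to_numpy()
        for i in (0, 40, 149):
            assert np.all(own_city[w.indices[i]] == own_city[i])

    def test_k_out_of_range(self, small_varying_panel):
        ds, _ = small_varying_panel
        with pytest.raises(DiagnosticsError):
            knn_binary_weights(ds, ds.n)


class TestMoransI:
    def test_hand_computed_two_point_case(self):
        # n=2, mutual weights, e = (1, −1): I = (2/2)·(−2)/2 = −1
        w = KnnWeights(indices=np.array([[1], [0]]), n=2, k=1)
        res = morans_i(np.array([1.0, -1.0]), w, method="permutation", n_perm=9, seed=0)
        assert res.I == pytest.approx(-1.0)
        assert res.expected == pytest.approx(-1.0)

    def test_expected_value_is_exact_formula(self, small_varying_panel):
        ds, _ = small_varying_panel
        w = knn_binary_weights(ds, 8)
        res = morans_i(np.sin(np.arange(ds.n)), w)
        assert res.expected == -1.0 / (ds.n - 1)

    def test_null_mean_matches_expectation(self):
        # iid residuals: mean of I over seeds ≈ −1/(n−1)
        ds, _ = simulate(SimConfig(n_locations=25, n_times=20, seed=3))
        w = knn_binary_weights(ds, 8)
        rng = np.random.default_rng(0)
        vals = [morans_i(rng.standard_normal(ds.n), w).I for _ in range(50)]
        assert abs(np.mean(vals) - (-1.0 / (ds.n - 1))) < 0.01

    def test_clustered_residuals_give_positive_autocorrelation(self):
        coords = [(0, 0), (0.01, 0), (0, 0.01), (5, 5), (5.01, 5), (5, 5.01)]
        e = np.array([1.0, 1.0, 1.0, -1.0, -1.0, -1.0])
        w = knn_binary_weights(_point_panel(coords, e), 2)
        assert morans_i(e, w).I > 0

    def test_analytic_variance_agrees_with_permutation(self, rng):
        ds, _ = simulate(SimConfig(n_locations=10, n_times=10, seed=6))
        w = knn_binary_weights(ds, 6)
        e = rng.standard_normal(ds.n)
        ana = morans_i(e, w, method="analytic")
        per = morans_i(e, w, method="permutation", n_perm=3999, seed=5)
        assert ana.variance == pytest.approx(per.variance, rel=0.15)

    def test_constant_residuals_rejected(self, small_varying_panel):
        ds, _ = small_varying_panel
        w = knn_binary_weights(ds, 5)
        with pytest.raises(DiagnosticsError):
            morans_i(np.ones(ds.n), w)


class TestMoranCurve:
    def test_row_per_grid_point(self, small_varying_panel):
        ds, _ = small_varying_panel
        e = np.sin(np.arange(ds.n))
        curve = moran_curve(e, ds, [5, 10, 20], method="analytic")
        assert list(curve["k"]) == [5, 10, 20]

    def test_magnitude_shrinks_with_wide_neighborhoods(self):
        hits = 0
        for seed in range(10):
            ds, _ = simulate(SimConfig(n_locations=20, n_times=10, seed=seed))
            rng = np.random.default_rng(seed)
            e = rng.standard_normal(ds.n)
            curve = moran_curve(e, ds, [5, ds.n - 1], method="analytic")
            hits += int(abs(curve["I"].iloc[-1]) <= abs(curve["I"].iloc[0]))
        assert hits >= 8

    def test_non_increasing_grid_rejected(self, small_varying_panel):
        ds, _ = small_varying_panel
        with pytest.raises(DiagnosticsError):
            moran_curve(np.arange(ds.n, dtype=float), ds, [10, 10])


class TestCorrMatrix:
    def test_symmetric_unit_diagonal(self, default_panel):
        ds, _ = default_panel
        c = corr_matrix(ds)
        assert np.allclose(np.diag(c), 1.0)
        assert np.allclose(c, c.T, atol=1e-12)

    def test_default_draw_sign_pattern(self, default_panel):
        ds, _ = default_panel
        c = corr_matrix(ds)
        assert c.loc["PM25", "PM10"] > 0.5
        assert c.loc["PM25", "O3"] < 0

    def test_duplicated_column_perfectly_correlated(self, default_panel):
        ds, _ = default_panel
        records = ds.records.copy()
        records["NO2"] = records["SO2"]
        dup = PanelDataset(locations=list(ds.locations), records=records)
        assert corr_matrix(dup).loc["SO2", "NO2"] == pytest.approx(1.0)

    def test_zero_variance_column_named(self, default_panel):
        ds, _ = default_panel
        records = ds.records.copy()
        records["CO"] = 1.0
        flat = PanelDataset(locations=list(ds.locations), records=records)
        with pytest.raises(DiagnosticsError, match="CO"):
            corr_matrix(flat)


class TestCompareModels:
    def test_single_ols_row_with_zero_reduction(self, small_varying_panel):
        ds, _ = small_varying_panel
        table = compare_models([fit_ols(ds)], ds).table
        assert len(table) == 1
        assert table["rmse_reduction_pct"].iloc[0] == pytest.approx(0.0)
        assert table["z_mean"].iloc[0] == pytest.approx(0.0, abs=1e-10)

    def test_uniform_weight_local_fit_matches_ols_row(self, small_varying_panel):
        ds, _ = small_varying_panel
        ols = fit_ols(ds)
        uni = fit_stwr(ds, KernelConfig(mode="temporal", kernel="uniform", k=ds.n))
        table = compare_models([ols, uni], ds).table
        a, b = table.iloc[0], table.iloc[1]
        for col in ("aicc", "r2a", "rmse", "mae", "z_mean", "z_std"):
            assert a[col] == pytest.approx(b[col], abs=1e-6)

    def test_mixed_data_lmm_explains_more_than_ols(self):
        wins = 0
        for seed in range(10):
            ds, _ = simulate(SimConfig(n_locations=8, n_times=60, seed=seed))
            table = compare_models([fit_ols(ds), fit_lmm(ds)], ds).table
            wins += int(table["r2a"].iloc[1] >= table["r2a"].iloc[0])
        assert wins >= 9

    def test_foreign_fit_rejected(self, small_varying_panel, default_panel):
        ds, _ = small_varying_panel
        other, _ = default_panel
        fit = fit_ols(other)
        with pytest.raises(DiagnosticsError):
            compare_models([fit], ds)
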