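"""Boosted-tree calibration, influence, response curves, and evaluation stats."""

import numpy as np
import pandas as pd
import pytest

from ridge2reef.brt import (
    BRTConfig,
    fit_brt,
    inverse_transform,
    morans_i,
    obs_vs_pred,
    partial_dependence,
    predict_map,
    sample_at_points,
    transform_response,
)
from ridge2reef.grid import RasterGrid

FAST = BRTConfig(grid=((0.1, 2, 0.75),), max_trees=120)


class TestTransforms:
    def test_fourth_root_of_16_is_2(self):
        assert transform_response(np.array([16.0]), "fourth_root")[0] == 2.0

    def test_zero_round_trip(self):
        assert transform_response(np.array([0.0]), "sqrt")[0] == 0.0
        assert inverse_transform(np.array([0.0]), "sqrt")[0] == 0.0

    def test_sqrt_round_trip(self):
        t = transform_response(np.array([49.0]), "sqrt")
        assert inverse_transform(t, "sqrt")[0] == pytest.approx(49.0)

    def test_negative_rejected_and_clip_applied(self):
        with pytest.raises(ValueError):
            transform_response(np.array([-1.0]), "sqrt")
        assert inverse_transform(np.array([20.0]), "sqrt", upper=100.0)[0] == 100.0


def _xy(n=200, seed=0, p=5):
    rng = np.random.default_rng(seed)
    X = pd.DataFrame(rng.normal(size=(n, p)), columns=[f"d{i}" for i in range(p)])
    return rng, X


class TestFitBRT:
    def test_perfect_signal_explains_nearly_all_deviance(self):
        _, X = _xy(300, 1)
        y = 3.0 * X["d0"].to_numpy()
        m = fit_brt(X, y, config=FAST)
        assert m.pde > 0.99

    def test_pure_noise_cv_pde_near_zero(self):
        vals = []
        for seed in range(12):
            rng, X = _xy(120, seed)
            y = rng.normal(size=120)
            m = fit_brt(X, y, config=BRTConfig(grid=((0.1, 2, 0.75),),
                                               max_trees=60, seed=seed))
            vals.append(m.cv_pde)
        assert abs(np.mean(vals)) < 0.1

    def test_same_seed_same_model_and_metrics(self):
        rng, X = _xy(150, 4)
        y = X["d1"].to_numpy() ** 2 + rng.normal(0, 0.1, 150)
        m1 = fit_brt(X, y, config=FAST)
        m2 = fit_brt(X, y, config=FAST)
        assert (m1.n_trees, m1.pde, m1.cv_pde) == (m2.n_trees, m2.pde, m2.cv_pde)
        assert m1.relative_influence == m2.relative_influence

    def test_constant_response_rejected(self):
        _, X = _xy(100, 0)
        with pytest.raises(ValueError, match="SST"):
            fit_brt(X, np.ones(100), config=FAST)

    def test_too_few_rows_rejected(self):
        _, X = _xy(20, 0)
        with pytest.raises(ValueError, match="30"):
            fit_brt(X, np.arange(20.0), config=FAST)


class TestRelativeInfluence:
    def test_sums_to_100_and_informative_driver_dominates(self):
        for seed in range(5):
            rng, X = _xy(300, seed, p=6)
            y = 2.0 * X["d3"].to_numpy() + rng.normal(0, 0.2, 300)
            m = fit_brt(X, y, config=FAST)
            infl = m.relative_influence
            assert sum(infl.values()) == pytest.approx(100.0, abs=1e-6)
            assert max(infl, key=infl.get) == "d3"

    def test_never_split_driver_scores_zero(self):
        rng, X = _xy(200, 2, p=4)
        X["constant"] = 1.0  # unsplittable
        y = X["d0"].to_numpy() + rng.normal(0, 0.05, 200)
        m = fit_brt(X, y, config=FAST)
        assert m.relative_influence["constant"] == 0.0


class TestPartialDependence:
    def test_linear_truth_recovered_with_unit_slope_scaling(self):
        _, X = _xy(400, 3, p=3)
        y = 2.0 * X["d0"].to_numpy()
        m = fit_brt(X, y, config=FAST)
        grid = np.linspace(-1.5, 1.5, 7)
        curve = partial_dependence(m, "d0", grid, X)
        slope = np.polyfit(grid, curve, 1)[0]
        assert slope == pytest.approx(2.0, rel=0.15)

    def test_noise_driver_curve_is_flat(self):
        rng, X = _xy(300, 6, p=3)
        y = 2.0 * X["d0"].to_numpy() + rng.normal(0, 0.1, 300)
        m = fit_brt(X, y, config=FAST)
        curve = partial_dependence(m, "d2", np.linspace(-1, 1, 5), X)
        assert np.ptp(curve) < 0.3 * np.ptp(y)

    def test_single_value_equals_brute_force_row_mean(self):
        _, X = _xy(100, 8, p=3)
        y = X["d0"].to_numpy() + X["d1"].to_numpy()
        m = fit_brt(X, y, config=FAST)
        v = 0.37
        Xm = X.copy()
        Xm["d1"] = v
        brute = m.estimator.predict(Xm.to_numpy()).mean()
        assert partial_dependence(m, "d1", np.array([v]), X)[0] == pytest.approx(brute)

    def test_unknown_driver_rejected(self):
        _, X = _xy(100, 0, p=2)
        m = fit_brt(X, X["d0"].to_numpy() + 0.01 * X["d1"].to_numpy(), config=FAST)
        with pytest.raises(KeyError):
            partial_dependence(m, "nope", np.array([0.0]), X)


class TestPredictMap:
    def _stack(self, v0, v1, cs=60.0):
        return {"d0": RasterGrid(v0, cs), "d1": RasterGrid(v1, cs)}

    def test_constant_drivers_give_constant_map(self):
        rng, X = _xy(100, 5, p=2)
        y = transform_response(np.abs(X["d0"].to_numpy()) * 10, "sqrt")
        m = fit_brt(X, y, transform="sqrt", config=FAST, response_upper=100.0)
        stack = self._stack(np.full((4, 4), 0.5), np.full((4, 4), -0.2))
        out = predict_map(m, stack)
        assert np.ptp(out.values) == 0.0

    def test_cover_predictions_clipped_to_100(self):
        _, X = _xy(100, 9, p=2)
        y = np.full(100, 30.0)  # transformed scale values far above sqrt(100)
        y[::2] = 29.0
        m = fit_brt(X, y, transform="sqrt", config=FAST, response_upper=100.0)
        out = predict_map(m, self._stack(np.zeros((3, 3)), np.zeros((3, 3))))
        assert np.nanmax(out.values) <= 100.0

    def test_nodata_driver_propagates(self):
        _, X = _xy(100, 1, p=2)
        m = fit_brt(X, X["d0"].to_numpy() + 0.1 * X["d1"].to_numpy(), config=FAST)
        v0 = np.zeros((3, 3))
        v0[1, 1] = np.nan
        out = predict_map(m, self._stack(v0, np.zeros((3, 3))))
        assert np.isnan(out.values[1, 1]) and np.isfinite(out.values[0, 0])

    def test_missing_layer_rejected(self):
        _, X = _xy(100, 1, p=2)
        m = fit_brt(X, X["d0"].to_numpy() + 0.1 * X["d1"].to_numpy(), config=FAST)
        with pytest.raises(KeyError, match="d1"):
            predict_map(m, {"d0": RasterGrid(np.zeros((3, 3)), 60.0)})

    def test_map_sampled_back_at_training_points_matches_fit(self, wet_stack):
        from ridge2reef.grid import bilinear_sample
        from ridge2reef.synth import generate_surveys
        df, _ = generate_surveys(wet_stack, n=80, seed=9, noise_fraction=0.25)
        X = sample_at_points(wet_stack, df["x"].to_numpy(), df["y"].to_numpy())
        y = transform_response(df["coral"].to_numpy(), "sqrt")
        m = fit_brt(X, y, transform="sqrt", config=FAST, response_upper=100.0)
        mapped = predict_map(m, wet_stack)
        at_pts = bilinear_sample(mapped, df["x"].to_numpy(), df["y"].to_numpy())
        fitted = m.predict(X)
        ok = np.isfinite(at_pts)
        # bilinear smoothing tolerance: strong agreement, not identity
        assert np.corrcoef(at_pts[ok], fitted[ok])[0, 1] > 0.95


class TestMoransI:
    def _coords(self, n, seed=0):
        rng = np.random.default_rng(seed)
        return rng.uniform(0, 100, size=(n, 2))

    def test_iid_values_match_null_expectation(self):
        rng = np.random.default_rng(3)
        coords = self._coords(80, 1)
        i_obs, p = morans_i(rng.normal(size=80), coords, band=25.0, seed=0)
        assert abs(i_obs - (-1 / 79)) < 0.1
        assert p > 0.05

    def test_smooth_gradient_detected_as_positive_autocorrelation(self):
        coords = self._coords(80, 2)
        values = coords[:, 0] + 0.5 * coords[:, 1]
        i_obs, p = morans_i(values, coords, band=25.0, seed=0)
        assert i_obs > 0.3 and p < 0.01

    def test_checkerboard_on_unit_lattice_is_negative(self):
        xs, ys = np.meshgrid(np.arange(6), np.arange(6))
        coords = np.column_stack([xs.ravel(), ys.ravel()]).astype(float)
        values = ((xs + ys) % 2).ravel().astype(float)
        i_obs, p = morans_i(values, coords, band=1.0, seed=0)  # rook neighbors
        assert i_obs < -0.9 and p < 0.01

    def test_constant_values_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            morans_i(np.ones(20), self._coords(20), band=30.0)


class TestObsVsPred:
    def test_identity_gives_r2_one(self):
        v = np.arange(10.0)
        r2, slope, p = obs_vs_pred(v, v)
        assert r2 == pytest.approx(1.0)
        assert slope == pytest.approx(1.0)

    def test_uncorrelated_pairs_near_zero(self):
        rng = np.random.default_rng(11)
        r2, _, _ = obs_vs_pred(rng.normal(size=100), rng.normal(size=100))
        assert r2 < 0.1

    def test_matches_hand_computed_ols_on_five_points(self):
        pred = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        obs = np.array([2.0, 2.5, 4.0, 4.5, 6.5])
        # hand OLS: slope = Sxy/Sxx, r2 = Sxy^2/(Sxx Syy)
        sxy = np.sum((pred - 3.0) * (obs - obs.mean()))
        sxx = np.sum((pred - 3.0) ** 2)
        syy = np.sum((obs - obs.mean()) ** 2)
        r2, slope, _ = obs_vs_pred(obs, pred)
        assert slope == pytest.approx(sxy / sxx)
        assert r2 == pytest.approx(sxy**2 / (sxx * syy))

    def test_zero_variance_prediction_rejected(self):
        with pytest.raises(ValueError, match="variance"):
            obs_vs_pred(np.arange(5.0), np.ones(5))


class TestSampleAtPoints:
    def test_every_layer_sampled(self, wet_stack):
        ref = wet_stack["depth"]
        x = np.array([ref.origin[0] + 500.0])
        y = np.array([ref.origin[1] + 500.0])
        df = sample_at_points(wet_stack, x, y)
        assert set(df.columns) == set(wet_stack.keys())
        assert df.notna().all().all()
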