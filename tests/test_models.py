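"""Linear and random-forest models: fitting, m_try tuning, importances."""

import numpy as np
import pytest

from somvnir.models import (
    STRATEGIES,
    build_feature_sets,
    fit_linear,
    fit_rf,
    normalize_importance,
    run_all_strategies,
    tune_mtry,
)


class TestFitLinear:
    def test_noiseless_recovery(self):
        x = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        slope, intercept, pred = fit_linear(x, 2 * x + 1)
        assert slope == pytest.approx(2.0)
        assert intercept == pytest.approx(1.0)
        np.testing.assert_allclose(pred, 2 * x + 1)

    def test_flat_response(self):
        slope, intercept, _ = fit_linear(np.array([1.0, 2, 3, 4]), np.full(4, 5.0))
        assert slope == pytest.approx(0.0)
        assert intercept == pytest.approx(5.0)

    def test_hand_ols_three_points(self):
        slope, intercept, _ = fit_linear(np.array([1.0, 2, 3]), np.array([1.0, 3, 2]))
        assert slope == pytest.approx(0.5)
        assert intercept == pytest.approx(1.0)

    def test_residuals_orthogonal_to_x(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=50)
        y = 1.5 * x + rng.normal(size=50)
        slope, intercept, pred = fit_linear(x, y)
        assert abs((y - pred) @ x) < 1e-9

    def test_constant_x_rejected(self):
        with pytest.raises(ValueError):
            fit_linear(np.full(5, 2.0), np.arange(5.0))


class TestRandomForest:
    def test_constant_target_constant_predictions(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(30, 3))
        rf = fit_rf(X, np.full(30, 7.0), m_try=2, n_trees=50, seed=0)
        np.testing.assert_allclose(rf.predict(X), 7.0)

    def test_seeded_determinism(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(40, 4))
        y = X[:, 0] + rng.normal(0, 0.1, 40)
        p1 = fit_rf(X, y, m_try=2, n_trees=100, seed=5).predict(X)
        p2 = fit_rf(X, y, m_try=2, n_trees=100, seed=5).predict(X)
        np.testing.assert_array_equal(p1, p2)

    def test_predictions_within_training_range(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(60, 3))
        y = rng.uniform(1, 40, 60)
        rf = fit_rf(X, y, m_try=1, n_trees=100, seed=0)
        pred = rf.predict(rng.normal(size=(20, 3)) * 3)
        assert pred.min() >= y.min() and pred.max() <= y.max()

    def test_strong_signal_validation_r2(self):
        rng = np.random.default_rng(4)
        X = rng.normal(size=(300, 3))
        y = 3 * X[:, 0] + rng.normal(0, 0.1, 300)
        rf = fit_rf(X[:200], y[:200], m_try=3, n_trees=200, seed=0)
        pred = rf.predict(X[200:])
        r = np.corrcoef(pred, y[200:])[0, 1]
        assert r * r > 0.9

    def test_mtry_out_of_range_rejected(self):
        rng = np.random.default_rng(5)
        X = rng.normal(size=(20, 3))
        with pytest.raises(ValueError):
            fit_rf(X, X[:, 0], m_try=4, n_trees=10)


class TestTuneMtry:
    def test_single_element_range(self):
        rng = np.random.default_rng(6)
        X = rng.normal(size=(30, 4))
        assert tune_mtry(X, X[:, 0], [3], n_trees=20) == 3

    def test_seeded_repeatability(self):
        rng = np.random.default_rng(7)
        X = rng.normal(size=(60, 5))
        y = X[:, 0] + 0.3 * rng.normal(size=60)
        a = tune_mtry(X, y, range(1, 6), n_trees=50, seed=3)
        b = tune_mtry(X, y, range(1, 6), n_trees=50, seed=3)
        assert a == b

    def test_selected_mtry_minimizes_oob_rmse(self):
        """Exhaustive refit confirms the winner's OOB RMSE is minimal."""
        from somvnir.models import _oob_rmse

        rng = np.random.default_rng(8)
        X = np.column_stack([rng.normal(size=200)] + [rng.normal(size=200) for _ in range(4)])
        y = X[:, 0].copy()
        chosen = tune_mtry(X, y, range(1, 6), n_trees=100, seed=1)
        rmses = {}
        for m in range(1, 6):
            rf = fit_rf(X, y, m_try=m, n_trees=100, seed=1, oob=True)
            rmses[m] = _oob_rmse(rf, y)
        assert rmses[chosen] == min(rmses.values())

    def test_empty_range_rejected(self):
        with pytest.raises(ValueError):
            tune_mtry(np.ones((20, 2)), np.arange(20.0), [])


class TestImportance:
    def test_uniform(self):
        np.testing.assert_allclose(normalize_importance([1, 1, 1, 1]), [25, 25, 25, 25])

    def test_proportional(self):
        np.testing.assert_allclose(normalize_importance([3, 1]), [75, 25])

    def test_single_feature(self):
        np.testing.assert_allclose(normalize_importance([0.42]), [100.0])

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            normalize_importance([0.0, 0.0])


@pytest.fixture(scope="module")
def feature_sets():
    rng = np.random.default_rng(9)
    n_cal, n_val = 60, 30
    pcs_cal, pcs_val = rng.normal(size=(n_cal, 5)), rng.normal(size=(n_val, 5))
    two_cal = {f"F{i}": rng.normal(size=n_cal) for i in range(5)}
    two_val = {f"F{i}": rng.normal(size=n_val) for i in range(5)}
    three_cal = {f"T{i}": rng.normal(size=n_cal) for i in range(5)}
    three_val = {f"T{i}": rng.normal(size=n_val) for i in range(5)}
    return build_feature_sets(pcs_cal, pcs_val, two_cal, two_val, three_cal, three_val)


class TestStrategies:
    def test_six_strategies_with_expected_widths(self, feature_sets):
        assert set(feature_sets) == set(STRATEGIES)
        for name, fs in feature_sets.items():
            assert fs.n_features == (5 if "+" not in name else 10)

    def test_run_all_produces_all_results(self, feature_sets):
        rng = np.random.default_rng(10)
        y_cal = rng.uniform(1, 40, 60)
        y_val = rng.uniform(1, 40, 30)
        results = run_all_strategies(feature_sets, y_cal, y_val, n_trees=30, seed=0)
        assert [r.strategy for r in results] == list(STRATEGIES)
        for r in results:
            assert sum(r.importance.values()) == pytest.approx(100.0, abs=1e-6)
            assert r.pred_cal.shape == (60,) and r.pred_val.shape == (30,)
            assert 1 <= r.hyperparameters["m_try"] <= 10

    def test_duplicate_columns_dropped_with_warning(self):
        rng = np.random.default_rng(11)
        col = rng.normal(size=20)
        X = np.column_stack([col, col, rng.normal(size=20)])
        from somvnir.models import _drop_duplicate_columns

        with pytest.warns(UserWarning, match="duplicate"):
            Xd, names, keep = _drop_duplicate_columns(X, ["a", "b", "c"])
        assert names == ["a", "c"]
        np.testing.assert_array_equal(Xd, X[:, [0, 2]])
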