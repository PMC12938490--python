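"""Ridge / logistic ridge: closed-form oracle, limits, invariances, metrics."""

import numpy as np
import pytest

from embaudit.datasets import BehaviorVector
from embaudit.regression import (
    EmbeddingLogisticRidge,
    EmbeddingRidge,
    fit,
    load_model,
    predict,
    save_model,
    score,
)
from embaudit.errors import DegenerateDataError, UsageError


def closed_form_ridge(X, y, lam):
    """Independent oracle: standardize X, center y, solve (Z'Z + lam I)^-1 Z'y."""
    center = X.mean(axis=0)
    scale = X.std(axis=0)
    scale = np.where(scale > 0, scale, 1.0)
    Z = (X - center) / scale
    yc = y - y.mean()
    coef = np.linalg.solve(Z.T @ Z + lam * np.eye(X.shape[1]), Z.T @ yc)
    return coef, y.mean()


class TestRidgeOracle:
    def test_matches_closed_form_on_random_instances(self, rng):
        """Fixed-lambda fits equal the naive closed-form solution (50 instances)."""
        for _ in range(50):
            X = rng.normal(size=(20, 5))
            y = rng.normal(size=20)
            lam = float(rng.uniform(0.1, 10.0))
            model = EmbeddingRidge(lambda_grid=[lam]).fit(X, y)
            coef, intercept = closed_form_ridge(X, y, lam)
            assert np.allclose(model.coef_, coef, atol=1e-8)
            assert model.intercept_ == pytest.approx(intercept, abs=1e-8)

    def test_zero_penalty_equals_least_squares(self, rng):
        X = rng.normal(size=(30, 4))
        beta = np.array([1.0, -2.0, 0.5, 3.0])
        y = X @ beta + rng.normal(scale=0.1, size=30)
        model = EmbeddingRidge(lambda_grid=[0.0]).fit(X, y)
        coef, intercept = closed_form_ridge(X, y, 0.0)
        assert np.allclose(model.coef_, coef, atol=1e-8)
        pred_ols = intercept + ((X - X.mean(0)) / np.where(X.std(0) > 0, X.std(0), 1)) @ coef
        assert np.allclose(model.predict(X), pred_ols, atol=1e-8)

    def test_infinite_penalty_predicts_mean(self, rng):
        X = rng.normal(size=(25, 6))
        y = rng.normal(loc=7.0, size=25)
        model = EmbeddingRidge(lambda_grid=[1e12]).fit(X, y)
        assert np.allclose(model.predict(X), y.mean(), atol=1e-6)

    def test_shrinkage_monotonicity(self, rng):
        X = rng.normal(size=(40, 8))
        y = rng.normal(size=40)
        lams = [0.01, 0.1, 1.0, 10.0, 100.0]
        norms = [np.linalg.norm(EmbeddingRidge(lambda_grid=[l]).fit(X, y).coef_)
                 for l in lams]
        assert all(a >= b for a, b in zip(norms, norms[1:]))

    def test_prediction_invariant_under_column_rescaling(self, rng):
        X = rng.normal(size=(30, 5))
        y = rng.normal(size=30)
        scales = np.array([0.01, 1.0, 5.0, 100.0, 0.5])
        a = EmbeddingRidge(lambda_grid=[2.0]).fit(X, y).predict(X)
        b = EmbeddingRidge(lambda_grid=[2.0]).fit(X * scales, y).predict(X * scales)
        assert np.allclose(a, b, atol=1e-8)


class TestCrossValidation:
    def test_selected_lambda_recorded_in_trace(self, rng):
        X = rng.normal(size=(40, 6))
        y = X[:, 0] * 2 + rng.normal(scale=0.5, size=40)
        model = EmbeddingRidge(lambda_grid=[0.1, 1.0, 10.0], k_folds=5,
                               random_state=0).fit(X, y)
        assert model.lambda_ in model.cv_trace_
        assert len(model.cv_trace_) == 3

    def test_min_rule_picks_loss_minimizer(self, rng):
        X = rng.normal(size=(40, 6))
        y = X[:, 0] * 2 + rng.normal(scale=0.5, size=40)
        model = EmbeddingRidge(lambda_grid=[0.1, 1.0, 10.0, 100.0], k_folds=5,
                               random_state=0, selection_rule="min").fit(X, y)
        assert model.lambda_ == min(model.cv_trace_, key=model.cv_trace_.get)

    def test_one_se_rule_never_less_regularized_than_min(self, rng):
        X = rng.normal(size=(60, 10))
        y = X[:, 0] + rng.normal(scale=1.0, size=60)
        grid = [0.01, 0.1, 1.0, 10.0, 100.0]
        m_min = EmbeddingRidge(lambda_grid=grid, k_folds=5, random_state=1,
                               selection_rule="min").fit(X, y)
        m_1se = EmbeddingRidge(lambda_grid=grid, k_folds=5, random_state=1,
                               selection_rule="1se").fit(X, y)
        assert m_1se.lambda_ >= m_min.lambda_

    def test_deterministic_given_seed(self, rng):
        X = rng.normal(size=(50, 6))
        y = rng.normal(size=50)
        a = EmbeddingRidge(k_folds=5, random_state=3).fit(X, y)
        b = EmbeddingRidge(k_folds=5, random_state=3).fit(X, y)
        assert a.lambda_ == b.lambda_
        assert np.array_equal(a.coef_, b.coef_)

    def test_too_few_rows_for_folds_rejected(self, rng):
        X = rng.normal(size=(5, 3))
        with pytest.raises(UsageError):
            EmbeddingRidge(lambda_grid=[0.1, 1.0], k_folds=10).fit(X, np.ones(5) + X[:, 0])


class TestLogisticRidge:
    def test_probabilities_in_open_interval_and_normalized(self, rng):
        X = rng.normal(size=(60, 5))
        y = (X[:, 0] + rng.normal(scale=0.5, size=60) > 0).astype(float)
        model = EmbeddingLogisticRidge(lambda_grid=[1.0]).fit(X, y)
        proba = model.predict_proba(X)
        assert np.all(proba > 0) and np.all(proba < 1)
        assert np.allclose(proba.sum(axis=1), 1.0)

    def test_separable_data_learned(self, rng):
        X = rng.normal(size=(80, 4))
        y = (X[:, 1] > 0).astype(float)
        model = EmbeddingLogisticRidge(lambda_grid=[0.1]).fit(X, y)
        assert (model.predict(X) == y).mean() > 0.9

    def test_constant_outcome_rejected(self, rng):
        X = rng.normal(size=(20, 3))
        with pytest.raises(DegenerateDataError):
            EmbeddingLogisticRidge(lambda_grid=[1.0]).fit(X, np.ones(20))

    def test_dim_mismatch_rejected(self, rng):
        X = rng.normal(size=(30, 4))
        y = (X[:, 0] > 0).astype(float)
        model = EmbeddingLogisticRidge(lambda_grid=[1.0]).fit(X, y)
        with pytest.raises(UsageError):
            model.predict_proba(rng.normal(size=(5, 3)))


class TestFunctionalSurface:
    def test_fit_dispatches_on_mode(self, rng):
        X = rng.normal(size=(30, 4))
        cont = BehaviorVector(rng.normal(size=30))
        binary = BehaviorVector((X[:, 0] > 0).astype(float), mode="binary")
        assert isinstance(fit(X, cont, lambda_grid=[1.0]), EmbeddingRidge)
        assert isinstance(fit(X, binary, lambda_grid=[1.0]), EmbeddingLogisticRidge)

    def test_predict_returns_probabilities_for_binary(self, rng):
        X = rng.normal(size=(30, 4))
        y = BehaviorVector((X[:, 0] > 0).astype(float), mode="binary")
        model = fit(X, y, lambda_grid=[1.0])
        p = predict(model, X)
        assert np.all((p > 0) & (p < 1))

    def test_save_load_round_trip(self, tmp_path, rng):
        X = rng.normal(size=(30, 4))
        y = rng.normal(size=30)
        model = EmbeddingRidge(lambda_grid=[0.5]).fit(X, y)
        path = tmp_path / "model.json"
        save_model(model, path, encoder_id="synthetic-test")
        loaded = load_model(path)
        assert np.allclose(loaded.predict(X), model.predict(X), atol=1e-12)
        assert loaded.lambda_ == model.lambda_


class TestScore:
    def test_perfect_predictions(self):
        y = np.array([1.0, 2.0, 3.0])
        s = score(y, y, "continuous")
        assert s.r == pytest.approx(1.0)
        assert s.mean_signed_error == pytest.approx(0.0)

    def test_anticorrelated_predictions(self):
        y = np.array([1.0, 2.0, 3.0])
        s = score(-y, y, "continuous")
        assert s.r == pytest.approx(-1.0)

    def test_zero_variance_reported_as_undefined(self):
        y = np.array([1.0, 2.0, 3.0])
        s = score(np.full(3, 5.0), y, "continuous")
        assert np.isnan(s.r)
        assert s.r_defined is False

    def test_binary_tie_rule_predicts_positive(self):
        y = np.array([0.0, 1.0, 0.0, 1.0])
        s = score(np.full(4, 0.5), y, "binary")
        assert s.accuracy == pytest.approx(0.5)

    def test_binary_perfect(self):
        y = np.array([0.0, 1.0, 1.0, 0.0])
        s = score(np.array([0.01, 0.99, 0.98, 0.02]), y, "binary")
        assert s.accuracy == 1.0
        assert s.deviance_r2 > 0.9
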