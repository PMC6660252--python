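"""LASSO solver contracts, cross-validated λ search, final GLM refit."""

import numpy as np
import pytest

from seegspeed import decoder
from seegspeed.behavior import SpeedNormalization
from seegspeed.decoder import (DecoderError, cross_validate_lambda,
                               fit_decoding_model, fit_final_glm, kkt_violation,
                               lambda_max, lasso_fit, make_lambda_grid,
                               predict_speed, select_features, split_train_test)


def _problem(rng, n=60, p=30, k=3, noise=0.5):
    X = rng.standard_normal((n, p))
    beta = np.zeros(p)
    beta[:k] = rng.uniform(0.5, 2.0, k)
    y = X @ beta + noise * rng.standard_normal(n)
    return X, y


class TestSplit:
    def test_sizes_80_20(self, rng):
        train, test = split_train_test(100, rng=rng)
        assert len(train) == 80 and len(test) == 20

    def test_partition(self, rng):
        train, test = split_train_test(73, rng=rng)
        assert len(train) == int(np.ceil(0.8 * 73))
        assert set(train) | set(test) == set(range(73))
        assert set(train) & set(test) == set()

    def test_deterministic_under_seed(self):
        a = split_train_test(50, rng=np.random.default_rng(3))
        b = split_train_test(50, rng=np.random.default_rng(3))
        assert np.array_equal(a[0], b[0]) and np.array_equal(a[1], b[1])

    def test_too_few_trials(self):
        with pytest.raises(DecoderError):
            split_train_test(5)


class TestLassoFit:
    def test_all_zero_at_lambda_max(self, rng):
        X, y = _problem(rng)
        lmax = lambda_max(X, y)
        intercept, coef = lasso_fit(X, y, lmax * 1.0001)
        assert np.all(coef == 0)
        assert intercept == pytest.approx(y.mean())

    def test_matches_ols_at_lambda_zero(self, rng):
        X, y = _problem(rng, n=80, p=10)
        intercept, coef = lasso_fit(X, y, 0.0)
        A = np.column_stack([np.ones(len(y)), X])
        ref, *_ = np.linalg.lstsq(A, y, rcond=None)
        assert intercept == pytest.approx(ref[0], abs=1e-8)
        assert np.allclose(coef, ref[1:], atol=1e-8)

    @staticmethod
    def _orthogonal_oracle(X, y, lam):
        """Closed form for orthogonal designs under the implementation's
        conventions (internal sample-sd standardization, objective
        (1/2N)·RSS + λ‖β‖₁): β̂_j = S(⟨xs_j, yc⟩/N, λ) / (⟨xs_j, xs_j⟩/N),
        mapped back to the original scale."""
        n = len(y)
        sd = X.std(axis=0, ddof=1)
        Xs = (X - X.mean(axis=0)) / sd
        yc = y - y.mean()
        c = Xs.T @ yc / n
        q = np.sum(Xs ** 2, axis=0) / n
        b = np.sign(c) * np.maximum(np.abs(c) - lam, 0.0) / q
        return b / sd

    def test_orthogonal_design_soft_threshold(self):
        # orthogonal ±1 columns; OLS coefficients (2.0, 0.5); λ = 1 shrinks
        # the strong one toward 1 and kills the weak one
        X = np.column_stack([np.tile([1.0, -1.0], 32),
                             np.repeat([1.0, -1.0], 32)])
        y = X @ np.array([2.0, 0.5])
        for lam in (1.0, 0.3):
            _, coef = lasso_fit(X, y, lam)
            assert np.allclose(coef, self._orthogonal_oracle(X, y, lam),
                               atol=1e-6)
        _, coef = lasso_fit(X, y, 1.0)
        assert np.allclose(coef, [1.0, 0.0], atol=0.05)
        assert coef[1] == 0.0

    def test_kkt_certificate_random_problems(self, rng):
        for i in range(5):
            X, y = _problem(rng, n=40 + 5 * i, p=25, k=4)
            grid = make_lambda_grid(X, y, n=7)
            for lam in grid[[0, 2, 4, 6]]:
                intercept, coef = lasso_fit(X, y, lam)
                assert kkt_violation(X, y, intercept, coef, lam) < 1e-8

    def test_zero_variance_column_dropped(self, rng):
        X, y = _problem(rng, n=40, p=5)
        X[:, 2] = 3.14
        intercept, coef = lasso_fit(X, y, 0.01)
        assert coef[2] == 0.0
        assert np.isfinite(intercept)

    def test_non_finite_rejected(self):
        with pytest.raises(DecoderError):
            lasso_fit(np.array([[np.nan, 1.0]]), np.array([1.0]), 0.1)
        with pytest.raises(DecoderError):
            lasso_fit(np.ones((4, 2)), np.ones(4), -0.5)


class TestCrossValidation:
    def test_fold_sizes_differ_by_at_most_one(self, rng):
        X, y = _problem(rng, n=67, p=10)
        cv = cross_validate_lambda(X, y, k=10, rng=rng)
        sizes = np.bincount(cv.fold_assignments)
        assert sizes.max() - sizes.min() <= 1

    def test_lambda_hat_attains_minimum(self, rng):
        X, y = _problem(rng, n=60, p=20)
        cv = cross_validate_lambda(X, y, rng=rng)
        assert cv.lambda_hat in cv.lambda_grid
        assert (cv.mean_mse[cv.lambda_grid == cv.lambda_hat]
                == cv.mean_mse.min())

    def test_exact_predictor_selected(self, rng):
        # noiseless y = x1: feature 0 must be in the selected set at λ̂
        X = rng.standard_normal((50, 8))
        y = X[:, 0].copy()
        cv = cross_validate_lambda(X, y, rng=rng)
        sel = select_features(X, y, cv.lambda_hat)
        assert 0 in sel

    def test_reproducible_under_seed(self, rng):
        X, y = _problem(rng, n=55, p=15)
        a = cross_validate_lambda(X, y, rng=np.random.default_rng(9))
        b = cross_validate_lambda(X, y, rng=np.random.default_rng(9))
        assert a.lambda_hat == b.lambda_hat
        assert np.array_equal(a.mean_mse, b.mean_mse)

    def test_too_many_folds(self, rng):
        X, y = _problem(rng, n=8, p=3)
        with pytest.raises(DecoderError):
            cross_validate_lambda(X, y, k=10, rng=rng)

    def test_training_mse_nondecreasing_in_lambda(self, rng):
        # in-sample fit can only get worse as the penalty grows
        X, y = _problem(rng, n=50, p=12)
        grid = make_lambda_grid(X, y, n=20)
        mses = []
        for lam in grid[::-1]:  # increasing λ
            b0, coef = lasso_fit(X, y, lam)
            mses.append(np.mean((y - b0 - X @ coef) ** 2))
        assert np.all(np.diff(mses) >= -1e-10)


class TestSelection:
    def test_empty_selection_above_lambda_max(self, rng):
        X, y = _problem(rng)
        sel = select_features(X, y, lambda_max(X, y) * 1.01)
        assert sel.size == 0

    def test_deterministic(self, rng):
        X, y = _problem(rng)
        lam = lambda_max(X, y) * 0.1
        assert np.array_equal(select_features(X, y, lam),
                              select_features(X, y, lam))

    def test_duplicated_column_tie_policy(self, rng):
        # at most one of two identical columns enters, and the solution's
        # objective matches any split of weight across the duplicates
        X, y = _problem(rng, n=50, p=6, k=2)
        X[:, 5] = X[:, 0]
        lam = lambda_max(X, y) * 0.2
        b0, coef = lasso_fit(X, y, lam)
        assert (coef[0] != 0) + (coef[5] != 0) <= 1

        def objective(c):
            n = len(y)
            return (0.5 / n * np.sum((y - b0 - X @ c) ** 2)
                    + lam * np.sum(np.abs(c * X.std(axis=0, ddof=1))))

        split = coef.copy()
        total = coef[0] + coef[5]
        split[0], split[5] = 0.3 * total, 0.7 * total
        assert objective(coef) == pytest.approx(objective(split), rel=1e-6)


class TestFinalGlm:
    def test_intercept_only(self):
        b0, betas, kept = fit_final_glm(np.empty((10, 0)), np.arange(10.0))
        assert b0 == pytest.approx(4.5)
        assert betas.size == 0

    def test_noiseless_exact_fit(self, rng):
        X = rng.standard_normal((30, 1))
        y = 2.0 * X[:, 0]
        b0, betas, _ = fit_final_glm(X, y)
        assert b0 == pytest.approx(0.0, abs=1e-10)
        assert betas[0] == pytest.approx(2.0, abs=1e-10)

    def test_refit_at_least_as_large_as_shrunken(self, rng):
        X, y = _problem(rng, n=80, p=10, k=3, noise=0.3)
        lam = lambda_max(X, y) * 0.3
        _, lasso_coef = lasso_fit(X, y, lam)
        sel = np.flatnonzero(lasso_coef)
        _, refit, _ = fit_final_glm(X[:, sel], y)
        assert np.all(np.abs(refit) >= np.abs(lasso_coef[sel]) - 1e-6)

    def test_rank_deficiency_drops_column(self, rng):
        X = rng.standard_normal((20, 2))
        X = np.column_stack([X, X[:, 0] + X[:, 1]])
        y = X[:, 0] + rng.standard_normal(20) * 0.1
        b0, betas, kept = fit_final_glm(X, y)
        assert len(kept) == 2
        assert np.isfinite(betas).all()


class TestPredict:
    def _model(self, betas, b0=0.5):
        return decoder.DecodingModel(
            variant="combined",
            selected_indices=np.arange(len(betas)),
            selected_ids=[f"f{i}" for i in range(len(betas))],
            beta0=b0, betas=np.asarray(betas, float),
            lasso_beta0=b0, lasso_betas=np.asarray(betas, float) * 0.8,
            lambda_hat=0.1,
            speed_norm=SpeedNormalization(-0.7, 0.5))

    def test_all_zero_features_give_intercept(self):
        m = self._model([1.0, -2.0])
        assert np.allclose(predict_speed(m, np.zeros((4, 2))), 0.5)

    def test_linearity_in_each_feature(self, rng):
        m = self._model([1.5, -0.5])
        X = rng.standard_normal((6, 2))
        base = predict_speed(m, X)
        X2 = X.copy()
        X2[:, 1] += 2.0
        assert np.allclose(predict_speed(m, X2), base - 0.5 * 2.0)

    def test_column_mismatch_rejected(self):
        with pytest.raises(DecoderError):
            predict_speed(self._model([1.0]), np.zeros((3, 2)))

    def test_scale_invariance_of_pipeline_predictions(self, rng):
        # multiplying a raw feature column by a constant is absorbed by
        # standardization: selected set and predictions are unchanged
        X, y = _problem(rng, n=60, p=8, k=2)
        ids = [f"f{i}" for i in range(8)]
        norm = SpeedNormalization(-0.7, 0.5)
        lam = lambda_max(X, y) * 0.2
        m1 = fit_decoding_model(X, y, lam, ids, norm)
        Xs = X.copy()
        Xs[:, 0] *= 13.0
        m2 = fit_decoding_model(Xs, y, lam, ids, norm)
        assert m1.selected_ids == m2.selected_ids
        Xt = rng.standard_normal((5, 8))
        Xts = Xt.copy()
        Xts[:, 0] *= 13.0
        assert np.allclose(m1.predict(Xt), m2.predict(Xts), atol=1e-8)
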