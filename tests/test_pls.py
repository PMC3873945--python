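"""PLS core: oracle equivalence, prediction identities, PRESS/R^2, CV."""

import numpy as np
import pytest
from sklearn.cross_decomposition import PLSRegression

from ecogdecode import (
    ConvergenceError,
    CvCurve,
    InvalidArgumentError,
    cross_validate,
    fit_pls,
    fit_pls_upto,
    press,
    r_squared,
    select_n_latent,
)


def _instance(rng, n=60, p=8, m=3):
    return rng.standard_normal((n, p)), rng.standard_normal((n, m))


class TestFit:
    def test_matches_independent_pls_implementation(self):
        """Predictions agree with scikit-learn's NIPALS (power iteration,
        ~1e-6 weight precision) across sizes and factor counts."""
        rng = np.random.default_rng(0)
        for _ in range(5):
            X, Y = _instance(rng)
            for k in (1, 3, 6):
                ours = fit_pls(X, Y, k)
                theirs = PLSRegression(n_components=k, scale=False, tol=1e-12,
                                       max_iter=5000).fit(X, Y)
                assert np.allclose(ours.predict(X), theirs.predict(X), atol=1e-4)

    def test_full_factor_fit_equals_least_squares(self):
        rng = np.random.default_rng(1)
        X, Y = _instance(rng, n=50, p=5)
        model = fit_pls(X, Y, 5)
        beta, *_ = np.linalg.lstsq(np.column_stack([X, np.ones(50)]), Y, rcond=None)
        assert np.allclose(model.B, beta[:-1], rtol=1e-6, atol=1e-10)
        assert np.allclose(model.a, beta[-1], rtol=1e-6, atol=1e-10)

    def test_noiseless_target_recovered(self):
        rng = np.random.default_rng(2)
        X = rng.standard_normal((200, 6))
        B0 = rng.standard_normal((6, 3))
        Y = X @ B0 + 1.5
        model = fit_pls(X, Y, 6)
        per_axis, mean = r_squared(Y, model.predict(X))
        assert mean > 0.999

    def test_single_active_column_recovers_univariate_slope(self):
        rng = np.random.default_rng(3)
        x = rng.standard_normal(100)
        X = np.zeros((100, 4))
        X[:, 2] = x
        y = 2.0 * x + 0.3 + 0.01 * rng.standard_normal(100)
        model = fit_pls(X, y, 1)
        xc = x - x.mean()
        slope = (xc @ (y - y.mean())) / (xc @ xc)
        assert model.B[2, 0] == pytest.approx(slope, rel=1e-10)

    def test_scores_orthogonal(self):
        rng = np.random.default_rng(4)
        X, Y = _instance(rng, n=120, p=30)
        model = fit_pls(X, Y, 10)
        G = model.x_scores.T @ model.x_scores
        off = np.abs(G - np.diag(np.diag(G))).max()
        assert off < 1e-8 * np.abs(np.diag(G)).max()

    def test_infeasible_factor_count_rejected(self):
        rng = np.random.default_rng(5)
        X, Y = _instance(rng, n=20, p=4)
        with pytest.raises(InvalidArgumentError):
            fit_pls(X, Y, 5)

    def test_rank_deficient_exhaustion_raises(self):
        rng = np.random.default_rng(6)
        u = rng.standard_normal((80, 2))
        X = u @ rng.standard_normal((2, 10))  # rank 2
        Y = rng.standard_normal((80, 3))
        with pytest.raises(ConvergenceError):
            fit_pls(X, Y, 6)
        assert fit_pls_upto(X, Y, 6).n_latent == 2

    def test_zero_predictors_rejected(self):
        with pytest.raises(InvalidArgumentError):
            fit_pls(np.zeros((20, 3)), np.ones((20, 2)), 1)


class TestPredict:
    def test_mean_input_predicts_mean_output(self):
        rng = np.random.default_rng(7)
        X, Y = _instance(rng)
        model = fit_pls(X, Y, 3)
        assert np.allclose(model.predict(X.mean(axis=0)[None, :]), Y.mean(axis=0))

    def test_affine_in_inputs(self):
        rng = np.random.default_rng(8)
        X, Y = _instance(rng)
        model = fit_pls(X, Y, 3)
        X1, X2 = _instance(rng)[0], _instance(rng)[0]
        a = 0.3
        lhs = model.predict(a * X1 + (1 - a) * X2)
        rhs = a * model.predict(X1) + (1 - a) * model.predict(X2)
        assert np.allclose(lhs, rhs, atol=1e-10)

    def test_column_mismatch_rejected(self):
        rng = np.random.default_rng(9)
        X, Y = _instance(rng)
        model = fit_pls(X, Y, 2)
        with pytest.raises(InvalidArgumentError):
            model.predict(np.zeros((5, 3)))

    def test_zero_latent_model_predicts_training_mean(self):
        rng = np.random.default_rng(10)
        X, Y = _instance(rng)
        model = fit_pls_upto(X, Y, 0)
        assert model.n_latent == 0
        assert np.allclose(model.predict(X), Y.mean(axis=0))


class TestPressAndR2:
    def test_perfect_prediction(self):
        Y = np.arange(12.0).reshape(4, 3)
        assert press(Y, Y) == 0.0
        per_axis, mean = r_squared(Y, Y)
        assert np.allclose(per_axis, 1.0) and mean == 1.0

    def test_hand_computed_example(self):
        assert press(np.zeros((2, 3)), np.ones((2, 3))) == 6.0

    def test_mean_predictor_scores_zero(self):
        rng = np.random.default_rng(11)
        Y = rng.standard_normal((50, 3))
        per_axis, mean = r_squared(Y, np.broadcast_to(Y.mean(axis=0), Y.shape))
        assert np.allclose(per_axis, 0.0, atol=1e-12)

    def test_negated_prediction_on_centered_targets(self):
        rng = np.random.default_rng(12)
        Y = rng.standard_normal((200, 3))
        Y = Y - Y.mean(axis=0)
        per_axis, _ = r_squared(Y, -Y)
        assert np.allclose(per_axis, -3.0)

    def test_press_matches_direct_summation(self):
        rng = np.random.default_rng(13)
        Y, Yhat = rng.standard_normal((30, 3)), rng.standard_normal((30, 3))
        direct = sum(
            (Y[i, j] - Yhat[i, j]) ** 2 for i in range(30) for j in range(3)
        )
        assert press(Y, Yhat) == pytest.approx(direct, abs=1e-12)

    def test_r2_press_consistency(self):
        """Per axis, R^2 = 1 - PRESS_axis / SS_tot_axis exactly."""
        rng = np.random.default_rng(14)
        Y, Yhat = rng.standard_normal((40, 3)), rng.standard_normal((40, 3))
        per_axis, _ = r_squared(Y, Yhat)
        for j in range(3):
            sstot = np.sum((Y[:, j] - Y[:, j].mean()) ** 2)
            assert per_axis[j] == pytest.approx(1 - press(Y[:, [j]], Yhat[:, [j]]) / sstot)

    @pytest.mark.parametrize("fn", [press, r_squared])
    def test_shape_mismatch(self, fn):
        with pytest.raises(InvalidArgumentError):
            fn(np.zeros((3, 3)), np.zeros((4, 3)))

    def test_zero_variance_axis_rejected(self):
        Y = np.ones((10, 3))
        with pytest.raises(InvalidArgumentError):
            r_squared(Y, Y)


class TestCrossValidation:
    def test_fold_partition(self):
        rng = np.random.default_rng(15)
        X, Y = _instance(rng, n=1000, p=6)
        curve = cross_validate(X, Y, max_latent=3, k_folds=10)
        sizes = [stop - start for start, stop in curve.fold_bounds]
        assert sizes == [100] * 10
        covered = sorted(i for a, b in curve.fold_bounds for i in range(a, b))
        assert covered == list(range(1000))

    def test_noiseless_press_decreases_then_flattens(self):
        rng = np.random.default_rng(16)
        X = rng.standard_normal((300, 5))
        Y = X @ rng.standard_normal((5, 3))
        curve = cross_validate(X, Y, max_latent=8, k_folds=5)
        assert np.all(np.diff(curve.press[:5]) <= 1e-6 * curve.press[0])
        assert np.allclose(curve.press[4:], curve.press[4], atol=1e-12)

    def test_deterministic(self):
        rng = np.random.default_rng(17)
        X, Y = _instance(rng, n=200, p=6)
        a = cross_validate(X, Y, max_latent=4, k_folds=5)
        b = cross_validate(X, Y, max_latent=4, k_folds=5)
        assert np.array_equal(a.press, b.press)
        assert np.array_equal(a.r2, b.r2)
        assert a.fold_bounds == b.fold_bounds

    def test_too_few_rows(self):
        with pytest.raises(InvalidArgumentError):
            cross_validate(np.zeros((50, 3)), np.zeros((50, 2)), 2, k_folds=1)


class TestSelectNLatent:
    def _curve(self, press_values, baseline=np.inf):
        press_values = np.asarray(press_values, dtype=float)
        return CvCurve(
            n_components=np.arange(1, len(press_values) + 1),
            press=press_values,
            r2=np.zeros_like(press_values),
            fold_bounds=[(0, 1)],
            baseline_press=baseline,
        )

    def test_knee_detected(self):
        press_values = [100, 60, 40, 25, 15, 8, 4, 1.0] + [1.0] * 12
        assert select_n_latent(self._curve(press_values), plateau_tol=0.01) == 8

    def test_steep_monotone_hits_cap(self):
        press_values = 100.0 * 0.5 ** np.arange(25)
        assert select_n_latent(self._curve(press_values), cap=20) == 20

    def test_flat_curve_selects_one(self):
        assert select_n_latent(self._curve([5.0] * 10)) == 1

    def test_baseline_beats_every_latent_count(self):
        """If the mean predictor already wins, zero latents are selected."""
        assert select_n_latent(self._curve([10.0, 11.0, 12.0], baseline=9.0)) == 0
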