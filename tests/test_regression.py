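import numpy as np
import pytest

from fnirscal.regression import (
    CalibrationModel,
    cross_validate,
    fit_pls1,
    load_model,
    predict,
    save_model,
    split_calibration_validation,
)


def _random_problem(rng, n=40, p=60, n_informative=4, noise=1e-3):
    """Low-rank spectra + linear response, the bread-and-butter PLS case."""
    scores = rng.normal(0, 1, (n, n_informative))
    loadings = rng.normal(0, 1, (n_informative, p))
    X = scores @ loadings + rng.normal(0, noise, (n, p))
    beta = rng.normal(0, 1, n_informative)
    y = scores @ beta + rng.normal(0, noise, n)
    return X, y


class TestFitPls1:
    def test_rank_one_exact_with_one_factor(self, rng):
        s = rng.normal(0, 1, 30)
        direction = rng.normal(0, 1, 50)
        X = np.outer(s, direction)
        model = fit_pls1(X, s, n_factors=1, variant="standard")
        np.testing.assert_allclose(model.fitted, s, atol=1e-8)

    def test_full_rank_equals_least_squares(self, rng):
        # at full factor count PLS predictions equal the minimum-norm LS fit
        X, y = _random_problem(rng, n=25, p=12, n_informative=12, noise=0.05)
        model = fit_pls1(X, y, n_factors=12, variant="standard")
        Xc = X - X.mean(axis=0)
        beta = np.linalg.pinv(Xc) @ (y - y.mean())
        np.testing.assert_allclose(model.fitted, y.mean() + Xc @ beta, atol=1e-6)

    def test_standard_matches_sklearn_nipals(self, rng):
        sklearn = pytest.importorskip("sklearn.cross_decomposition")
        X, y = _random_problem(rng)
        for m in (1, 3, 5):
            ours = fit_pls1(X, y, n_factors=m, variant="standard")
            ref = sklearn.PLSRegression(n_components=m, scale=False).fit(X, y)
            np.testing.assert_allclose(
                ours.fitted, ref.predict(X).ravel(), atol=1e-8,
                err_msg=f"mismatch at {m} factors",
            )

    def test_modified_equals_standard_at_one_factor(self, rng):
        X, y = _random_problem(rng)
        a = fit_pls1(X, y, 1, variant="modified")
        b = fit_pls1(X, y, 1, variant="standard")
        np.testing.assert_allclose(a.fitted, b.fitted, atol=1e-8)

    def test_modified_differs_beyond_one_factor(self, rng):
        X, y = _random_problem(rng, noise=0.1)
        a = fit_pls1(X, y, 4, variant="modified")
        b = fit_pls1(X, y, 4, variant="standard")
        assert not np.allclose(a.fitted, b.fitted, atol=1e-10)

    def test_coefficient_form_matches_replay(self, rng):
        X, y = _random_problem(rng)
        for variant in ("standard", "modified"):
            model = fit_pls1(X, y, 3, variant=variant)
            direct = model.intercept + X @ model.coefficients
            np.testing.assert_allclose(direct, predict(model, X), atol=1e-9)

    def test_zero_variance_y_rejected(self, rng):
        X = rng.normal(0, 1, (10, 5))
        with pytest.raises(ValueError, match="variance"):
            fit_pls1(X, np.ones(10), 2)

    def test_excess_factors_rejected(self, rng):
        X, y = _random_problem(rng, n=8, p=5)
        with pytest.raises(ValueError, match="n_factors"):
            fit_pls1(X, y, 8)

    def test_wavelength_permutation_invariance(self, rng):
        X, y = _random_problem(rng)
        perm = rng.permutation(X.shape[1])
        a = fit_pls1(X, y, 3)
        b = fit_pls1(X[:, perm], y, 3)
        np.testing.assert_allclose(a.fitted, b.fitted, atol=1e-9)


class TestPredict:
    def test_training_predictions_match_fitted(self, rng):
        X, y = _random_problem(rng)
        model = fit_pls1(X, y, 3)
        np.testing.assert_allclose(predict(model, X), model.fitted)

    def test_duplicate_row_duplicate_prediction(self, rng):
        X, y = _random_problem(rng)
        model = fit_pls1(X, y, 3)
        two = predict(model, np.vstack([X[0], X[0]]))
        assert two[0] == two[1]

    def test_prediction_is_affine(self, rng):
        X, y = _random_problem(rng)
        model = fit_pls1(X, y, 4, variant="modified")
        x1, x2 = X[0], X[1]
        for alpha in (0.0, 0.3, 1.0):
            mix = alpha * x1 + (1 - alpha) * x2
            expected = alpha * predict(model, x1[None])[0] + (1 - alpha) * predict(model, x2[None])[0]
            assert predict(model, mix[None])[0] == pytest.approx(expected, abs=1e-9)

    def test_grid_mismatch_rejected(self, rng):
        X, y = _random_problem(rng)
        model = fit_pls1(X, y, 2)
        with pytest.raises(ValueError, match="grid mismatch"):
            predict(model, X[:, :-1])


class TestCrossValidate:
    def test_noiseless_linear_system_near_zero_secv(self, rng):
        X, y = _random_problem(rng, noise=0.0)
        cv = cross_validate(X, y, k=5, max_factors=6, seed=3)
        assert cv.secv <= 1e-6

    def test_same_seed_same_folds_and_curve(self, rng):
        X, y = _random_problem(rng)
        a = cross_validate(X, y, k=6, max_factors=5, seed=11)
        b = cross_validate(X, y, k=6, max_factors=5, seed=11)
        assert all(np.array_equal(f, g) for f, g in zip(a.folds, b.folds))
        np.testing.assert_array_equal(a.secv_by_factors, b.secv_by_factors)

    def test_loo_matches_explicit_refit_loop(self, rng):
        X, y = _random_problem(rng, n=14, p=10, noise=0.05)
        m = 3
        cv = cross_validate(X, y, k=14, max_factors=m, variant="standard", seed=0)
        # brute-force oracle: refit without each sample, predict it
        press = 0.0
        for i in range(14):
            mask = np.arange(14) != i
            model = fit_pls1(X[mask], y[mask], m, variant="standard")
            press += (predict(model, X[i][None])[0] - y[i]) ** 2
        np.testing.assert_allclose(cv.secv_by_factors[m - 1], np.sqrt(press / 14),
                                   atol=1e-8)

    def test_selected_not_worse_than_one_factor(self, rng):
        X, y = _random_problem(rng)
        cv = cross_validate(X, y, k=6, max_factors=6, seed=2)
        assert 0 <= cv.secv <= cv.secv_by_factors[0]

    def test_too_many_folds_rejected(self, rng):
        X, y = _random_problem(rng, n=5, p=4)
        with pytest.raises(ValueError):
            cross_validate(X, y, k=6)


class TestSplit:
    def test_192_samples_gives_144_48(self, rng):
        y = rng.normal(74, 3, 192)
        cal, val = split_calibration_validation(list(range(192)), y=y)
        assert (len(cal), len(val)) == (144, 48)
        assert set(cal) | set(val) == set(range(192))
        assert set(cal) & set(val) == set()

    def test_stratified_validation_inside_calibration_range(self, rng):
        y = rng.normal(0, 1, 60)
        ids = list(range(60))
        cal, val = split_calibration_validation(ids, y=y)
        assert y[val].min() >= y[cal].min()
        assert y[val].max() <= y[cal].max()

    def test_random_strategy_seeded(self):
        ids = list(range(40))
        y = np.arange(40.0)
        a = split_calibration_validation(ids, y=y, strategy="random", seed=5)
        b = split_calibration_validation(ids, y=y, strategy="random", seed=5)
        assert a == b

    def test_tiny_input_rejected(self):
        with pytest.raises(ValueError):
            split_calibration_validation([1, 2, 3], y=np.array([1.0, 2.0, 3.0]))


class TestSerialization:
    def test_save_load_round_trip_bit_exact(self, tmp_path, rng):
        X, y = _random_problem(rng)
        model = fit_pls1(X, y, 3, recipe="SNV/1.4.4.1", seed=9)
        model.secv, model.r2_cv = 0.1, 0.99
        path = tmp_path / "model.json"
        save_model(model, path)
        back = load_model(path)
        np.testing.assert_array_equal(back.coefficients, model.coefficients)
        np.testing.assert_array_equal(back.weights, model.weights)
        assert back.intercept == model.intercept
        assert (back.recipe, back.secv, back.n_factors) == ("SNV/1.4.4.1", 0.1, 3)
        np.testing.assert_array_equal(predict(back, X), predict(model, X))
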