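"""PCA, PLS1 and cross-validation against independent oracles."""

import numpy as np
import pandas as pd
import pytest

from ftirlip import (PLSCalibration, SpectraSet, calibrate, default_grid,
                     load_calibration, pca_region, save_calibration,
                     select_n_factors)
from ftirlip.chemometrics import pls1_prediction_path


def toy_data(n=20, p=5, seed=0, noise=0.0):
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(n, p))
    beta = rng.normal(size=p)
    y = X @ beta + noise * rng.normal(size=n)
    return X, y


def as_spectra_set(X, ids=None):
    grid = default_grid(3000.0, 3000.0 - 2.0 * (X.shape[1] - 1), 2.0)
    meta = pd.DataFrame({"spectrum_id": ids or
                         [f"s{i}" for i in range(X.shape[0])]})
    meta["sample_id"] = meta["spectrum_id"]
    return SpectraSet(grid, X, meta)


class TestPCA:
    def test_one_dimensional_data_explained_by_pc1(self):
        t = np.linspace(-1, 1, 12)
        direction = np.random.default_rng(0).normal(size=30)
        X = np.outer(t, direction)
        res = pca_region(as_spectra_set(X), region=(3000.0, 2942.0),
                         n_components=2)
        assert res.explained_variance_ratio[0] == pytest.approx(1.0,
                                                                abs=1e-12)

    def test_full_decomposition_reconstructs_data(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(10, 50))
        res = pca_region(as_spectra_set(X), region=(3000.0, 2902.0),
                         n_components=9)
        recon = res.scores @ res.loadings.T + res.mean
        np.testing.assert_allclose(recon, X, atol=1e-8)

    def test_loadings_orthonormal_and_ratios_monotone(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(15, 40))
        res = pca_region(as_spectra_set(X), region=(3000.0, 2922.0),
                         n_components=5)
        gram = res.loadings.T @ res.loadings
        np.testing.assert_allclose(gram, np.eye(5), atol=1e-8)
        assert np.all(np.diff(res.explained_variance_ratio) <= 1e-12)
        assert res.explained_variance_ratio.sum() <= 1.0 + 1e-12

    def test_matches_sklearn_pca(self):
        from sklearn.decomposition import PCA

        rng = np.random.default_rng(3)
        X = rng.normal(size=(12, 25))
        res = pca_region(as_spectra_set(X), region=(3000.0, 2952.0),
                         n_components=3)
        sk = PCA(n_components=3).fit(X)
        np.testing.assert_allclose(res.explained_variance_ratio,
                                   sk.explained_variance_ratio_, atol=1e-10)
        np.testing.assert_allclose(np.abs(res.loadings.T),
                                   np.abs(sk.components_), atol=1e-8)

    def test_too_few_samples_rejected(self):
        X = np.zeros((1, 30))
        with pytest.raises(ValueError, match="2 samples"):
            pca_region(as_spectra_set(X), region=(3000.0, 2942.0))


class TestPLS1Fit:
    def test_exact_linear_rank_one_fits_with_one_factor(self):
        t = np.linspace(0, 1, 15)
        X = np.outer(t, np.arange(1.0, 7.0))  # rank 1, y linear in X
        y = 3.0 * t + 1.0
        res = PLSCalibration(X, y).fit(1)
        np.testing.assert_allclose(res.fitted_values, y, atol=1e-8)

    def test_full_rank_pls_equals_least_squares(self):
        X, y = toy_data(20, 5, noise=0.3)
        res = PLSCalibration(X, y).fit(5)
        Xc = X - X.mean(axis=0)
        beta = np.linalg.lstsq(Xc, y - y.mean(), rcond=None)[0]
        ols_fit = y.mean() + Xc @ beta
        np.testing.assert_allclose(res.fitted_values, ols_fit, atol=1e-6)

    def test_joint_permutation_leaves_coefficients_unchanged(self):
        X, y = toy_data(18, 6, seed=4, noise=0.2)
        res1 = PLSCalibration(X, y).fit(3)
        perm = np.random.default_rng(0).permutation(18)
        res2 = PLSCalibration(X[perm], y[perm]).fit(3)
        np.testing.assert_allclose(res1.coef, res2.coef, atol=1e-10)

    def test_matches_sklearn_pls_predictions(self):
        from sklearn.cross_decomposition import PLSRegression

        X, y = toy_data(25, 10, seed=5, noise=0.5)
        for k in (1, 3, 5):
            res = PLSCalibration(X, y).fit(k)
            sk = PLSRegression(n_components=k, scale=False).fit(X, y)
            np.testing.assert_allclose(res.fitted_values,
                                       sk.predict(X).ravel(), atol=1e-8)

    def test_zero_variance_y_rejected(self):
        X, _ = toy_data()
        with pytest.raises(ValueError, match="zero-variance"):
            PLSCalibration(X, np.ones(20))

    def test_factors_beyond_rank_rejected_with_achievable_rank(self):
        t = np.linspace(0, 1, 10)
        X = np.outer(t, np.ones(5))  # rank 1 after centering
        y = t + 0.01 * np.sin(t * 20)
        with pytest.raises(ValueError, match="supports only 1"):
            PLSCalibration(X, y).fit(3)


def brute_force_loo_rmsecv(X, y, max_factors):
    """Independent LOO oracle: refit from scratch per fold using the
    prediction-path helper only through a fresh model object."""
    n = y.size
    preds = np.zeros((n, max_factors))
    for i in range(n):
        mask = np.ones(n, dtype=bool)
        mask[i] = False
        preds[i] = pls1_prediction_path(X[mask], y[mask], X[[i]],
                                        max_factors)
    return np.sqrt(np.mean((preds - y[:, None]) ** 2, axis=0)), preds


def sklearn_loo_rmsecv(X, y, max_factors):
    """Fully independent oracle built on scikit-learn's PLS."""
    from sklearn.cross_decomposition import PLSRegression

    n = y.size
    preds = np.zeros((n, max_factors))
    for i in range(n):
        mask = np.ones(n, dtype=bool)
        mask[i] = False
        for f in range(1, max_factors + 1):
            sk = PLSRegression(n_components=f, scale=False)
            sk.fit(X[mask], y[mask])
            preds[i, f - 1] = sk.predict(X[[i]]).ravel()[0]
    return np.sqrt(np.mean((preds - y[:, None]) ** 2, axis=0))


class TestCrossValidation:
    def test_noiseless_linear_gives_zero_rmsecv_and_unit_r2(self):
        t = np.linspace(0, 1, 15)
        X = np.column_stack([t, t ** 2 * 0.01])
        y = 2.0 * t + 0.5
        rmsecv, r2, _ = PLSCalibration(X, y).cross_validate(2)
        assert rmsecv[1] <= 1e-6
        assert r2[1] == pytest.approx(1.0, abs=1e-9)

    def test_matches_from_scratch_refit_oracle(self):
        X, y = toy_data(25, 8, seed=6, noise=0.5)
        model = PLSCalibration(X, y)
        rmsecv, _, preds = model.cross_validate(5)
        oracle, opreds = brute_force_loo_rmsecv(X, y, 5)
        np.testing.assert_allclose(rmsecv, oracle, atol=1e-10)
        np.testing.assert_allclose(preds, opreds, atol=1e-10)

    def test_matches_sklearn_loo_oracle(self):
        X, y = toy_data(15, 6, seed=7, noise=0.5)
        rmsecv, _, _ = PLSCalibration(X, y).cross_validate(4)
        oracle = sklearn_loo_rmsecv(X, y, 4)
        np.testing.assert_allclose(rmsecv, oracle, atol=1e-8)

    def test_pure_noise_response_has_low_r2(self):
        rng = np.random.default_rng(8)
        X = rng.normal(size=(30, 10))
        y = rng.normal(size=30)
        _, r2, _ = PLSCalibration(X, y).cross_validate(5)
        assert np.all(r2 < 0.2)

    def test_rmsecv_invariant_to_joint_permutation(self):
        X, y = toy_data(20, 6, seed=9, noise=0.4)
        rmsecv1, _, _ = PLSCalibration(X, y).cross_validate(4)
        perm = np.random.default_rng(1).permutation(20)
        rmsecv2, _, _ = PLSCalibration(X[perm], y[perm]).cross_validate(4)
        np.testing.assert_allclose(np.sort(rmsecv1), np.sort(rmsecv2),
                                   atol=1e-10)

    def test_group_cv_holds_out_whole_groups(self):
        X, y = toy_data(12, 4, seed=10, noise=0.2)
        groups = np.repeat(np.arange(4), 3)
        rmsecv, _, _ = PLSCalibration(X, y).cross_validate(3, cv="group",
                                                           groups=groups)
        assert rmsecv.shape == (3,)

    def test_too_few_samples_rejected(self):
        X, y = toy_data(2, 3)
        with pytest.raises(ValueError, match="at least 3"):
            PLSCalibration(X, y).cross_validate(1)


class TestFactorSelection:
    def test_flattening_curve_selects_knee(self):
        curve = np.array([10.0, 6.0, 3.0, 1.0, 0.99, 0.985, 0.984])
        assert select_n_factors(curve) == 4

    def test_monotone_increasing_curve_selects_one(self):
        assert select_n_factors(np.array([1.0, 2.0, 3.0])) == 1

    def test_constant_curve_selects_one(self):
        assert select_n_factors(np.ones(6)) == 1

    def test_f_test_rule_is_parsimonious(self):
        curve = np.array([10.0, 2.0, 1.0, 0.98, 0.97])
        nf = select_n_factors(curve, rule="f-test", n_samples=150)
        assert 2 <= nf <= 3

    def test_empty_curve_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            select_n_factors(np.array([]))


class TestPredictionAndSerialization:
    def test_training_set_prediction_reproduces_fit(self):
        X, y = toy_data(20, 5, noise=0.3)
        res = PLSCalibration(X, y).fit(3)
        np.testing.assert_allclose(res.predict(X), res.fitted_values,
                                   atol=1e-12)

    def test_mean_input_predicts_mean_response(self):
        X, y = toy_data(20, 5, noise=0.3)
        res = PLSCalibration(X, y).fit(3)
        pred = res.predict(X.mean(axis=0, keepdims=True))
        assert pred[0] == pytest.approx(y.mean(), abs=1e-12)

    def test_provenance_mismatch_names_setting(self):
        X, y = toy_data(20, 5, noise=0.3)
        model = PLSCalibration(X, y, provenance={"savgol": [9, 3, 2]})
        res = model.fit(2)
        with pytest.raises(ValueError, match="savgol"):
            res.predict(X, provenance={"savgol": [11, 3, 2]})

    def test_grid_mismatch_rejected(self):
        X, y = toy_data(20, 5, noise=0.3)
        res = PLSCalibration(X, y).fit(2)
        with pytest.raises(ValueError, match="grid mismatch"):
            res.predict(np.zeros((3, 7)))

    def test_json_round_trip_preserves_predictions(self, tmp_path):
        X, y = toy_data(20, 5, noise=0.3)
        res = PLSCalibration(X, y, target="MUFA").fit_with_cv(max_factors=4)
        path = tmp_path / "model.json"
        save_calibration(res, path)
        back = load_calibration(path)
        assert back.target == "MUFA"
        assert back.n_factors == res.n_factors
        np.testing.assert_allclose(back.predict(X), res.predict(X),
                                   atol=1e-12)
        assert back.rmsecv == pytest.approx(res.rmsecv, abs=1e-12)


class TestCalibrateReport:
    def test_report_has_three_targets_with_positive_rmsecv(self):
        rng = np.random.default_rng(11)
        n, p = 30, 20
        scores = rng.normal(size=(n, 3))
        X = scores @ rng.normal(size=(3, p)) + 0.01 * rng.normal(size=(n, p))
        ids = [f"s{i}" for i in range(n)]
        ref = pd.DataFrame({"sample_id": ids})
        for j, t in enumerate(("SAT", "MUFA", "PUFA")):
            ref[t] = 50 + 5 * scores[:, j] + 0.5 * rng.normal(size=n)
        results, report = calibrate(as_spectra_set(X, ids), ref,
                                    max_factors=8)
        assert list(report["Fatty acid"]) == ["SAT", "MUFA", "PUFA"]
        assert (report["RMSECV"] > 0).all()
        assert (report["Factors"] >= 1).all()
        for res in results.values():
            assert "RMSECV" in res.summary()
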