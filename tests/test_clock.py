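"""Elastic-net solver, CV penalty selection, clock training and prediction."""

import numpy as np
import pandas as pd
import pytest

import germclock as g
from germclock.clock import _standardize, elastic_net_objective, lambda_max, lambda_path


def random_instance(rng, n=20, p=5, noise=0.5):
    X = rng.normal(size=(n, p))
    Xs, _, _ = _standardize(X)
    beta = rng.normal(size=p)
    y = Xs @ beta + noise * rng.normal(size=n)
    return Xs, y


class TestFitElasticNet:
    def test_unpenalized_fit_matches_ols(self):
        rng = np.random.default_rng(0)
        X, y = random_instance(rng)
        coef, intercept, _ = g.fit_elastic_net(X, y, alpha=0.5, lam=0.0, tol=1e-10)
        yc = y - y.mean()
        ols, *_ = np.linalg.lstsq(X, yc, rcond=None)
        np.testing.assert_allclose(coef, ols, atol=1e-6)
        assert intercept == pytest.approx(y.mean())

    def test_lasso_null_threshold_zeroes_everything(self):
        rng = np.random.default_rng(1)
        X, y = random_instance(rng)
        lmax = lambda_max(X, y, alpha=1.0)
        coef, intercept, _ = g.fit_elastic_net(X, y, alpha=1.0, lam=lmax * 1.0001)
        assert np.all(coef == 0.0)
        assert intercept == pytest.approx(y.mean())

    @pytest.mark.parametrize("alpha", [0.25, 0.5, 1.0])
    def test_objective_matches_sklearn_coordinate_descent(self, alpha):
        """Independent cross-check against scikit-learn's solver."""
        from sklearn.linear_model import ElasticNet

        rng = np.random.default_rng(2)
        X, y = random_instance(rng, n=30, p=8)
        lam = 0.3
        coef, intercept, _ = g.fit_elastic_net(X, y, alpha=alpha, lam=lam, tol=1e-10)
        sk = ElasticNet(alpha=lam, l1_ratio=alpha, fit_intercept=True, tol=1e-10, max_iter=100_000)
        sk.fit(X, y)
        np.testing.assert_allclose(coef, sk.coef_, atol=1e-5)
        yc = y - y.mean()
        ours = elastic_net_objective(X, yc, coef, alpha, lam)
        theirs = elastic_net_objective(X, yc, sk.coef_, alpha, lam)
        assert ours <= theirs + 1e-8

    @pytest.mark.parametrize("alpha", [0.25, 1.0])
    def test_kkt_conditions_at_convergence(self, alpha):
        rng = np.random.default_rng(3)
        X, y = random_instance(rng, n=25, p=6)
        lam = 0.2
        coef, _, _ = g.fit_elastic_net(X, y, alpha=alpha, lam=lam, tol=1e-12)
        n = X.shape[0]
        yc = y - y.mean()
        r = yc - X @ coef
        z = X.T @ r / n
        for j in range(len(coef)):
            if coef[j] == 0.0:
                assert abs(z[j]) <= lam * alpha + 1e-8
            else:
                # stationarity: z_j = lam*alpha*sign(b_j) + lam*(1-alpha)*b_j
                target = lam * alpha * np.sign(coef[j]) + lam * (1 - alpha) * coef[j]
                assert z[j] == pytest.approx(target, abs=1e-8)

    def test_objective_non_increasing_with_warm_start_path(self):
        rng = np.random.default_rng(4)
        X, y = random_instance(rng)
        grid = lambda_path(lambda_max(X, y, 0.5), n_lambda=20)
        yc = y - y.mean()
        beta = np.zeros(X.shape[1])
        for lam in grid:
            before = elastic_net_objective(X, yc, beta, 0.5, lam)
            beta, _, _ = g.fit_elastic_net(X, y, alpha=0.5, lam=lam, beta_init=beta)
            after = elastic_net_objective(X, yc, beta, 0.5, lam)
            assert after <= before + 1e-12

    def test_non_finite_input_raises(self):
        X = np.array([[1.0, np.nan], [0.0, 1.0]])
        with pytest.raises(ValueError):
            g.fit_elastic_net(X, np.array([1.0, 2.0]))


class TestCvSelectLambda:
    def test_single_value_grid_is_returned(self):
        rng = np.random.default_rng(5)
        X, y = random_instance(rng)
        lam, curve = g.cv_select_lambda(X, y, lambda_grid=np.array([0.7]), k_folds=3, seed=0)
        assert lam == pytest.approx(0.7)
        assert len(curve) == 1

    def test_pure_noise_prefers_heavy_penalty(self):
        """Under a null signal the CV minimum sits at or near the top of the path."""
        hits = 0
        for seed in range(20):
            rng = np.random.default_rng(100 + seed)
            X = rng.normal(size=(30, 5))
            Xs, _, _ = _standardize(X)
            y = rng.normal(size=30)
            lmax = lambda_max(Xs, y, 0.5)
            grid = lambda_path(lmax, n_lambda=50)
            lam, _ = g.cv_select_lambda(Xs, y, alpha=0.5, k_folds=5, lambda_grid=grid, seed=seed)
            hits += lam >= lmax * 0.1  # within the top decade of a four-decade path
        assert hits >= 18

    def test_strong_signal_beats_null_model_error(self):
        rng = np.random.default_rng(6)
        X = rng.normal(size=(40, 5))
        Xs, _, _ = _standardize(X)
        y = 3.0 * Xs[:, 0] + 0.3 * rng.normal(size=40)
        lam, curve = g.cv_select_lambda(Xs, y, alpha=0.5, k_folds=5, seed=0)
        best = curve.loc[curve["lam"] == lam, "cv_mse"].iloc[0]
        assert best < y.var()

    def test_sparsity_monotone_along_path(self):
        rng = np.random.default_rng(7)
        X, y = random_instance(rng, n=30, p=8)
        _, curve = g.cv_select_lambda(X, y, alpha=1.0, k_folds=5, seed=1)
        nnz = curve["n_nonzero"].to_numpy()  # along descending lambda
        # active set grows as the penalty relaxes, bar rare plateau ties
        assert nnz[0] == 0
        violations = np.sum(np.diff(nnz) < 0)
        assert violations <= max(1, int(0.05 * len(nnz)))

    def test_fold_assignment_deterministic(self):
        rng = np.random.default_rng(8)
        X, y = random_instance(rng)
        lam1, c1 = g.cv_select_lambda(X, y, k_folds=4, seed=3)
        lam2, c2 = g.cv_select_lambda(X, y, k_folds=4, seed=3)
        assert lam1 == lam2
        pd.testing.assert_frame_equal(c1, c2)


def region_features(seed, n_per_cell=6, bmi_years=0.0, include_bmi=False):
    cohort = g.generate_cohort(g.CohortDesign(n_per_cell=n_per_cell), seed=seed)
    params = g.SimulationParams(
        n_cpgs=96, cpgs_per_region=8, n_clock_regions=12,
        age_slope_sd=0.02, noise_sd=0.3, bmi_acceleration_years=bmi_years,
    )
    beta, region_map, truth = g.simulate_methylome(cohort, params, seed=seed)
    region_m = g.aggregate_regions(beta, region_map)
    feats = g.clock_features(region_m, truth.clock_region_ids, cohort=cohort, include_bmi=include_bmi)
    ages = cohort.set_index("id")["age"].reindex(feats.index).to_numpy()
    return cohort, feats, ages


class TestTrainPredict:
    def test_bmi_toggles_feature_count(self, small_sim):
        cohort, beta, region_map, truth = small_sim
        region_m = g.aggregate_regions(beta, region_map)
        feats = g.clock_features(region_m, truth.clock_region_ids, cohort=cohort, include_bmi=False)
        feats_bmi = g.clock_features(region_m, truth.clock_region_ids, cohort=cohort, include_bmi=True)
        assert feats.shape[1] == len(truth.clock_region_ids)
        assert feats_bmi.shape[1] == len(truth.clock_region_ids) + 1
        assert "bmi" in feats_bmi.columns

    def test_training_deterministic_and_serializable(self):
        _, feats, ages = region_features(seed=30)
        m1 = g.train_clock(feats, ages, alpha=0.5, k_folds=4,
                           lambda_grid=g.lambda_path(5.0, n_lambda=20), seed=7)
        m2 = g.train_clock(feats, ages, alpha=0.5, k_folds=4,
                           lambda_grid=g.lambda_path(5.0, n_lambda=20), seed=7)
        assert m1.to_json() == m2.to_json()
        restored = g.ClockModel.from_json(m1.to_json())
        np.testing.assert_allclose(restored.coef, m1.coef)
        p1 = g.predict_age(m1, feats)
        p2 = g.predict_age(restored, feats)
        np.testing.assert_allclose(p1["predicted_age"], p2["predicted_age"])

    def test_training_mae_below_five_years(self):
        _, feats, ages = region_features(seed=31)
        model = g.train_clock(feats, ages, lam=0.01, seed=0)
        pred = g.predict_age(model, feats, ages=ages)
        assert g.mae(pred["actual_age"], pred["predicted_age"]) < 5.0

    def test_noiseless_full_rank_interpolates(self):
        rng = np.random.default_rng(9)
        X = pd.DataFrame(rng.normal(size=(10, 3)), columns=list("abc"),
                         index=[f"s{i}" for i in range(10)])
        ages = 30.0 + X.to_numpy() @ np.array([2.0, -1.0, 0.5])
        model = g.train_clock(X, ages, lam=0.0, seed=0, tol=1e-12)
        pred = g.predict_age(model, X, ages=ages)
        np.testing.assert_allclose(pred["predicted_age"], ages, atol=1e-6)

    def test_null_model_predicts_intercept_everywhere(self):
        _, feats, ages = region_features(seed=32)
        Xs, _, _ = _standardize(feats.to_numpy())
        yn = (ages - ages.mean()) / ages.std()  # training normalizes the response
        lmax = lambda_max(Xs, yn, 1.0)
        model = g.train_clock(feats, ages, alpha=1.0, lam=lmax * 1.1, seed=0)
        assert np.all(model.coef == 0.0)
        pred = g.predict_age(model, feats)
        np.testing.assert_allclose(pred["predicted_age"], model.intercept)
        # a feature vector at the training means also maps to the intercept
        mean_row = pd.DataFrame([model.feature_means], columns=model.feature_names, index=["mean"])
        assert g.predict_age(model, mean_row)["predicted_age"].iloc[0] == pytest.approx(model.intercept)

    def test_scale_equivariance_of_ages(self):
        _, feats, ages = region_features(seed=33)
        m1 = g.train_clock(feats, ages, k_folds=4, seed=5)
        m2 = g.train_clock(feats, ages * 2.0, k_folds=4, seed=5)
        p1 = g.predict_age(m1, feats)["predicted_age"]
        p2 = g.predict_age(m2, feats)["predicted_age"]
        np.testing.assert_allclose(p2, 2.0 * p1, rtol=1e-9)

    def test_bmi_coefficient_corrects_injected_acceleration(self):
        """With injected high-BMI over-aging the clock weights BMI negatively,
        subtracting the acceleration to recover chronological age."""
        negatives = 0
        for seed in range(10):
            _, feats, ages = region_features(seed=40 + seed, bmi_years=5.0, include_bmi=True)
            model = g.train_clock(feats, ages, include_bmi=True, lam=0.01, seed=seed)
            negatives += model.coef[model.feature_names.index("bmi")] < 0
        assert negatives >= 9

    def test_feature_mismatch_and_missing_bmi_raise(self):
        _, feats, ages = region_features(seed=34)
        with pytest.raises(ValueError):
            g.train_clock(feats, ages, include_bmi=True, lam=0.1)
        model = g.train_clock(feats, ages, lam=0.1)
        with pytest.raises(ValueError):
            g.predict_age(model, feats.drop(columns=feats.columns[:1]))
        with pytest.raises(ValueError):
            g.predict_age(model, feats.assign(extra=1.0))
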