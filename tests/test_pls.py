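"""From-scratch PLS against least-squares and sklearn oracles."""

import numpy as np
import pandas as pd
import pytest

from gaitdose import (
    PLSEFieldRegressor,
    center_columns,
    default_montage_profiles,
    extract_loadings,
    fit_pls,
    generate_cohort,
    generate_efield_matrix,
    plant_gait_change,
    random_planted_association,
    response_r2,
)
from gaitdose.events import SchemaError
from gaitdose.indices import InvalidInputError


def random_problem(rng, n=25, p=6, m=3, noise=0.1):
    X = rng.normal(size=(n, p))
    B = rng.normal(size=(p, m))
    Y = X @ B + rng.normal(size=(n, m)) * noise
    return X, Y


class TestCenterColumns:
    def test_hand_example(self):
        centered, means = center_columns(np.array([[1.0], [2.0], [3.0]]))
        assert np.allclose(centered.ravel(), [-1, 0, 1])
        assert means[0] == pytest.approx(2.0)

    def test_idempotent(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(10, 4))
        once, _ = center_columns(X)
        twice, means2 = center_columns(once)
        assert np.allclose(once, twice)
        assert np.allclose(means2, 0.0)

    def test_single_row_rejected(self):
        with pytest.raises(InvalidInputError):
            center_columns(np.ones((1, 3)))


class TestResponseR2:
    def test_perfect_fit(self):
        Y = np.arange(6.0).reshape(3, 2)
        assert response_r2(Y, Y) == pytest.approx(1.0)

    def test_column_mean_fit_is_zero(self):
        Y = np.array([[0.0, 0.0], [2.0, 2.0]])
        fitted = np.array([[1.0, 1.0], [1.0, 1.0]])
        assert response_r2(Y, fitted) == pytest.approx(0.0)

    def test_constant_observed_rejected(self):
        Y = np.ones((4, 2))
        with pytest.raises(InvalidInputError):
            response_r2(Y, Y)


class TestFit:
    def test_univariate_proportional_response_exact(self):
        X = np.array([[1.0], [2.0], [3.0], [4.0]])
        model = fit_pls(X, 2.0 * X, n_components=1)
        assert model.r_squared_ == pytest.approx(1.0)
        assert model.coef_[0, 0] == pytest.approx(2.0)

    def test_full_components_match_normal_equations_oracle(self):
        """Full-component PLS equals OLS on 20 random full-rank problems."""
        rng = np.random.default_rng(123)
        for _ in range(20):
            X, Y = random_problem(rng)
            model = fit_pls(X, Y, n_components=X.shape[1])
            Xc = X - X.mean(axis=0)
            Yc = Y - Y.mean(axis=0)
            B = np.linalg.solve(Xc.T @ Xc, Xc.T @ Yc)
            oracle = Xc @ B + Y.mean(axis=0)
            fitted = model.predict(X)
            assert np.abs(fitted - oracle).max() / np.abs(oracle).max() < 1e-8

    def test_matches_sklearn_pls_predictions(self):
        """Independent cross-check against sklearn's NIPALS (scale=False)."""
        sklearn_pls = pytest.importorskip(
            "sklearn.cross_decomposition").PLSRegression
        rng = np.random.default_rng(5)
        X, Y = random_problem(rng, n=30, p=8, m=4)
        for k in (1, 3, 8):
            ours = fit_pls(X, Y, n_components=k).predict(X)
            theirs = sklearn_pls(n_components=k, scale=False,
                                 tol=1e-14, max_iter=10000).fit(X, Y).predict(X)
            # sklearn extracts weights by iterative power method, ours by
            # direct SVD; agreement is limited by its convergence tolerance
            assert np.allclose(ours, theirs, atol=1e-5)

    def test_scores_mutually_orthogonal(self):
        rng = np.random.default_rng(2)
        X, Y = random_problem(rng)
        model = fit_pls(X, Y, n_components=5)
        G = model.x_scores_.T @ model.x_scores_
        off = G - np.diag(np.diag(G))
        assert np.abs(off).max() / np.abs(np.diag(G)).max() < 1e-8

    def test_sign_convention_is_deterministic(self):
        rng = np.random.default_rng(3)
        X, Y = random_problem(rng)
        m1 = fit_pls(X, Y, n_components=4)
        m2 = fit_pls(X, Y, n_components=4)
        assert np.array_equal(m1.x_weights_, m2.x_weights_)
        for k in range(m1.x_weights_.shape[1]):
            w = m1.x_weights_[:, k]
            assert w[np.argmax(np.abs(w))] > 0

    def test_rank_deficient_cross_covariance_truncates_with_warning(self):
        X = np.array([[1.0, 1.0], [2.0, 2.0], [3.0, 3.0], [4.0, 4.0]])
        Y = X @ np.array([[1.0], [0.5]])
        with pytest.warns(RuntimeWarning, match="truncated"):
            model = fit_pls(X, Y, n_components=2)
        assert model.n_components_ == 1
        assert model.r_squared_ == pytest.approx(1.0)

    def test_mismatched_rows_rejected(self):
        with pytest.raises(InvalidInputError):
            fit_pls(np.ones((4, 2)), np.ones((5, 1)), 1)


class TestExplainedVariance:
    def test_cumulative_y_variance_equals_r_squared(self):
        rng = np.random.default_rng(9)
        X, Y = random_problem(rng, noise=0.5)
        model = fit_pls(X, Y, n_components=X.shape[1])
        table = model.explained_variance()
        assert table["cum_pct_var_y"].iloc[-1] == pytest.approx(
            100.0 * model.r_squared_, rel=1e-10)

    def test_cumulative_y_variance_monotone(self):
        rng = np.random.default_rng(10)
        X, Y = random_problem(rng, noise=1.0)
        model = fit_pls(X, Y, n_components=X.shape[1])
        cum = model.explained_variance()["cum_pct_var_y"].to_numpy()
        assert (np.diff(cum) >= -1e-12).all()
        assert cum[-1] <= 100.0 + 1e-9

    def test_noise_free_map_reaches_100(self):
        rng = np.random.default_rng(11)
        X, Y = random_problem(rng, noise=0.0)
        model = fit_pls(X, Y, n_components=X.shape[1])
        assert model.pct_var_y_.sum() == pytest.approx(100.0)

    def test_rank1_design_splits_match_svd_shares(self):
        # X with two orthogonal blocks; one component captures exactly the
        # dominant singular share of the centered X sum of squares
        Xc = np.array([[2.0, 0.0], [-2.0, 0.0], [0.0, 1.0], [0.0, -1.0]])
        Y = Xc[:, [0]]
        model = fit_pls(Xc, Y, n_components=1)
        # component 1 is the first column direction: captures 8 of SSX=10
        assert model.pct_var_x_[0] == pytest.approx(80.0)
        assert model.pct_var_y_[0] == pytest.approx(100.0)


class TestPredict:
    def test_training_prediction_exact_for_noise_free(self):
        rng = np.random.default_rng(12)
        X, Y = random_problem(rng, noise=0.0)
        model = fit_pls(X, Y, n_components=X.shape[1])
        assert np.allclose(model.predict(X), Y, atol=1e-8)

    def test_row_of_means_predicts_means(self):
        rng = np.random.default_rng(13)
        X, Y = random_problem(rng)
        model = fit_pls(X, Y, n_components=3)
        pred = model.predict(X.mean(axis=0)[None, :])
        assert np.allclose(pred.ravel(), Y.mean(axis=0))

    def test_column_permutation_aligned_by_labels(self):
        rng = np.random.default_rng(14)
        X, Y = random_problem(rng, p=5)
        cols = [f"lob{i}" for i in range(5)]
        Xdf = pd.DataFrame(X, columns=cols)
        Ydf = pd.DataFrame(Y, columns=["a", "b", "c"])
        model = fit_pls(Xdf, Ydf, n_components=3)
        permuted = Xdf[cols[::-1]]
        assert np.allclose(model.predict(permuted).to_numpy(),
                           model.predict(Xdf).to_numpy())

    def test_label_mismatch_is_schema_error(self):
        Xdf = pd.DataFrame(np.random.default_rng(0).normal(size=(6, 3)),
                           columns=["a", "b", "c"])
        model = fit_pls(Xdf, Xdf[["a"]] * 2.0, n_components=1)
        with pytest.raises(SchemaError):
            model.predict(Xdf.rename(columns={"a": "z"}))


class TestLoadings:
    @pytest.fixture
    def planted_fit(self):
        cohort = generate_cohort(10, seed=21)
        efield = generate_efield_matrix(
            default_montage_profiles(), cohort, seed=21)
        assoc = random_planted_association(n_active=1, seed=21)
        change = plant_gait_change(efield, assoc)
        return efield, assoc, fit_pls(efield, change, n_components=5)

    def test_long_format_tables(self, planted_fit):
        efield, _, model = planted_fit
        tables = extract_loadings(model, efield)
        assert set(tables) == {"x_loadings", "y_loadings", "contrast"}
        assert list(tables["x_loadings"].columns) == [
            "component", "variable", "loading"]
        n_predictors = efield.shape[1]
        assert len(tables["x_loadings"]) == model.n_components_ * n_predictors

    def test_rank1_association_dominates_component1_y_loadings(self, planted_fit):
        """With one active lobule the response loadings of component 1 are
        proportional to the planted coefficient row."""
        _, assoc, model = planted_fit
        planted_row = assoc.coefficient_matrix.loc[
            assoc.active_lobules[0]].to_numpy()
        q1 = model.y_loadings_[:, 0]
        cosine = abs(q1 @ planted_row) / (
            np.linalg.norm(q1) * np.linalg.norm(planted_row))
        assert cosine > 0.99

    def test_identical_profiles_give_zero_contrast(self):
        profiles = default_montage_profiles(between_subject_sd=0.0)
        same = {"dentate": profiles["dentate"],
                "leg": type(profiles["leg"])(
                    "leg", profiles["dentate"].lobule_labels,
                    profiles["dentate"].mean_field,
                    profiles["dentate"].between_subject_sd)}
        cohort = generate_cohort(4, seed=0)
        efield = generate_efield_matrix(same, cohort, seed=0)
        assoc = random_planted_association(seed=1)
        change = plant_gait_change(efield, assoc)
        # identical montage profiles: no montage contrast to model
        means = efield.groupby(level="montage").mean()
        contrast = means.loc["dentate"] - means.loc["leg"]
        assert np.allclose(contrast.to_numpy(), 0.0)
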