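import warnings

import numpy as np
import pytest
from scipy.special import expit, logit

from latentniche import (
    ModelSpec,
    SpatialGLLVM,
    SyntheticConfig,
    candidate_model_grid,
    cross_validate_select,
    generate_coastline_sites,
    generate_communities,
    linear_predictor,
    log_likelihood,
    variance_partition,
)


class TestCandidateGrid:
    def test_three_sets_times_six_dimensions(self):
        sets = {"a": ("temp", "sal"),
                "b": ("sst_min", "sst_max", "chl", "pic"),
                "c": ("temp", "sal", "sst_min", "sst_max", "chl", "pic")}
        specs = candidate_model_grid(sets)
        assert len(specs) == 18
        assert len({s.name for s in specs}) == 18
        assert sorted({s.n_latent for s in specs}) == [0, 1, 2, 3, 4, 5]

    def test_latent_dimension_bounds(self):
        with pytest.raises(ValueError):
            ModelSpec(name="bad", covariate_cols=(), n_latent=6)


class TestLinearPredictor:
    def test_all_zero_gives_half(self):
        eta, p = linear_predictor(np.zeros(3), np.zeros((1, 3)), np.zeros((1, 3)),
                                  np.zeros((4, 1)), np.zeros((4, 1)), np.zeros(4))
        np.testing.assert_allclose(eta, 0.0)
        np.testing.assert_allclose(p, 0.5)

    def test_hand_arithmetic(self):
        # 0.5 + 2*(-0.25) + 1*0.5 - 0.5 = 0 -> p = 0.5
        eta, p = linear_predictor([0.5], [[-0.25]], [[0.5]],
                                  [[2.0]], [[1.0]], [-0.5])
        np.testing.assert_allclose(eta, 0.0, atol=1e-15)
        np.testing.assert_allclose(p, 0.5, atol=1e-15)

    def test_monotone_in_eta(self):
        etas = np.linspace(-30, 30, 101)
        p = expit(etas)
        assert np.all(np.diff(p) > 0)
        # overflow-safe at extreme predictors
        _, p_ext = linear_predictor([1000.0], np.zeros((0, 1)), np.zeros((0, 1)),
                                    np.zeros((1, 0)), np.zeros((1, 0)))
        assert np.isfinite(p_ext).all()

    def test_dimension_mismatch_rejected(self):
        with pytest.raises(ValueError):
            linear_predictor([0.0, 0.0], [[1.0]], np.zeros((0, 2)),
                             np.zeros((3, 2)), np.zeros((3, 0)))


class TestLogLikelihood:
    def test_single_cell_half(self):
        np.testing.assert_allclose(log_likelihood(np.array([[1.0]]), np.array([[0.5]])),
                                   np.log(0.5), atol=1e-12)

    def test_degenerate_consistent(self):
        assert log_likelihood(np.array([[1.0]]), np.array([[1.0]])) == 0.0

    def test_degenerate_contradiction_is_minus_inf(self):
        assert log_likelihood(np.array([[1.0]]), np.array([[0.0]])) == -np.inf
        assert log_likelihood(np.array([[0.0]]), np.array([[1.0]])) == -np.inf

    def test_brute_force_equivalence(self):
        rng = np.random.default_rng(4)
        y = (rng.random((3, 3)) < 0.5).astype(float)
        p = rng.uniform(0.05, 0.95, (3, 3))
        brute = sum(np.log(p[i, j]) if y[i, j] else np.log(1 - p[i, j])
                    for i in range(3) for j in range(3))
        np.testing.assert_allclose(log_likelihood(y, p), brute, atol=1e-12)


class TestFit:
    def test_intercept_only_closed_form(self):
        # with no covariates, latent variables or site effects the MLE of each
        # species intercept is logit of its prevalence
        rng = np.random.default_rng(0)
        Y = (rng.random((40, 5)) < np.array([0.2, 0.4, 0.5, 0.7, 0.9])).astype(float)
        coords = generate_coastline_sites(40, seed=0)
        m = SpatialGLLVM(n_latent=0, include_site_effects=False).fit(Y, coords)
        np.testing.assert_allclose(m.intercepts_, logit(Y.mean(axis=0)), atol=1e-4)

    def test_loading_identifiability_constraint(self, small_fit):
        G = small_fit.loadings_
        for k in range(G.shape[0]):
            assert np.all(G[k, :k] == 0.0)
            assert G[k, k] > 0.0

    def test_objective_trace_non_increasing(self, small_fit):
        assert np.all(np.diff(small_fit.objective_trace_) <= 1e-6)

    def test_fit_deterministic(self, small_community):
        truth, det, _ = small_community
        Y = det.data.to_numpy().T.astype(float)
        kw = dict(n_latent=1, spatial_ranges=(0.4,), sigma_alpha=0.3,
                  n_outer=1, max_iter=300)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            a = SpatialGLLVM(**kw).fit(Y, truth.coords, truth.covariates)
            b = SpatialGLLVM(**kw).fit(Y, truth.coords, truth.covariates)
        np.testing.assert_array_equal(a.latent_fields_, b.latent_fields_)
        np.testing.assert_array_equal(a.intercepts_, b.intercepts_)

    def test_non_convergence_warns(self, small_community):
        truth, det, _ = small_community
        Y = det.data.to_numpy().T.astype(float)
        with pytest.warns(UserWarning, match="did not report convergence"):
            m = SpatialGLLVM(n_latent=1, spatial_ranges=(0.4,), sigma_alpha=0.3,
                             n_outer=1, max_iter=2).fit(Y, truth.coords, truth.covariates)
        assert not m.converged_

    def test_non_binary_input_rejected(self):
        coords = generate_coastline_sites(5, seed=0)
        with pytest.raises(ValueError):
            SpatialGLLVM(n_latent=0).fit(np.full((5, 2), 3.0), coords)


class TestPrediction:
    def test_training_sites_reproduced(self, small_fit):
        _, P_train = linear_predictor(small_fit.intercepts_, small_fit.coefs_,
                                      small_fit.loadings_, small_fit.X_,
                                      small_fit.latent_fields_, small_fit.site_effects_)
        P = small_fit.predict_proba(small_fit.coords_, small_fit.X_)
        np.testing.assert_allclose(P, P_train, atol=1e-8)
        # marginal mode also reproduces training sites (zero predictive variance)
        P_marg = small_fit.predict_proba(small_fit.coords_, small_fit.X_, marginal=True)
        np.testing.assert_allclose(P_marg, P_train, atol=1e-6)

    def test_far_field_is_covariate_only(self, small_fit):
        far = np.array([[200.0, 200.0]])
        x = np.array([[0.5, -0.3]])
        P = small_fit.predict_proba(far, x)
        eta_cov = small_fit.intercepts_ + x @ small_fit.coefs_
        np.testing.assert_allclose(P, expit(eta_cov), atol=1e-6)

    def test_latent_prediction_matches_dense_conditional(self, small_fit):
        from latentniche.spatial import matern_covariance, matern_cross_covariance
        new = small_fit.coords_[:5] + 0.013
        U_pred = small_fit.predict_latent(new)
        for k in range(small_fit.n_latent):
            C = matern_covariance(small_fit.coords_, small_fit.ranges_[k], 1.0)
            C[np.diag_indices_from(C)] += 1e-10
            Cnt = matern_cross_covariance(new, small_fit.coords_, small_fit.ranges_[k], 1.0)
            oracle = Cnt @ np.linalg.solve(C, small_fit.latent_fields_[:, k])
            np.testing.assert_allclose(U_pred[:, k], oracle, atol=1e-6)

    def test_missing_covariates_rejected(self, small_fit):
        with pytest.raises(ValueError):
            small_fit.predict_proba(np.zeros((2, 2)))
        with pytest.raises(ValueError):
            small_fit.predict_proba(np.zeros((1, 2)), np.array([[np.nan, 0.0]]))


class TestVariancePartition:
    def test_single_latent_no_covariates(self, small_community):
        truth, det, _ = small_community
        Y = det.data.to_numpy().T.astype(float)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            m = SpatialGLLVM(n_latent=1, spatial_ranges=(0.4,), sigma_alpha=0.3,
                             n_outer=1, max_iter=400).fit(Y, truth.coords)
        vp = variance_partition(m)
        np.testing.assert_allclose(vp.to_numpy(), [1.0], atol=1e-10)

    def test_fractions_sum_to_one(self, small_fit):
        vp = variance_partition(small_fit)
        np.testing.assert_allclose(vp.sum(), 1.0, atol=1e-10)
        assert np.all(vp.to_numpy() >= 0)

    def test_null_covariates_get_near_zero_share(self):
        # zero true covariate effects with spatially white covariates (so the
        # covariate and latent contributions are identifiable): the fitted
        # covariate fractions are ~ 0
        from latentniche import generate_coastline_sites, sample_matern_fields
        rng = np.random.default_rng(21)
        n, n_sp = 150, 30
        coords = generate_coastline_sites(n, seed=21)
        x = rng.standard_normal((n, 2))
        u = sample_matern_fields(coords, (0.3, 0.6), (1.0, 1.0), seed=22)
        beta0 = rng.normal(-1, 1, n_sp)
        G = rng.normal(0, 1, (2, n_sp))
        alpha = rng.normal(0, 0.25, n)
        eta = beta0[None, :] + u @ G + alpha[:, None]
        Y = (rng.random((n, n_sp)) < expit(eta)).astype(float)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            m = SpatialGLLVM(n_latent=2, n_outer=2, max_iter=800).fit(Y, coords, x)
        vp = variance_partition(m, covariate_names=["cov_a", "cov_b"])
        assert vp["cov_a"] < 0.05
        assert vp["cov_b"] < 0.05


class TestCrossValidation:
    def test_folds_partition_sites(self, small_community):
        truth, det, sites = small_community
        specs = [ModelSpec(name="L0", covariate_cols=("temperature", "salinity"), n_latent=0),
                 ModelSpec(name="L1", covariate_cols=("temperature", "salinity"), n_latent=1)]
        cv = cross_validate_select(det, sites, specs, k=4, seed=0,
                                   max_iter=150, n_outer=1, sigma_alpha=0.3)
        counts = cv.fold_assignment.value_counts()
        assert cv.fold_assignment.shape[0] == det.n_sites
        assert sorted(counts.index) == [0, 1, 2, 3]
        assert counts.sum() == det.n_sites
        assert cv.table.shape == (2, 5)
        assert cv.selected.name == cv.table["mean_nll"].idxmin()

    def test_invalid_k_rejected(self, small_community):
        _, det, sites = small_community
        spec = ModelSpec(name="L0", covariate_cols=(), n_latent=0)
        with pytest.raises(ValueError):
            cross_validate_select(det, sites, [spec], k=1)
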