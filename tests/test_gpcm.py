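import numpy as np
import pytest
from scipy.stats import multivariate_normal
from sklearn.metrics import adjusted_rand_score

from ricemix import gpcm


def naive_full_cov_em(X, z0, max_iter=50):
    """Independent naive EM for an unconstrained Gaussian mixture.

    Direct densities via scipy multivariate_normal, no Woodbury, no floors;
    returns the log-likelihood trace (one entry per iteration, recorded after
    each E-step) for trajectory comparison against the VVV fit.
    """
    n, p = X.shape
    G = z0.shape[1]
    z = z0.copy()
    trace = []
    for _ in range(max_iter):
        ng = z.sum(axis=0)
        w = ng / n
        mu = (z.T @ X) / ng[:, None]
        covs = []
        for g in range(G):
            d = X - mu[g]
            covs.append((z[:, g][:, None] * d).T @ d / ng[g])
        dens = np.column_stack([
            w[g] * multivariate_normal.pdf(X, mu[g], covs[g]) for g in range(G)
        ])
        tot = dens.sum(axis=1)
        trace.append(float(np.log(tot).sum()))
        z = dens / tot[:, None]
    return np.array(trace)


def sample_mixture(rng, n_per, centers, cov_scale=0.05):
    X = np.vstack([
        rng.multivariate_normal(c, cov_scale * np.eye(len(c)), size=n_per)
        for c in centers
    ])
    labels = np.repeat(np.arange(len(centers)), n_per)
    return X, labels


class TestSingleComponentClosedForm:
    @pytest.mark.parametrize("model", gpcm.MODEL_NAMES)
    def test_mean_is_sample_mean(self, model):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(40, 4))
        fit = gpcm.fit_gpcm(X, G=1, model_name=model)
        np.testing.assert_allclose(fit.means[0], X.mean(axis=0), atol=1e-10)

    def test_eii_lambda_is_trace_over_np(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(30, 4)) * np.array([1.0, 2.0, 0.5, 1.5])
        fit = gpcm.fit_gpcm(X, G=1, model_name="EII")
        scatter = ((X - X.mean(axis=0)) ** 2).sum()
        lam = scatter / (X.shape[0] * X.shape[1])
        np.testing.assert_allclose(fit.covariances[0], lam * np.eye(4), atol=1e-10)

    def test_vvv_is_mle_covariance(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(25, 3))
        fit = gpcm.fit_gpcm(X, G=1, model_name="VVV")
        np.testing.assert_allclose(fit.covariances[0], np.cov(X.T, bias=True), atol=1e-10)


class TestWellSeparatedRecovery:
    def test_two_cluster_means_and_weights(self):
        rng = np.random.default_rng(3)
        X = np.vstack([
            np.zeros((10, 4)) + rng.uniform(-0.01, 0.01, (10, 4)),
            np.full((10, 4), 10.0) + rng.uniform(-0.01, 0.01, (10, 4)),
        ])
        fit = gpcm.fit_gpcm(X, G=2, model_name="VII", seed=0, n_starts=4)
        means = fit.means[np.argsort(fit.means[:, 0])]
        assert np.all(np.abs(means[0]) < 0.05)
        assert np.all(np.abs(means[1] - 10.0) < 0.05)
        np.testing.assert_allclose(fit.weights, [0.5, 0.5], atol=1e-6)

    def test_labels_match_ground_truth(self):
        rng = np.random.default_rng(4)
        X, truth = sample_mixture(rng, 30, [[0, 0, 0, 0], [8, 8, 8, 8]])
        fit = gpcm.fit_gpcm(X, G=2, model_name="EII", seed=1, n_starts=4)
        assert adjusted_rand_score(truth, gpcm.predict_labels(fit)) == 1.0

    def test_tie_goes_to_lowest_index(self):
        fit_like = gpcm.GPCMFit(
            G=2, model_name="EII", weights=np.array([0.5, 0.5]),
            means=np.zeros((2, 2)), covariances=np.stack([np.eye(2)] * 2),
            volumes=np.ones(2), orientations=np.stack([np.eye(2)] * 2),
            shapes=np.ones((2, 2)),
            responsibilities=np.array([[0.9, 0.1], [0.5, 0.5]]),
            log_likelihood=0.0, n_params=1, bic=0.0, n_iter=1, converged=True)
        np.testing.assert_array_equal(gpcm.predict_labels(fit_like), [0, 0])


class TestOracleEquivalence:
    def test_vvv_matches_naive_em_trajectory(self):
        """VVV EM equals an independently coded naive full-covariance EM to
        1e-6 in log-likelihood at every iteration (same data, same init)."""
        rng = np.random.default_rng(5)
        for seed in range(5):
            r = np.random.default_rng(seed)
            X = np.vstack([
                r.normal(0.0, 1.0, (10, 2)),
                r.normal(3.0, 0.8, (10, 2)),
            ])
            z0 = r.dirichlet(np.ones(2), size=20)
            oracle = naive_full_cov_em(X, z0, max_iter=40)
            fit = gpcm.fit_gpcm(X, G=2, model_name="VVV", init=z0,
                                tol=0.0, max_iter=40)
            # the fit may stop one step early once the likelihood is exactly
            # stationary; compare the overlapping trajectory point by point
            L = len(fit.loglik_trace)
            np.testing.assert_allclose(fit.loglik_trace, oracle[:L], atol=1e-6)
            assert L == 40 or oracle[L:].max() - oracle[L - 1] < 1e-9


class TestEMProperties:
    @pytest.mark.parametrize("model", gpcm.MODEL_NAMES)
    def test_loglik_nondecreasing(self, model):
        for seed in range(5):
            rng = np.random.default_rng(seed)
            X, _ = sample_mixture(rng, 20, [[0] * 4, [3] * 4, [-3, 3, -3, 3]],
                                  cov_scale=0.5)
            fit = gpcm.fit_gpcm(X, G=3, model_name=model, seed=seed, n_starts=2)
            d = np.diff(fit.loglik_trace)
            assert np.all(d >= -1e-8 * np.maximum(1.0, np.abs(fit.loglik_trace[:-1])))

    def test_responsibilities_rows_sum_to_one(self):
        rng = np.random.default_rng(6)
        X, _ = sample_mixture(rng, 25, [[0] * 4, [4] * 4])
        fit = gpcm.fit_gpcm(X, G=2, model_name="VVI", seed=0, n_starts=2)
        np.testing.assert_allclose(fit.responsibilities.sum(axis=1), 1.0, atol=1e-10)

    def test_shape_matrices_have_unit_determinant(self):
        rng = np.random.default_rng(7)
        X, _ = sample_mixture(rng, 30, [[0] * 4, [4] * 4], cov_scale=0.3)
        for model in gpcm.MODEL_NAMES:
            fit = gpcm.fit_gpcm(X, G=2, model_name=model, seed=0, n_starts=2)
            dets = np.prod(fit.shapes, axis=1)
            np.testing.assert_allclose(dets, 1.0, atol=1e-8)
            # decomposition reconstructs the covariance
            for g in range(2):
                rec = fit.volumes[g] * (fit.orientations[g] * fit.shapes[g]) @ fit.orientations[g].T
                np.testing.assert_allclose(rec, fit.covariances[g], atol=1e-8)

    def test_translation_equivariance(self):
        rng = np.random.default_rng(8)
        X, _ = sample_mixture(rng, 20, [[0] * 4, [4] * 4], cov_scale=0.2)
        shift = np.array([10.0, -5.0, 2.0, 0.5])
        fit0 = gpcm.fit_gpcm(X, G=2, model_name="EEE", seed=3, n_starts=2)
        fit1 = gpcm.fit_gpcm(X + shift, G=2, model_name="EEE", seed=3, n_starts=2)
        order0 = np.argsort(fit0.means[:, 0])
        order1 = np.argsort(fit1.means[:, 0])
        np.testing.assert_allclose(fit1.means[order1], fit0.means[order0] + shift, atol=1e-6)
        np.testing.assert_allclose(fit1.covariances[order1], fit0.covariances[order0], atol=1e-6)

    def test_spherical_rotation_equivariance(self):
        rng = np.random.default_rng(9)
        X, _ = sample_mixture(rng, 20, [[0, 0], [4, 4]], cov_scale=0.2)
        theta = 0.7
        R = np.array([[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]])
        for model in ("EII", "VII"):
            fit0 = gpcm.fit_gpcm(X, G=2, model_name=model, seed=3, n_starts=2)
            fit1 = gpcm.fit_gpcm(X @ R.T, G=2, model_name=model, seed=3, n_starts=2)
            assert fit1.log_likelihood == pytest.approx(fit0.log_likelihood, abs=1e-6)


class TestBICAndSelection:
    def test_parameter_counting(self):
        assert gpcm.n_free_params("EII", G=2, p=2) == 1 + 4 + 1
        assert gpcm.n_free_params("VVV", G=1, p=4) == 0 + 4 + 10
        assert gpcm.n_free_params("VVI", G=3, p=4) == 2 + 12 + 12
        assert gpcm.n_free_params("EEE", G=2, p=4) == 1 + 8 + 10

    def test_bic_formula_and_penalty_monotonicity(self):
        rng = np.random.default_rng(10)
        X = rng.normal(size=(30, 2))
        fit = gpcm.fit_gpcm(X, G=1, model_name="EII")
        assert gpcm.bic_of(fit, 30) == pytest.approx(
            2 * fit.log_likelihood - fit.n_params * np.log(30))
        with pytest.raises(ValueError):
            gpcm.bic_of(fit, 0)
        # equal loglik, more params -> smaller BIC
        fit_vvv = gpcm.fit_gpcm(X, G=1, model_name="VVV")
        assert fit_vvv.log_likelihood >= fit.log_likelihood
        m_e, m_v = fit.n_params, fit_vvv.n_params
        assert m_v > m_e
        assert 2 * 0.0 - m_v * np.log(30) < 2 * 0.0 - m_e * np.log(30)

    def test_infeasible_cells_flagged(self):
        rng = np.random.default_rng(11)
        X = rng.normal(size=(8, 4))
        fit, grid = gpcm.select_model(X, G_range=[1, 2], model_set=("EII",), seed=0,
                                      n_starts=2)
        assert grid.loc[grid["G"] == 2, "status"].item() == "unfitted"
        assert fit.G == 1

    def test_singleton_grid(self):
        rng = np.random.default_rng(12)
        X = rng.normal(size=(30, 4))
        fit, grid = gpcm.select_model(X, G_range=[1], model_set=("VVI",), seed=0)
        assert len(grid) == 1 and fit.G == 1 and fit.model_name == "VVI"

    def test_selects_true_G_on_separated_data(self):
        hits = 0
        for seed in range(10):
            rng = np.random.default_rng(100 + seed)
            X, truth = sample_mixture(rng, 100, [[0] * 4, [5] * 4, [0, 5, 0, 5]],
                                      cov_scale=1.0)
            fit, _ = gpcm.select_model(X, G_range=range(1, 6), model_set=("EII",),
                                       seed=seed, n_starts=3)
            if fit.G == 3 and adjusted_rand_score(truth, gpcm.predict_labels(fit)) >= 0.95:
                hits += 1
        assert hits >= 9
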