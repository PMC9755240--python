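"""EM mixture fitting and cross-validated model-selection behaviour."""

import numpy as np
import pytest
from scipy import stats

from morphohet.gaussian import fit_gaussian, loglik_data
from morphohet.mixture import (
    _e_step,
    em_fit_gmm,
    gmm_loglik_data,
    gmm_loglik_point,
    loo_compare,
)


def _two_cluster(rng, n=200, sep=5.0, d=1):
    half = n // 2
    a = rng.normal(size=(half, d)) - sep / 2
    b = rng.normal(size=(n - half, d)) + sep / 2
    return np.concatenate([a, b])


class TestEStep:
    def test_responsibility_rows_normalize(self, rng):
        for _ in range(25):
            d = int(rng.integers(1, 4))
            X = rng.normal(size=(30, d))
            mus = [rng.normal(size=d), rng.normal(size=d)]
            sigmas = [np.eye(d) * float(rng.uniform(0.5, 2.0)) for _ in range(2)]
            gamma, ll = _e_step(X, np.array([0.3, 0.7]), mus, sigmas)
            assert np.allclose(gamma.sum(axis=1), 1.0, atol=1e-12)
            assert np.isfinite(ll)


class TestEMFit:
    def test_loglik_trace_nondecreasing(self, rng):
        for _ in range(20):
            d = int(rng.integers(1, 4))
            X = rng.normal(size=(40, d)) + rng.choice([-2.0, 2.0], size=(40, 1))
            fit = em_fit_gmm(X, K=2, seed=rng, n_restarts=2)
            assert np.all(np.diff(fit.ll_trace) >= -1e-8)

    def test_mixing_weights_on_simplex(self, rng):
        fit = em_fit_gmm(_two_cluster(rng), K=2, seed=0, n_restarts=3)
        assert np.all(fit.pi >= 0)
        assert fit.pi.sum() == pytest.approx(1.0, abs=1e-12)

    def test_in_sample_nesting_vs_single_gaussian(self, rng):
        for _ in range(10):
            X = rng.normal(size=(35, 2))
            gmm = em_fit_gmm(X, K=2, seed=rng, n_restarts=3)
            single = fit_gaussian(X)
            assert gmm_loglik_data(X, gmm) >= loglik_data(X, single) - 1e-8

    def test_parameter_recovery_well_separated(self, rng):
        X = _two_cluster(rng, n=500, sep=10.0)
        fit = em_fit_gmm(X, K=2, seed=1, n_restarts=5)
        means = sorted(c.mu[0] for c in fit.components)
        assert abs(means[0] + 5.0) < 0.3 and abs(means[1] - 5.0) < 0.3
        assert np.all(np.abs(fit.pi - 0.5) < 0.1)

    def test_agrees_with_sklearn_on_separated_data(self, rng):
        sklearn = pytest.importorskip("sklearn.mixture")
        X = _two_cluster(rng, n=300, sep=8.0)
        ours = em_fit_gmm(X, K=2, seed=0, n_restarts=5)
        ref = sklearn.GaussianMixture(2, covariance_type="full", n_init=5,
                                      random_state=0).fit(X)
        assert np.allclose(sorted(c.mu[0] for c in ours.components),
                           sorted(ref.means_.ravel()), atol=0.2)
        # average per-point log-likelihoods agree at the optimum
        assert gmm_loglik_data(X, ours) / len(X) == pytest.approx(
            ref.score(X), abs=1e-3
        )

    def test_too_few_samples_rejected(self, rng):
        from morphohet.gaussian import DegenerateFitError

        with pytest.raises(DegenerateFitError):
            em_fit_gmm(rng.normal(size=3), K=2)


class TestGMMLoglik:
    def test_k1_reduces_to_gaussian(self, rng):
        X = rng.normal(size=(30, 2))
        fit = em_fit_gmm(X, K=1)
        single = fit_gaussian(X)
        z = rng.normal(size=2)
        from morphohet.gaussian import loglik_point

        assert gmm_loglik_point(z, fit) == pytest.approx(loglik_point(z, single), abs=1e-12)

    def test_identical_components_collapse(self, rng):
        from morphohet.gaussian import GaussianFit, loglik_point
        from morphohet.mixture import GMMFit

        comp = GaussianFit(np.array([1.0]), np.array([[2.0]]), 10, 1)
        for pi0 in (0.1, 0.5, 0.9):
            fit = GMMFit(K=2, pi=np.array([pi0, 1 - pi0]),
                         components=[comp, comp], loglik=0.0,
                         ll_trace=np.zeros(1), n_iter=0, converged=True,
                         n_restarts_used=1)
            z = np.array([0.3])
            assert gmm_loglik_point(z, fit) == pytest.approx(
                loglik_point(z, comp), abs=1e-12
            )

    def test_matches_direct_density_sum_oracle(self, rng):
        for _ in range(50):
            d = int(rng.integers(1, 4))
            X = rng.normal(size=(6 * (d + 1), d)) * 2
            fit = em_fit_gmm(X, K=2, seed=rng, n_restarts=2)
            z = rng.normal(size=d)
            direct = np.log(sum(
                fit.pi[k] * stats.multivariate_normal(
                    mean=c.mu, cov=c.sigma).pdf(z)
                for k, c in enumerate(fit.components)
            ))
            assert gmm_loglik_point(z, fit) == pytest.approx(direct, abs=1e-10)


class TestLOOCompare:
    def test_fold_contract(self, rng):
        X = rng.normal(size=20)
        res = loo_compare(X, seed=0, n_restarts=2)
        assert res.n_folds == 20
        assert res.n_failed == 0
        assert not res.inconclusive

    def test_ties_prefer_single_gaussian(self):
        from morphohet.mixture import ModelComparison

        res = ModelComparison(ll_gaussian_cv=-10.0, ll_gmm_cv=-10.0,
                              preferred="gmm" if -10.0 > -10.0 else "gaussian",
                              n_folds=10, n_failed=0, inconclusive=False)
        assert res.preferred == "gaussian"

    def test_unimodal_prefers_gaussian(self, rng):
        prefers = [
            loo_compare(rng.normal(size=34), seed=i, n_restarts=3).preferred
            for i in range(10)
        ]
        assert prefers.count("gaussian") >= 9

    def test_separated_mixture_prefers_gmm(self, rng):
        prefers = [
            loo_compare(_two_cluster(rng, n=34, sep=10.0), seed=i, n_restarts=3).preferred
            for i in range(10)
        ]
        assert prefers.count("gmm") >= 9

    def test_minimum_sample_size(self, rng):
        with pytest.raises(ValueError, match="at least 8"):
            loo_compare(rng.normal(size=5))
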