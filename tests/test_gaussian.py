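"""Gaussian estimator, log-likelihood and conformity-score contracts."""

import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy import stats

from morphohet import registry
from morphohet.gaussian import (
    DegenerateFitError,
    GaussianFit,
    conformity_scores,
    fit_gaussian,
    loglik_data,
    loglik_point,
    loglik_points,
)


class TestFitGaussian:
    def test_hand_computed_1d(self):
        fit = fit_gaussian(np.array([0.0, 2.0]))
        assert fit.mu[0] == 1.0
        assert fit.sigma[0, 0] == 1.0  # ML: divide by S=2
        assert fit.S == 2 and fit.d == 1

    def test_ddof_switch(self):
        fit = fit_gaussian(np.array([0.0, 2.0]), ddof=1)
        assert fit.sigma[0, 0] == 2.0

    def test_monte_carlo_covariance_recovery(self, rng):
        mu0 = np.array([1.0, -2.0, 0.5])
        A = rng.normal(size=(3, 3))
        sigma0 = A @ A.T + np.eye(3)
        n = 100_000
        X = rng.multivariate_normal(mu0, sigma0, size=n)
        fit = fit_gaussian(X)
        se = np.sqrt((np.outer(np.diag(sigma0), np.diag(sigma0)) + sigma0**2) / n)
        assert np.all(np.abs(fit.sigma - sigma0) < 4 * se)
        assert np.all(np.abs(fit.mu - mu0) < 4 * np.sqrt(np.diag(sigma0) / n))

    def test_degenerate_inputs_rejected(self, rng):
        with pytest.raises(DegenerateFitError, match="samples"):
            fit_gaussian(rng.normal(size=(3, 3)))
        X = rng.normal(size=(10, 3))
        X[:, 1] = 7.0
        with pytest.raises(DegenerateFitError, match="zero-variance"):
            fit_gaussian(X)

    def test_ml_estimate_maximizes_loglik(self, rng):
        X = rng.normal(size=(50, 3))
        fit = fit_gaussian(X)
        best = loglik_data(X, fit)
        for _ in range(20):
            mu_p = fit.mu + rng.normal(scale=0.1, size=3)
            sig_p = fit.sigma + np.diag(np.abs(rng.normal(scale=0.1, size=3)))
            assert loglik_data(X, GaussianFit(mu_p, sig_p, fit.S, 3)) <= best


class TestLoglik:
    def test_closed_forms(self):
        f1 = GaussianFit(np.zeros(1), np.eye(1), 10, 1)
        assert loglik_point(np.zeros(1), f1) == pytest.approx(-0.5 * np.log(2 * np.pi), abs=1e-12)
        f3 = GaussianFit(np.zeros(3), np.eye(3), 10, 3)
        assert loglik_point(np.zeros(3), f3) == pytest.approx(-1.5 * np.log(2 * np.pi), abs=1e-12)

    def test_matches_independent_density_oracle(self, rng):
        for _ in range(100):
            d = rng.integers(1, 5)
            A = rng.normal(size=(d, d))
            sigma = A @ A.T + 0.5 * np.eye(d)
            mu = rng.normal(size=d)
            z = rng.normal(size=d)
            fit = GaussianFit(mu, sigma, 10, int(d))
            oracle = stats.multivariate_normal(mean=mu, cov=sigma).logpdf(z)
            assert loglik_point(z, fit) == pytest.approx(oracle, abs=1e-10)

    def test_dataset_loglik_is_sum_of_points(self, rng):
        X = rng.normal(size=(20, 2))
        fit = fit_gaussian(X)
        total = sum(loglik_point(x, fit) for x in X)
        assert loglik_data(X, fit) == pytest.approx(total, rel=1e-12)

    def test_dimension_mismatch(self):
        fit = GaussianFit(np.zeros(3), np.eye(3), 10, 3)
        with pytest.raises(ValueError, match="dimension"):
            loglik_point(np.zeros(2), fit)

    @given(st.floats(-5, 5), st.floats(0.1, 4.0))
    def test_univariate_reduces_to_scalar_normal(self, x, sd):
        fit = GaussianFit(np.zeros(1), np.array([[sd**2]]), 10, 1)
        assert loglik_point(np.array([x]), fit) == pytest.approx(
            stats.norm(0, sd).logpdf(x), abs=1e-10
        )


class TestConformity:
    def _residuals(self, rng, regions, n=20):
        cols = registry.region_feature_columns(regions)
        import pandas as pd

        df = pd.DataFrame(rng.normal(size=(n, len(cols))), columns=cols)
        df.insert(0, "subject_id", [f"ET{i:03d}" for i in range(n)])
        return df

    def test_scores_match_rowwise_loglik(self, rng, small_design):
        regions = small_design.regions
        resid = self._residuals(rng, regions)
        scores, flagged = conformity_scores(resid, regions)
        assert flagged == []
        for region in regions:
            X = resid[registry.feature_columns(region)].to_numpy()
            fit = fit_gaussian(X)
            expect = loglik_points(X, fit)
            assert np.allclose(scores[region.name].to_numpy(), expect)

    def test_mean_subject_scores_highest(self, rng, small_design):
        regions = small_design.regions
        resid = self._residuals(rng, regions, n=21)
        region = regions[0]
        cols = registry.feature_columns(region)
        X = resid[cols].to_numpy()
        # move subject 0 exactly onto the sample mean of the others; after
        # refitting, its score must be the maximum achievable for the fit
        X[0] = X.mean(axis=0)
        resid[cols] = X
        scores, _ = conformity_scores(resid, regions)
        fit = fit_gaussian(resid[cols].to_numpy())
        at_mu = loglik_point(fit.mu, fit)
        assert scores[region.name].max() <= at_mu + 1e-12

    def test_equal_mahalanobis_equal_score(self):
        fit = GaussianFit(np.zeros(2), np.diag([1.0, 4.0]), 10, 2)
        a = loglik_point(np.array([1.0, 0.0]), fit)
        b = loglik_point(np.array([-1.0, 0.0]), fit)
        c = loglik_point(np.array([0.0, 2.0]), fit)  # same quadratic form
        assert a == pytest.approx(b, abs=1e-12)
        assert a == pytest.approx(c, abs=1e-12)

    def test_score_decreases_with_distance(self):
        fit = GaussianFit(np.zeros(1), np.eye(1), 10, 1)
        ds = [loglik_point(np.array([x]), fit) for x in (0.0, 0.5, 1.0, 2.0, 4.0)]
        assert all(np.diff(ds) < 0)

    def test_degenerate_region_flagged(self, rng, small_design):
        regions = small_design.regions
        resid = self._residuals(rng, regions)
        resid["Left-Thalamus_vol"] = 1.0  # constant => degenerate fit
        scores, flagged = conformity_scores(resid, regions)
        assert flagged == ["Left-Thalamus"]
        assert scores["Left-Thalamus"].isna().all()
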