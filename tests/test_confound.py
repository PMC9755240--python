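"""Confound-model fitting and marginal-residual contracts."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

from morphohet import registry, synthetic
from morphohet.confound import (
    FIXED_EFFECT_NAMES,
    extract_marginal_residuals,
    fit_confound_model,
    regress_all,
)
from morphohet.synthetic import CohortDesign, CovariateModel, PlantedEffect


def _design_with_betas(beta_vol, n_hc=26, n_et=34, sigma_b_frac=0.1,
                       sigma_frac=0.25, second=True, **kw):
    cov = CovariateModel.null(sigma_b_frac=sigma_b_frac, sigma_frac=sigma_frac)
    cov.beta_by_feature["vol"] = np.asarray(beta_vol, dtype=float)
    return CohortDesign(
        n_hc=n_hc, n_et=n_et, include_second_timepoint=second,
        regions=synthetic._subset_registry(["Left-Thalamus"]),
        covariates=cov, **kw,
    )


def _cohort_vectors(design, seed=0):
    morpho, cov, _ = synthetic.generate_cohort(design, seed=seed)
    return morpho["Left-Thalamus_vol"].to_numpy(), cov


BETA_TRUE = np.array([100.0, 5.0, 80.0, 2e-3, 1.0, -1.0, 30.0, -30.0, 5e-4, -5e-4])


class TestFit:
    def test_known_coefficients_recovered_within_4se(self):
        design = _design_with_betas(BETA_TRUE)
        y, cov = _cohort_vectors(design, seed=4)
        fit = fit_confound_model(y, cov)
        assert fit.converged
        assert fit.method == "mixed-ml"
        # the generator's group draw adds its mean to the intercept
        mu0 = design.base_params["Left-Thalamus"][0][0]
        target = BETA_TRUE.copy()
        target[0] += mu0
        assert np.all(np.abs(fit.beta - target) < 4 * fit.beta_se)

    def test_null_coefficients_within_4se_of_zero(self):
        design = _design_with_betas(np.zeros(10))
        y, cov = _cohort_vectors(design, seed=5)
        fit = fit_confound_model(y, cov)
        assert np.all(np.abs(fit.beta[1:]) < 4 * fit.beta_se[1:])

    def test_variance_components_recovered(self):
        design = _design_with_betas(np.zeros(10), sigma_b_frac=0.5, sigma_frac=0.25)
        y, cov = _cohort_vectors(design, seed=6)
        fit = fit_confound_model(y, cov)
        # subject-level SD = sqrt(sigma_b^2 + group-draw variance)
        scale = synthetic._FEATURE_SCALE["vol"]
        sd_subject = np.hypot(0.5 * scale, scale)
        sd_noise = 0.25 * scale
        n_subj = design.n_hc + design.n_et
        assert abs(fit.sigma_b - sd_subject) < 4 * sd_subject / np.sqrt(2 * (n_subj - 1))
        n_obs = design.n_hc + 2 * design.n_et
        assert abs(fit.sigma - sd_noise) < 4 * sd_noise / np.sqrt(2 * (n_obs - n_subj))

    def test_single_timepoint_reduces_to_ols(self):
        design = _design_with_betas(BETA_TRUE, second=False, sigma_b_frac=0.0)
        y, cov = _cohort_vectors(design, seed=7)
        with pytest.warns(UserWarning, match="sigma_b"):
            fit = fit_confound_model(y, cov)
        assert fit.method == "ols"
        assert fit.sigma_b == 0.0
        # oracle equivalence with a direct least-squares fit (covariates
        # grand-mean centred, as in the model definition)
        A = cov["age"].to_numpy() - cov["age"].mean()
        G = cov["gender"].to_numpy() - cov["gender"].mean()
        V = cov["total_gm_volume"].to_numpy() - cov["total_gm_volume"].mean()
        ipre = (cov["group"] == "ET_pre").to_numpy().astype(float)
        X = np.column_stack([np.ones(len(cov)), A, G, V, ipre * A, ipre * G, ipre * V])
        ref = sm.OLS(y, X).fit().params
        active = [0, 1, 2, 3, 4, 6, 8]  # ET_post terms dropped (level absent)
        assert np.allclose(fit.beta[active], ref, atol=1e-8)
        assert set(fit.dropped_terms) == {
            "ET_post:age", "ET_post:gender", "ET_post:total_gm_volume"}

    def test_rank_deficiency_names_columns(self):
        design = _design_with_betas(np.zeros(10), second=False, sigma_b_frac=0.0)
        y, cov = _cohort_vectors(design, seed=8)
        cov = cov.copy()
        cov["total_gm_volume"] = cov["age"]  # perfectly collinear
        with pytest.raises(ValueError, match="total_gm_volume"):
            fit_confound_model(y, cov)


class TestResiduals:
    def test_zero_slope_fit_residuals_are_centred_values(self):
        design = _design_with_betas(np.zeros(10), second=False, sigma_b_frac=0.0)
        y, cov = _cohort_vectors(design, seed=9)
        with pytest.warns(UserWarning):
            fit = fit_confound_model(y, cov)
        fit.beta[1:] = 0.0  # force a pure-intercept fit
        resid = extract_marginal_residuals(fit, y, cov)
        assert np.allclose(resid, y - fit.beta[0])

    def test_age_confound_removed(self):
        beta = np.zeros(10)
        beta[1] = 10.0  # strong age slope
        design = _design_with_betas(beta, n_hc=2500, n_et=2500, second=False,
                                    sigma_b_frac=0.0)
        y, cov = _cohort_vectors(design, seed=10)
        with pytest.warns(UserWarning):
            fit = fit_confound_model(y, cov)
        resid = extract_marginal_residuals(fit, y, cov)
        assert abs(np.corrcoef(resid, cov["age"])[0, 1]) < 0.05

    def test_group_mean_difference_preserved(self):
        scale = synthetic._FEATURE_SCALE["vol"]
        delta = scale  # HC - ET mean shift of one feature SD
        design = _design_with_betas(
            np.zeros(10), n_hc=400, n_et=400, second=False, sigma_b_frac=0.0,
            planted_effects=[PlantedEffect("Left-Thalamus", "mean_0", delta)],
        )
        y, cov = _cohort_vectors(design, seed=11)
        with pytest.warns(UserWarning):
            fit = fit_confound_model(y, cov)
        resid = extract_marginal_residuals(fit, y, cov)
        hc = resid[(cov["group"] == "HC").to_numpy()]
        et = resid[(cov["group"] == "ET_pre").to_numpy()]
        se = np.sqrt(hc.var() / len(hc) + et.var() / len(et))
        assert abs((hc.mean() - et.mean()) - delta) < 4 * se

    def test_affine_shift_of_covariate_leaves_residuals_invariant(self):
        design = _design_with_betas(BETA_TRUE, second=False, sigma_b_frac=0.0)
        y, cov = _cohort_vectors(design, seed=12)
        with pytest.warns(UserWarning):
            fit1 = fit_confound_model(y, cov)
        shifted = cov.copy()
        shifted["age"] = shifted["age"] + 25.0
        with pytest.warns(UserWarning):
            fit2 = fit_confound_model(y, shifted)
        r1 = extract_marginal_residuals(fit1, y, cov)
        r2 = extract_marginal_residuals(fit2, y, shifted)
        assert np.allclose(r1, r2, atol=1e-6)


class TestRegressAll:
    def test_all_region_features_fit_once(self, small_cohort, small_design):
        morpho, cov, _ = small_cohort
        resid, summary, flagged = regress_all(morpho, cov, small_design.regions)
        assert flagged == []
        assert len(summary) == 4  # 3 cortical features + 1 volume
        assert resid.shape == morpho.shape
        assert not resid.drop(columns=["subject_id", "group"]).isna().any().any()

    def test_deterministic(self, small_cohort, small_design):
        morpho, cov, _ = small_cohort
        r1, _, _ = regress_all(morpho, cov, small_design.regions)
        r2, _, _ = regress_all(morpho, cov, small_design.regions)
        pd.testing.assert_frame_equal(r1, r2)

    def test_missing_covariate_row_rejected(self, small_cohort, small_design):
        morpho, cov, _ = small_cohort
        with pytest.raises(ValueError, match="missing"):
            regress_all(morpho, cov.iloc[1:], small_design.regions)

    def test_full_registry_fit_count(self):
        design = synthetic.null_design(n_hc=8, n_et=10, seed=3)
        morpho, cov, _ = synthetic.generate_cohort(design)
        resid, summary, flagged = regress_all(morpho, cov, design.regions)
        assert len(summary) == 3 * 68 + 19  # one fit per region-feature
        assert flagged == []
        assert summary["converged"].all()
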