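"""Mixed-effects confound regression for regional morphometry.

Each region-feature is modelled independently as

    M = b0 + b1*age + b2*gender + b3*gmv
        + group-specific age/gender/gmv interactions (b4..b9)
        + subject random intercept (SD sigma_b) + noise (SD sigma),

with the three-level group factor (HC reference; patients at baseline and
at the second timepoint) entering only through interactions with the
three covariates -- group main effects are deliberately absent, so group
differences survive in the residuals.  Estimation is by maximum
likelihood (REML available via ``reml=True``).  The residuals handed to
the downstream analyses are *marginal*: only the fitted fixed-covariate
part is subtracted, so subject random intercepts and any group structure
remain in them.

When every subject contributes a single observation the random intercept
is unidentifiable; sigma_b is then fixed at zero and the fit reduces
exactly to ordinary least squares.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .registry import RegionRecord, feature_columns

__all__ = [
    "MixedModelFit",
    "fit_confound_model",
    "extract_marginal_residuals",
    "regress_all",
    "FIXED_EFFECT_NAMES",
]

FIXED_EFFECT_NAMES = (
    "intercept", "age", "gender", "total_gm_volume",
    "ET_pre:age", "ET_post:age",
    "ET_pre:gender", "ET_post:gender",
    "ET_pre:total_gm_volume", "ET_post:total_gm_volume",
)


@dataclasses.dataclass
class MixedModelFit:
    """Fitted confound model for one region-feature."""

    beta: np.ndarray  # always 10 coefficients, absent-level terms zero
    beta_names: tuple[str, ...]
    sigma_b: float
    sigma: float
    converged: bool
    loglik: float
    method: str  # "mixed-ml", "mixed-reml" or "ols"
    dropped_terms: tuple[str, ...] = ()
    beta_se: np.ndarray | None = None  # same layout as beta; NaN for dropped terms


def _design_matrix(covariates: pd.DataFrame) -> tuple[np.ndarray, list[str], list[str]]:
    """Build the 10-column fixed-effect design; drop all-zero interaction
    columns for group levels absent from the data (recorded as dropped).

    Covariates are grand-mean centred before the interaction columns are
    formed.  With interaction-only group coding this is essential: an
    uncentred group-by-age column contains a constant group offset, so the
    fit would silently absorb group mean differences that are supposed to
    survive in the residuals.
    """
    A = covariates["age"].to_numpy(float)
    G = covariates["gender"].to_numpy(float)
    V = covariates["total_gm_volume"].to_numpy(float)
    A = A - A.mean()
    G = G - G.mean()
    V = V - V.mean()
    i_pre = (covariates["group"] == "ET_pre").to_numpy().astype(float)
    i_post = (covariates["group"] == "ET_post").to_numpy().astype(float)
    cols = [np.ones(len(covariates)), A, G, V,
            i_pre * A, i_post * A, i_pre * G, i_post * G, i_pre * V, i_post * V]
    X = np.column_stack(cols)
    active = [i for i in range(10) if i < 4 or np.any(X[:, i] != 0)]
    dropped = [FIXED_EFFECT_NAMES[i] for i in range(10) if i not in active]
    Xa = X[:, active]
    rank = np.linalg.matrix_rank(Xa)
    if rank < Xa.shape[1]:
        # name the collinear columns by greedy QR elimination
        keep: list[int] = []
        collinear: list[str] = []
        for j in range(Xa.shape[1]):
            trial = keep + [j]
            if np.linalg.matrix_rank(Xa[:, trial]) == len(trial):
                keep.append(j)
            else:
                collinear.append(FIXED_EFFECT_NAMES[active[j]])
        raise ValueError(f"rank-deficient fixed-effect design; collinear columns: {collinear}")
    names = [FIXED_EFFECT_NAMES[i] for i in active]
    return Xa, names, dropped


def fit_confound_model(
    values: np.ndarray,
    covariates: pd.DataFrame,
    reml: bool = False,
) -> MixedModelFit:
    """Fit the confound model for one region-feature.

    ``values`` is the per-observation feature vector aligned row-for-row
    with ``covariates`` (columns ``subject_id``, ``group``, ``age``,
    ``gender``, ``total_gm_volume``).  Maximum-likelihood by default.
    """
    values = np.asarray(values, dtype=float)
    if values.shape[0] != len(covariates):
        raise ValueError("values and covariates must align row-for-row")
    X, names, dropped = _design_matrix(covariates)
    subjects = covariates["subject_id"].astype(str).to_numpy()
    counts = pd.Series(subjects).value_counts()
    single_obs_everywhere = bool((counts == 1).all())

    if single_obs_everywhere:
        warnings.warn(
            "one observation per subject everywhere: sigma_b is unidentifiable "
            "and fixed to 0 (ordinary least squares fit)",
            stacklevel=2,
        )
        ols = sm.OLS(values, X).fit()
        beta_active = ols.params
        se_active = np.asarray(ols.bse)
        sigma = float(np.sqrt(np.sum(ols.resid**2) / len(values)))  # ML variance
        fit = MixedModelFit(
            beta=np.zeros(10), beta_names=FIXED_EFFECT_NAMES, sigma_b=0.0,
            sigma=sigma, converged=True, loglik=float(ols.llf), method="ols",
            dropped_terms=tuple(dropped),
        )
    else:
        model = sm.MixedLM(values, X, groups=subjects)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = model.fit(reml=reml, method=["lbfgs", "powell"])
        beta_active = np.asarray(res.fe_params)
        se_active = np.asarray(res.bse_fe)
        sigma_b = float(np.sqrt(max(np.asarray(res.cov_re)[0, 0], 0.0)))
        sigma = float(np.sqrt(res.scale))
        fit = MixedModelFit(
            beta=np.zeros(10), beta_names=FIXED_EFFECT_NAMES, sigma_b=sigma_b,
            sigma=sigma, converged=bool(res.converged), loglik=float(res.llf),
            method="mixed-reml" if reml else "mixed-ml",
            dropped_terms=tuple(dropped),
        )
    idx = [FIXED_EFFECT_NAMES.index(n) for n in names]
    fit.beta[idx] = beta_active
    fit.beta_se = np.full(10, np.nan)
    fit.beta_se[idx] = se_active
    return fit


def extract_marginal_residuals(
    fit: MixedModelFit, values: np.ndarray, covariates: pd.DataFrame
) -> np.ndarray:
    """Observed minus fitted fixed-covariate part.

    Subject random intercepts and group mean structure are *not*
    subtracted; they are the signal of the downstream analyses.
    """
    values = np.asarray(values, dtype=float)
    if values.shape[0] != len(covariates):
        raise ValueError("a covariate row is missing for some observation")
    X, names, _ = _design_matrix(covariates)
    idx = [FIXED_EFFECT_NAMES.index(n) for n in names]
    return values - X @ fit.beta[idx]


def regress_all(
    morphometry: pd.DataFrame,
    covariates: pd.DataFrame,
    regions: list[RegionRecord],
    reml: bool = False,
) -> tuple[pd.DataFrame, pd.DataFrame, list[str]]:
    """Fit the confound model independently for every region-feature.

    Returns the residual table (same shape as the morphometry table), a
    per-fit summary frame, and the list of region-feature columns whose
    fit failed or did not converge (their residuals are NaN; the run
    continues).
    """
    cov = covariates.set_index(["subject_id", "group"])
    key = pd.MultiIndex.from_frame(morphometry[["subject_id", "group"]])
    missing = [k for k in key if k not in cov.index]
    if missing:
        raise ValueError(f"covariate rows missing for observations: {missing[:5]}")
    cov_aligned = cov.loc[key].reset_index()

    resid_cols: dict[str, np.ndarray] = {}
    rows = []
    flagged: list[str] = []
    for region in regions:
        for col in feature_columns(region):
            y = morphometry[col].to_numpy(float)
            try:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    fit = fit_confound_model(y, cov_aligned, reml=reml)
                resid = extract_marginal_residuals(fit, y, cov_aligned)
                if not fit.converged:
                    flagged.append(col)
            except Exception as exc:  # a single failed fit must not kill the run
                flagged.append(col)
                resid_cols[col] = np.full(len(y), np.nan)
                rows.append({"column": col, "error": str(exc)})
                continue
            resid_cols[col] = resid
            row = {"column": col, "region": region.name,
                   "sigma_b": fit.sigma_b, "sigma": fit.sigma,
                   "converged": fit.converged, "loglik": fit.loglik,
                   "method": fit.method}
            row.update({f"beta_{n}": b for n, b in zip(fit.beta_names, fit.beta)})
            rows.append(row)
    residuals = pd.concat(
        [morphometry[["subject_id", "group"]], pd.DataFrame(resid_cols)], axis=1
    )
    summary = pd.DataFrame(rows)
    return residuals, summary, flagged
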