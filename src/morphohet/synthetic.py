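"""Synthetic cohort generator with the statistical structure the pipeline assumes.

Each generated cohort mimics a two-group morphometry study: healthy
controls (HC) and patients (ET) measured once, with an optional second
patient timepoint.  For every region the morphometric value of subject
``s`` decomposes as

    value = covariate part (beta . [1, A, G, V, group interactions])
            + subject random intercept b_s
            + group-specific multivariate Gaussian (or mixture) draw
            + observation noise,

which is exactly the generative counterpart of the confound model fitted
downstream.  Group differences are planted as deltas on individual
Gaussian parameters (HC minus ET convention), bimodality as a
two-component mixture replacing the patient group's draw in selected
regions, and a brain-behaviour association as a rank-one latent mode
shared between patient morphometry and the clinical scores.

Every quantity a recovery test needs is echoed by :func:`describe_truth`.
"""

from __future__ import annotations

import dataclasses
import re
from typing import Sequence

import numpy as np
import pandas as pd

from .registry import (
    CLINICAL_SCORES,
    CORTICAL_FEATURES,
    NONCORTICAL_FEATURE,
    RegionRecord,
    feature_columns,
    load_region_registry,
    region_feature_columns,
)

__all__ = [
    "PlantedEffect",
    "BimodalSpec",
    "CovariateModel",
    "ClinicalModel",
    "CohortDesign",
    "generate_cohort",
    "describe_truth",
    "null_design",
    "planted_design",
]

_PARAM_RE = re.compile(r"^(mean|var)_(\d)$|^cov_(\d)(\d)$")


@dataclasses.dataclass(frozen=True)
class PlantedEffect:
    """A planted HC-minus-ET difference on one Gaussian parameter.

    ``parameter`` is ``mean_j``, ``var_j`` or ``cov_jk`` (j < k feature
    indices within the region).  The patient-group parameter is set to the
    control value minus ``delta``, so e.g. a planted variance ratio
    ET/HC = 4 corresponds to ``delta = -3 * hc_variance``.
    """

    region: str
    parameter: str
    delta: float

    def indices(self) -> tuple[int, ...]:
        m = _PARAM_RE.match(self.parameter)
        if m is None:
            raise ValueError(f"malformed parameter spec {self.parameter!r}")
        if m.group(1) is not None:
            return (int(m.group(2)),)
        j, k = int(m.group(3)), int(m.group(4))
        if not j < k:
            raise ValueError(f"cov indices must satisfy j<k in {self.parameter!r}")
        return (j, k)


@dataclasses.dataclass(frozen=True)
class BimodalSpec:
    """Replace the patient group's draw in one region by a K-component mixture."""

    region: str
    means: tuple  # K tuples of length d
    covariances: tuple  # K (d, d) nested tuples
    weights: tuple  # K mixing proportions on the simplex


@dataclasses.dataclass
class CovariateModel:
    """Confound structure shared by every region-feature.

    ``beta_by_feature`` maps each feature kind (CT/SA/MC/vol) to the ten
    fixed coefficients (intercept; age; gender; total GM volume; patient
    and second-timepoint interactions with each of the three covariates,
    in that order).  ``sigma_b`` / ``sigma`` are the subject random
    intercept SD and the observation noise SD per feature kind, in the
    feature's own units.
    """

    beta_by_feature: dict
    sigma_b_by_feature: dict
    sigma_by_feature: dict
    age_range: tuple = (49.0, 83.0)
    gm_volume_mean: float = 6.0e5
    gm_volume_sd: float = 5.0e4
    second_timepoint_shift: dict = dataclasses.field(default_factory=dict)

    @staticmethod
    def null(sigma_b_frac: float = 0.0, sigma_frac: float = 0.25) -> "CovariateModel":
        """No covariate effects; SDs expressed as fractions of feature scale."""
        zeros = {f: np.zeros(10) for f in (*CORTICAL_FEATURES, NONCORTICAL_FEATURE)}
        scale = _FEATURE_SCALE
        return CovariateModel(
            beta_by_feature=zeros,
            sigma_b_by_feature={f: sigma_b_frac * scale[f] for f in scale},
            sigma_by_feature={f: sigma_frac * scale[f] for f in scale},
        )


@dataclasses.dataclass
class ClinicalModel:
    """Clinical score marginals plus a planted rank-one covariance mode.

    A standard-normal latent score ``t_s`` per patient loads on the
    morphometry columns through the unit-norm imaging salience ``u_star``
    (scaled by ``mode_strength``, in units of the feature noise) and on
    the clinical scores through the unit-norm ``v_star`` (scaled by
    ``clinical_strength``); independent noise of SD ``noise_sd`` (in
    z-units of each score's marginal SD) completes the scores.
    """

    u_star: np.ndarray | None = None  # aligned to region-feature columns
    v_star: np.ndarray | None = None  # aligned to CLINICAL_SCORES
    mode_strength: float = 0.0
    clinical_strength: float = 1.0
    noise_sd: float = 1.0
    marginal_mean: dict = dataclasses.field(
        default_factory=lambda: {
            "adl": 29.6, "tsth": 20.4, "head_tremor": 1.0,
            "symptoms_duration": 35.5, "family_history": 0.68,
        }
    )
    marginal_sd: dict = dataclasses.field(
        default_factory=lambda: {
            "adl": 11.4, "tsth": 5.5, "head_tremor": 0.85,
            "symptoms_duration": 18.3, "family_history": 0.47,
        }
    )


# Realistic regional scales: CT ~ 2.5 mm, SA ~ 2500 mm^2, MC ~ 0.13 mm^-1,
# subcortical volume ~ 4000 mm^3; SDs roughly 5-20 % of the mean, in line
# with published regional summaries.
_FEATURE_MEAN = {"CT": 2.5, "SA": 2500.0, "MC": 0.13, "vol": 4000.0}
_FEATURE_SCALE = {"CT": 0.15, "SA": 500.0, "MC": 0.01, "vol": 400.0}
_CORTICAL_CORR = np.array(
    [[1.0, 0.3, -0.2], [0.3, 1.0, 0.1], [-0.2, 0.1, 1.0]]
)


def _default_base_params(regions: Sequence[RegionRecord]) -> dict:
    params = {}
    for region in regions:
        feats = region.features
        mu = np.array([_FEATURE_MEAN[f] for f in feats])
        sd = np.array([_FEATURE_SCALE[f] for f in feats])
        if region.kind == "cortical":
            sigma = _CORTICAL_CORR * np.outer(sd, sd)
        else:
            sigma = np.array([[sd[0] ** 2]])
        params[region.name] = (mu, sigma)
    return params


def _check_spd(sigma: np.ndarray, where: str) -> None:
    sigma = np.asarray(sigma, dtype=float)
    if sigma.ndim != 2 or sigma.shape[0] != sigma.shape[1]:
        raise ValueError(f"{where}: covariance must be square")
    if not np.allclose(sigma, sigma.T):
        raise ValueError(f"{where}: covariance must be symmetric")
    try:
        np.linalg.cholesky(sigma)
    except np.linalg.LinAlgError as exc:
        raise ValueError(f"{where}: covariance is not positive definite") from exc


@dataclasses.dataclass
class CohortDesign:
    """Full generative specification of a synthetic cohort."""

    n_hc: int = 29
    n_et: int = 34
    include_second_timepoint: bool = True
    regions: Sequence[RegionRecord] | None = None
    base_params: dict | None = None  # region name -> (mu, sigma) for HC
    planted_effects: Sequence[PlantedEffect] = ()
    bimodal: Sequence[BimodalSpec] = ()
    covariates: CovariateModel | None = None
    clinical: ClinicalModel | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.regions is None:
            self.regions = load_region_registry()
        self.regions = list(self.regions)
        if self.base_params is None:
            self.base_params = _default_base_params(self.regions)
        if self.covariates is None:
            self.covariates = CovariateModel.null()
        if self.clinical is None:
            self.clinical = ClinicalModel()
        self.validate()

    # -- validation ---------------------------------------------------
    def validate(self) -> None:
        names = {r.name for r in self.regions}
        for region in self.regions:
            mu, sigma = self.base_params[region.name]
            if len(np.atleast_1d(mu)) != region.dim:
                raise ValueError(f"{region.name}: mean has wrong dimension")
            _check_spd(np.atleast_2d(sigma), f"base params of {region.name}")
        for eff in self.planted_effects:
            if eff.region not in names:
                raise ValueError(f"planted effect on unknown region {eff.region!r}")
            eff.indices()
            _, sigma_et = self.group_params(eff.region, "ET")
            _check_spd(sigma_et, f"ET params of {eff.region} after planting")
        for spec in self.bimodal:
            if spec.region not in names:
                raise ValueError(f"bimodal spec on unknown region {spec.region!r}")
            w = np.asarray(spec.weights, dtype=float)
            if np.any(w < 0) or not np.isclose(w.sum(), 1.0):
                raise ValueError(f"{spec.region}: mixing weights must lie on the simplex")
            for cov in spec.covariances:
                _check_spd(np.atleast_2d(np.asarray(cov, float)), f"bimodal {spec.region}")
        for f, sb in self.covariates.sigma_b_by_feature.items():
            if sb < 0:
                raise ValueError(f"sigma_b for {f} must be >= 0")
        for f, s in self.covariates.sigma_by_feature.items():
            if s <= 0:
                raise ValueError(f"sigma for {f} must be > 0")

    # -- derived truth ------------------------------------------------
    def group_params(self, region_name: str, group: str) -> tuple[np.ndarray, np.ndarray]:
        """Gaussian (mu, sigma) of the group-specific draw for one region."""
        mu, sigma = self.base_params[region_name]
        mu = np.atleast_1d(np.asarray(mu, float)).copy()
        sigma = np.atleast_2d(np.asarray(sigma, float)).copy()
        if group == "HC":
            return mu, sigma
        for eff in self.planted_effects:
            if eff.region != region_name:
                continue
            idx = eff.indices()
            if eff.parameter.startswith("mean"):
                mu[idx[0]] -= eff.delta
            elif eff.parameter.startswith("var"):
                sigma[idx[0], idx[0]] -= eff.delta
            else:
                j, k = idx
                sigma[j, k] -= eff.delta
                sigma[k, j] -= eff.delta
        return mu, sigma

    def feature_column_names(self) -> list[str]:
        return region_feature_columns(self.regions)


def _unit(v: np.ndarray) -> np.ndarray:
    v = np.asarray(v, dtype=float)
    n = np.linalg.norm(v)
    if n == 0:
        raise ValueError("salience vector must be nonzero")
    return v / n


def describe_truth(design: CohortDesign) -> dict:
    """Machine-readable record of every planted effect in a design."""
    truth: dict = {
        "planted_effects": [
            {"region": e.region, "parameter": e.parameter, "delta": e.delta,
             "indices": list(e.indices())}
            for e in design.planted_effects
        ],
        "bimodal_regions": [spec.region for spec in design.bimodal],
        "pls_mode": None,
    }
    clin = design.clinical
    if clin.mode_strength > 0 and clin.u_star is not None and clin.v_star is not None:
        truth["pls_mode"] = {
            "u_star": _unit(clin.u_star).tolist(),
            "v_star": _unit(clin.v_star).tolist(),
            "mode_strength": clin.mode_strength,
        }
    return truth


def _feature_kinds(regions: Sequence[RegionRecord]) -> list[str]:
    kinds: list[str] = []
    for region in regions:
        kinds.extend(region.features)
    return kinds


def generate_cohort(
    design: CohortDesign, seed: int | None = None
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Draw one cohort from a design; fully reproducible from the seed.

    Returns the morphometry, covariate and clinical tables.  Clinical
    rows exist for patients only.
    """
    rng = np.random.default_rng(design.seed if seed is None else seed)
    cov_model = design.covariates
    regions = design.regions
    columns = design.feature_column_names()
    kinds = _feature_kinds(regions)

    hc_ids = [f"HC{i + 1:03d}" for i in range(design.n_hc)]
    et_ids = [f"ET{i + 1:03d}" for i in range(design.n_et)]

    # subject-level covariates
    age = rng.uniform(*cov_model.age_range, size=design.n_hc + design.n_et)
    gender = np.tile([0.0, 1.0], (design.n_hc + design.n_et + 1) // 2)
    gender = rng.permutation(gender[: design.n_hc + design.n_et])
    gmv = rng.normal(cov_model.gm_volume_mean, cov_model.gm_volume_sd,
                     size=design.n_hc + design.n_et)

    subj_rows = []  # (subject_id, group, age, gender, gmv)
    for i, sid in enumerate(hc_ids):
        subj_rows.append((sid, "HC", age[i], gender[i], gmv[i]))
    for i, sid in enumerate(et_ids):
        j = design.n_hc + i
        subj_rows.append((sid, "ET_pre", age[j], gender[j], gmv[j]))
    if design.include_second_timepoint:
        for i, sid in enumerate(et_ids):
            j = design.n_hc + i
            subj_rows.append((sid, "ET_post", age[j], gender[j], gmv[j]))
    cov_df = pd.DataFrame(
        subj_rows, columns=["subject_id", "group", "age", "gender", "total_gm_volume"]
    )

    n_obs = len(cov_df)
    is_et = cov_df["group"].isin(["ET_pre", "ET_post"]).to_numpy()
    is_post = (cov_df["group"] == "ET_post").to_numpy()
    # covariates enter grand-mean centred, matching the downstream
    # confound model (interaction columns then carry no group offset)
    A = cov_df["age"].to_numpy()
    G = cov_df["gender"].to_numpy()
    V = cov_df["total_gm_volume"].to_numpy()
    A = A - A.mean()
    G = G - G.mean()
    V = V - V.mean()
    # fixed-effect design:
    # [1, A, G, V, I_pre*A, I_post*A, I_pre*G, I_post*G, I_pre*V, I_post*V]
    i_pre = (cov_df["group"] == "ET_pre").to_numpy().astype(float)
    i_post = is_post.astype(float)
    X = np.column_stack(
        [np.ones(n_obs), A, G, V,
         i_pre * A, i_post * A, i_pre * G, i_post * G, i_pre * V, i_post * V]
    )

    # subject random intercepts, shared across timepoints
    subjects = cov_df["subject_id"].to_numpy()
    uniq_subjects = list(dict.fromkeys(subjects))
    b_raw = {f: dict(zip(uniq_subjects,
                         rng.normal(0.0, 1.0, size=len(uniq_subjects))))
             for f in (*CORTICAL_FEATURES, NONCORTICAL_FEATURE)}

    # patient latent score driving the brain-behaviour mode
    t_latent = dict(zip(et_ids, rng.normal(0.0, 1.0, size=design.n_et)))

    clin = design.clinical
    u_star = None
    if clin.mode_strength > 0 and clin.u_star is not None:
        u_star = _unit(clin.u_star)
        if u_star.shape[0] != len(columns):
            raise ValueError("u_star length must match the region-feature columns")

    bimodal_by_region = {spec.region: spec for spec in design.bimodal}
    values = np.empty((n_obs, len(columns)))
    col_offset = 0
    for region in regions:
        d = region.dim
        # group-level structural draw, persistent across timepoints
        mu_hc, sig_hc = design.group_params(region.name, "HC")
        mu_et, sig_et = design.group_params(region.name, "ET")
        draw = np.empty((len(uniq_subjects), d))
        chol_hc = np.linalg.cholesky(sig_hc)
        chol_et = np.linalg.cholesky(sig_et)
        spec = bimodal_by_region.get(region.name)
        if spec is not None:
            w = np.asarray(spec.weights, float)
            comp_means = [np.atleast_1d(np.asarray(m, float)) for m in spec.means]
            comp_chols = [np.linalg.cholesky(np.atleast_2d(np.asarray(c, float)))
                          for c in spec.covariances]
        for si, sid in enumerate(uniq_subjects):
            z = rng.standard_normal(d)
            if sid.startswith("HC"):
                draw[si] = mu_hc + chol_hc @ z
            elif spec is not None:
                k = rng.choice(len(w), p=w)
                draw[si] = comp_means[k] + comp_chols[k] @ z
            else:
                draw[si] = mu_et + chol_et @ z
        draw_by_subject = dict(zip(uniq_subjects, draw))

        for fi, feat in enumerate(region.features):
            ci = col_offset + fi
            beta = np.asarray(cov_model.beta_by_feature[feat], float)
            sigma_b = cov_model.sigma_b_by_feature[feat]
            sigma_e = cov_model.sigma_by_feature[feat]
            shift = cov_model.second_timepoint_shift.get(feat, 0.0)
            col = X @ beta
            col += np.array([draw_by_subject[s][fi] for s in subjects])
            col += sigma_b * np.array([b_raw[feat][s] for s in subjects])
            col += rng.normal(0.0, sigma_e, size=n_obs)
            col += shift * is_post
            if u_star is not None:
                load = u_star[ci] * clin.mode_strength * sigma_e
                col += load * np.array(
                    [t_latent.get(s, 0.0) if et else 0.0
                     for s, et in zip(subjects, is_et)]
                )
            values[:, ci] = col
        col_offset += d

    morpho_df = pd.DataFrame(values, columns=columns)
    morpho_df.insert(0, "group", cov_df["group"])
    morpho_df.insert(0, "subject_id", cov_df["subject_id"])

    # clinical table (patients only)
    v_star = _unit(clin.v_star) if clin.v_star is not None else np.zeros(len(CLINICAL_SCORES))
    clin_rows = []
    for sid in et_ids:
        t = t_latent[sid]
        row = {"subject_id": sid}
        for j, score in enumerate(CLINICAL_SCORES):
            m, s = clin.marginal_mean[score], clin.marginal_sd[score]
            latent = m + s * (clin.clinical_strength * v_star[j] * t
                              + clin.noise_sd * rng.standard_normal())
            if score == "head_tremor":
                latent = float(np.clip(np.rint(latent), 0, 3))
            elif score == "family_history":
                # threshold the latent so the null marginal rate equals
                # the nominal mean of the 0/1 indicator
                from scipy.stats import norm

                cut = m + s * clin.noise_sd * norm.ppf(1.0 - m)
                latent = float(latent > cut)
            elif score in ("adl", "tsth", "symptoms_duration"):
                latent = float(max(latent, 0.0))
            row[score] = latent
        clin_rows.append(row)
    clin_df = pd.DataFrame(clin_rows, columns=["subject_id", *CLINICAL_SCORES])
    return morpho_df, cov_df, clin_df


# ---------------------------------------------------------------------------
# Canned designs


#: Desk-scale region subset used by the packaged planted scenario: four
#: cortical parcels and two subcortical structures.
SCENARIO_REGIONS = (
    "lh_caudalanteriorcingulate",
    "lh_lingual",
    "lh_postcentral",
    "rh_superiortemporal",
    "Left-Thalamus",
    "Right-Putamen",
)


def _subset_registry(names):
    by_name = {r.name: r for r in load_region_registry()}
    return [by_name[n] for n in names]


def null_design(
    n_hc: int = 29,
    n_et: int = 34,
    region_names: Sequence[str] | None = None,
    include_second_timepoint: bool = True,
    sigma_b_frac: float = 0.1,
    sigma_frac: float = 0.25,
    seed: int = 0,
) -> CohortDesign:
    """Cohort with no planted effects: HC and ET draws are exchangeable."""
    regions = _subset_registry(region_names) if region_names is not None else None
    return CohortDesign(
        n_hc=n_hc,
        n_et=n_et,
        include_second_timepoint=include_second_timepoint,
        regions=regions,
        covariates=CovariateModel.null(sigma_b_frac=sigma_b_frac, sigma_frac=sigma_frac),
        seed=seed,
    )


def planted_design(
    n_hc: int = 29,
    n_et: int = 34,
    region_names: Sequence[str] = SCENARIO_REGIONS,
    variance_region: str = "lh_caudalanteriorcingulate",
    variance_feature: int = 1,  # SA
    variance_ratio: float = 16.0,
    bimodal_region: str = "Right-Putamen",
    bimodal_separation_sd: float = 8.0,
    mode_strength: float = 7.0,
    include_second_timepoint: bool = True,
    seed: int = 0,
) -> CohortDesign:
    """The packaged planted scenario: one patient-group variance increase
    (ratio ``variance_ratio`` on one cortical SA), one bimodal subcortical
    volume, and one rank-one brain-behaviour mode.

    Effect sizes are deliberately strong (variance ratio 16, eight
    component-SDs of bimodal separation, a latent mode loading ~0.8 of a
    feature SD per column): at the study's group sizes each planted effect
    is then detected with high probability at its family-wise threshold,
    which is what an end-to-end recovery run must exercise.  The
    bimodality is variance-matched, and the latent-mode loadings are kept
    below the level the variance test can resolve, so each effect lands in
    exactly one effect class.
    """
    regions = _subset_registry(region_names)
    base = _default_base_params(regions)

    hc_var = base[variance_region][1][variance_feature, variance_feature]
    effects = [
        PlantedEffect(
            region=variance_region,
            parameter=f"var_{variance_feature}",
            delta=hc_var * (1.0 - variance_ratio),
        )
    ]

    # Variance-matched bimodality: component SD sigma_c and half-separation h
    # chosen so the mixture's total variance equals the control variance
    # (h = (s/2) * sigma_c with s = bimodal_separation_sd component-SDs of
    # separation, sigma_c^2 + h^2 = sigma_0^2).  The region then differs
    # from controls in shape only, not in any single Gaussian parameter.
    mu0 = float(base[bimodal_region][0][0])
    sd0 = float(np.sqrt(base[bimodal_region][1][0, 0]))
    s = bimodal_separation_sd
    sd_c = sd0 / np.sqrt(1.0 + s**2 / 4.0)
    half = 0.5 * s * sd_c
    bimodal = [
        BimodalSpec(
            region=bimodal_region,
            means=((mu0 - half,), (mu0 + half,)),
            covariances=(((sd_c**2,),), ((sd_c**2,),)),
            weights=(0.5, 0.5),
        )
    ]

    columns = region_feature_columns(regions)
    u = np.zeros(len(columns))
    for i, col in enumerate(columns):
        if col.endswith("_MC"):
            u[i] = -1.0  # broad negative gyrification loading
        elif col.endswith("_CT"):
            u[i] = 0.5
    v = np.array([0.0, 0.7, 0.6, 0.4, 0.0])  # tsth, head tremor, duration
    clinical = ClinicalModel(
        u_star=u,
        v_star=v,
        mode_strength=mode_strength,
        clinical_strength=1.0,
        noise_sd=0.5,
    )
    return CohortDesign(
        n_hc=n_hc,
        n_et=n_et,
        include_second_timepoint=include_second_timepoint,
        regions=regions,
        planted_effects=effects,
        bimodal=bimodal,
        covariates=CovariateModel.null(sigma_b_frac=0.1, sigma_frac=0.25),
        clinical=clinical,
        seed=seed,
    )
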