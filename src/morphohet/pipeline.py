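"""End-to-end orchestration: simulate/ingest -> regress -> compare -> score -> PLS.

A single :class:`RunConfig` drives the full analysis under one master
seed.  Every stochastic stage derives its own stream deterministically
from that seed, so re-running a configuration reproduces every output
file byte for byte.  The run writes per-stage TSV tables plus a summary
JSON listing, per analysis, the regions (and parameters) found
significant.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from . import confound, gaussian, groupdiff, mixture, pls, registry, synthetic

__all__ = ["RunConfig", "validate_inputs", "run_pipeline"]


@dataclasses.dataclass
class RunConfig:
    """Configuration of one pipeline run.

    Either ``design`` (a synthetic cohort specification) or the three
    input table paths must be provided.
    """

    design: synthetic.CohortDesign | None = None
    morphometry_path: str | None = None
    covariates_path: str | None = None
    clinical_path: str | None = None
    n_perm: int = 10_000
    n_boot: int = 10_000
    K: int = 2
    bonferroni_regions: int = groupdiff.DEFAULT_N_REGIONS
    alpha: float = 0.05
    em_opts: dict = dataclasses.field(default_factory=dict)
    pls_frac: float = 0.8
    pls_alpha: float = 0.01
    pls_imaging: Sequence[str] = ("raw", "conformity")
    seed: int = 0
    outdir: str | None = None

    @staticmethod
    def from_yaml(path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "design" in raw and raw["design"] is not None:
            d = raw["design"]
            kind = d.pop("kind", "null")
            factory = {"null": synthetic.null_design, "planted": synthetic.planted_design}
            raw["design"] = factory[kind](**d)
        return RunConfig(**raw)

    def echo(self) -> dict:
        out = dataclasses.asdict(self)
        out.pop("outdir", None)  # keep run outputs location-independent
        if self.design is not None:
            out["design"] = {"regions": [r.name for r in self.design.regions],
                             "n_hc": self.design.n_hc, "n_et": self.design.n_et,
                             "seed": self.design.seed,
                             "truth": synthetic.describe_truth(self.design)}
        return out


def validate_inputs(
    morphometry: pd.DataFrame,
    covariates: pd.DataFrame,
    clinical: pd.DataFrame,
    regions: Sequence[registry.RegionRecord],
) -> list[str]:
    """Cross-check the three tables; return a list of problems (empty = ok)."""
    problems: list[str] = []
    expected = registry.region_feature_columns(regions)
    missing_cols = [c for c in expected if c not in morphometry.columns]
    if missing_cols:
        problems.append(f"morphometry table missing registry columns: {missing_cols}")
    m_keys = set(zip(morphometry["subject_id"], morphometry["group"]))
    c_keys = set(zip(covariates["subject_id"], covariates["group"]))
    for sid, grp in sorted(m_keys - c_keys):
        problems.append(f"subject {sid} ({grp}) present in morphometry but absent in covariates")
    for sid, grp in sorted(c_keys - m_keys):
        problems.append(f"subject {sid} ({grp}) present in covariates but absent in morphometry")
    bad_groups = sorted(set(morphometry["group"]) - set(registry.GROUP_LEVELS))
    if bad_groups:
        problems.append(f"unknown group labels: {bad_groups}")
    patients = {s for s, g in m_keys if g in ("ET_pre", "ET_post")}
    for sid in sorted(set(clinical["subject_id"]) - patients):
        problems.append(f"clinical row for non-patient subject {sid}")
    baseline = {s for s, g in m_keys if g == "ET_pre"}
    for sid in sorted(baseline - set(clinical["subject_id"])):
        problems.append(f"patient {sid} has no clinical row")
    return problems


def _derived_seed(master: int, index: int) -> int:
    return int(
        np.random.SeedSequence(entropy=master, spawn_key=(index,)).generate_state(1)[0]
        % (2**31)
    )


def run_pipeline(config: RunConfig) -> dict:
    """Execute every stage of the analysis and return the summary record.

    Stages: cohort simulation or ingestion, input validation, confound
    regression, per-region Gaussian group comparison with permutation
    significance and Bonferroni correction, Gaussian-vs-mixture selection
    by leave-one-out cross-validation, per-patient conformity scoring,
    and behavioural PLS on raw morphometry and/or conformity scores.
    """
    outdir = Path(config.outdir) if config.outdir else None
    if outdir:
        outdir.mkdir(parents=True, exist_ok=True)

    # --- stage: obtain tables
    if config.design is not None:
        regions = list(config.design.regions)
        morpho, cov, clin = synthetic.generate_cohort(config.design, seed=config.seed)
    elif config.morphometry_path:
        regions = registry.load_region_registry()
        morpho = registry.read_morphometry_table(config.morphometry_path, regions)
        cov = registry.read_covariate_table(config.covariates_path)
        clin = registry.read_clinical_table(config.clinical_path)
    else:
        raise ValueError("config needs either a design or input table paths")

    problems = validate_inputs(morpho, cov, clin, regions)
    if problems:
        raise ValueError("input validation failed: " + "; ".join(problems))

    # --- stage: confound regression
    residuals, fit_summary, flagged = confound.regress_all(morpho, cov, regions)
    resid_hc = residuals[residuals["group"] == "HC"].reset_index(drop=True)
    resid_et = residuals[residuals["group"] == "ET_pre"].reset_index(drop=True)

    # --- stage: group difference
    gd_table, gd_meta = groupdiff.group_difference_all(
        resid_hc, resid_et, regions,
        n_perm=config.n_perm, seed=_derived_seed(config.seed, 1),
        n_regions_correction=config.bonferroni_regions,
    )
    sig = gd_table[gd_table["p_corr"] < config.alpha]
    significant: dict = {"mean": {}, "variance": {}, "covariance": {}}
    for row in sig.itertuples(index=False):
        family = ("mean" if row.parameter.startswith("mean")
                  else "variance" if row.parameter.startswith("var") else "covariance")
        significant[family].setdefault(row.region, []).append(row.parameter)

    # --- stage: model comparison (patient baseline group)
    mc_table = mixture.compare_all(
        resid_et, regions, K=config.K, seed=_derived_seed(config.seed, 2),
        **config.em_opts,
    )
    gmm_preferred = mc_table.loc[
        (mc_table["preferred"] == "gmm") & ~mc_table["inconclusive"], "region"
    ].tolist()

    # --- stage: conformity scores
    conf_scores, conf_flagged = gaussian.conformity_scores(resid_et, regions)

    # --- stage: behavioural PLS
    clin_idx = clin.set_index("subject_id").loc[resid_et["subject_id"].tolist()]
    pls_results: dict = {}
    pls_objects: dict = {}
    for mode_i, setting in enumerate(config.pls_imaging):
        if setting == "raw":
            imaging = resid_et.drop(columns=["subject_id", "group"]).drop(
                columns=flagged, errors="ignore"
            )
            imaging.index = resid_et["subject_id"].tolist()
        elif setting == "conformity":
            imaging = conf_scores.drop(columns=conf_flagged, errors="ignore")
        else:
            raise ValueError(f"unknown PLS imaging setting {setting!r}")
        res = pls.pls_analysis(
            imaging, clin_idx,
            n_perm=config.n_perm, n_boot=config.n_boot,
            frac=config.pls_frac, alpha=config.pls_alpha,
            seed=_derived_seed(config.seed, 10 + mode_i),
        )
        pls_objects[setting] = res
        pls_results[setting] = {
            "mode_pvalues": res.p_modes.tolist(),
            "explained_covariance": res.explained.tolist(),
            "significant_modes": res.significant_modes.tolist(),
            "n_imputed_clinical": res.n_imputed,
        }

    summary = {
        "n_subjects": {"HC": int(len(resid_hc)), "ET": int(len(resid_et))},
        "n_regions": len(regions),
        "flagged_confound_fits": flagged,
        "significant": significant,
        "gmm_preferred_regions": gmm_preferred,
        "inconclusive_regions": mc_table.loc[mc_table["inconclusive"], "region"].tolist(),
        "conformity_flagged_regions": conf_flagged,
        "pls": pls_results,
        "metadata": {
            "seed": config.seed,
            "n_perm": config.n_perm,
            "n_boot": config.n_boot,
            "groupdiff": gd_meta,
            "config": _jsonable(config.echo()),
        },
    }

    if outdir:
        registry.write_table(morpho, outdir / "morphometry.tsv")
        registry.write_table(cov, outdir / "covariates.tsv")
        registry.write_table(clin, outdir / "clinical.tsv")
        registry.write_table(residuals, outdir / "residuals.tsv")
        registry.write_table(fit_summary, outdir / "confound_fits.tsv")
        registry.write_table(gd_table, outdir / "group_difference.tsv")
        registry.write_table(mc_table, outdir / "model_comparison.tsv")
        conf_scores.reset_index().pipe(registry.write_table, outdir / "conformity.tsv")
        for setting, res in pls_objects.items():
            registry.write_table(res.mode_summary(), outdir / f"pls_{setting}_modes.tsv")
            sal = pd.DataFrame(
                {"variable": res.imaging_names,
                 "salience": res.U[:, 0],
                 "ci_low": res.U_ci_low[:, 0], "ci_high": res.U_ci_high[:, 0],
                 "significant": res.U_significant(0)}
            )
            registry.write_table(sal, outdir / f"pls_{setting}_imaging_saliences.tsv")
            salv = pd.DataFrame(
                {"score": res.clinical_names,
                 "salience": res.V[:, 0],
                 "ci_low": res.V_ci_low[:, 0], "ci_high": res.V_ci_high[:, 0],
                 "significant": res.V_significant(0)}
            )
            registry.write_table(salv, outdir / f"pls_{setting}_clinical_saliences.tsv")
        with open(outdir / "summary.json", "w") as fh:
            json.dump(summary, fh, indent=2, sort_keys=True)
    return summary


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer, np.floating)):
        return obj.item()
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return _jsonable(dataclasses.asdict(obj))
    return obj
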