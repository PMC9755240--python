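# morphohet

Probabilistic modelling of heterogeneous regional brain morphometry.

Standard group comparisons of brain morphometry (e.g. a *t*-test per region)
assume unimodal distributions and only detect shifts in the mean. In
disorders with heterogeneous presentation — essential tremor is the
motivating case — patient groups may instead differ in *variance*, in the
*covariance* between morphometric features, or split into *sub-groups*
(multimodal distributions), none of which a mean comparison can see. This
package implements a modelling framework that makes those differences
measurable on regional surface-based morphometry: per-region cortical
thickness (CT, mm), surface area (SA, mm²) and mean curvature (MC, mm⁻¹)
for the 68 cortical parcels of the Desikan-Killiany atlas, plus volumes
(mm³) for 19 non-cortical structures — 87 regions in total.

## The model

After removing confounds with a per-region-feature mixed-effects model
(age, gender, total grey-matter volume, their group interactions, and a
subject random intercept — group main effects are deliberately absent so
group structure survives in the residuals), each group's regional data
`x_s ∈ R^d` (d = 3 cortical, d = 1 non-cortical) is modelled as a
multivariate Gaussian `N(x | μ, Σ)` with the maximum-likelihood
estimators (mean, 1/S-normalised covariance). The framework then provides:

- **Parameter-wise group comparison** — each of the `2d + d(d−1)/2`
  distribution parameters is contrasted between groups (HC − ET), with
  two-tailed permutation p-values (10 000 shuffles by default, exhaustive
  enumeration when feasible) and Bonferroni correction over the 87 regions.
- **Bimodality detection** — a K = 2 Gaussian mixture
  `Σ_k π_k N(x | μ_k, Σ_k)` fitted by EM is compared to the single
  Gaussian by leave-one-out cross-validated log-likelihood, which penalises
  the mixture's extra flexibility out of sample.
- **Conformity scores** — each patient's regional data point is scored by
  its log-likelihood `LL_N(z_s | μ̂_ET, Σ̂_ET)` under the patient-group
  fit: a normative "distance to the distribution" that weighs different
  kinds of deviation equally.
- **Behavioural PLS** — the SVD `R = IᵀB = UΣVᵀ` of the z-scored
  imaging × clinical cross-covariance extracts covariance modes between
  morphometry (raw residuals or conformity scores) and clinical scores
  (ADL, TSTH, head tremor, symptoms' duration, family history), with
  permutation p-values per mode and 99 % bootstrap confidence intervals
  per salience weight (80 % of subjects resampled with replacement).

Because cohort data of this kind is rarely public, the package ships a
first-class synthetic cohort generator (`morphohet.synthetic`) whose
draws follow exactly the generative model the pipeline assumes, with
plantable effects on any Gaussian parameter, variance-matched bimodal
regions, and a plantable rank-one brain-behaviour mode — so every stage
is testable by parameter recovery.

## Worked example

The numbered scripts under `analysis/` run the whole study on a planted
synthetic cohort (29 controls, 34 patients, six regions):

```sh
python analysis/01_simulate_cohort.py --seed 1
python analysis/02_regress_confounds.py
python analysis/03_group_differences.py --seed 1
python analysis/04_mixture_selection.py --seed 1 --n-restarts 10
python analysis/05_conformity_scores.py
python analysis/06_pls_brainbehavior.py --seed 1 --n-perm 2000 --n-boot 2000
```

prints, among other things:

```
40 parameter comparisons across 6 regions (10000 permutations each)
  lh_caudalanteriorcingulate var_SA: delta=-5.67858e+06 p_raw=0 p_corr=0
...
  Right-Putamen: LL_cv gaussian=-255.58 gmm=-245.39  <-- bimodal
1 of 6 regions prefer the mixture representation
...
[raw] mode 1: p=0.0000, 71.08% of covariance explained; ...
```

Reading this: the planted surface-area variance increase in the left
caudal anterior cingulate appears as a negative HC − ET variance delta
with a Bonferroni-corrected permutation p below resolution; the planted
bimodal right putamen is the only region whose cross-validated
log-likelihood favours the two-component mixture; and the planted
brain-behaviour mode surfaces as a significant first PLS covariance mode.
The same sequence on a null cohort reports nothing — see the calibration
tests.

The same stages are available as a CLI
(`morphohet simulate|regress|groupdiff|gmm-compare|conformity|pls|run-all`)
and as one orchestrated, fully seeded run
(`morphohet.pipeline.run_pipeline`), which writes all stage tables plus a
machine-readable `summary.json`.

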