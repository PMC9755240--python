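# Methods

This note documents the statistical model behind `morphohet`, the
defaults and numerical choices, what the synthetic cohort generator does
and does not emulate, and the design decisions taken where the design was
genuinely open.

## Data model and region registry

The unit of analysis is a *region*: one of 68 Desikan-Killiany cortical
parcels (34 per hemisphere), where each subject contributes a
three-dimensional data point — cortical thickness (CT, mm), surface area
(SA, mm²), mean curvature (MC, mm⁻¹) — or one of 19 non-cortical
structures (bilateral cerebellar cortex and white matter, thalamus,
caudate, putamen, pallidum, hippocampus, amygdala, accumbens, brainstem),
where the data point is a scalar volume (mm³). The exact non-cortical
list is a documented assumption: it is the standard whole-brain
subcortical segmentation set with the required count of 19. Inputs are
plain delimited tables (one row per subject-timepoint), validated against
the registry; all outputs are TSV plus JSON run metadata.

## Confound regression

Each region-feature is modelled independently as

    M_is = β0 + β1·A_s + β2·G_s + β3·V_s
         + Σ_k [ β_{3+k}·I_k·A_s + β_{5+k}·I_k·G_s + β_{7+k}·I_k·V_s ]
         + b_s + ε_is ,

with age `A`, gender `G` (0/1), total grey-matter volume `V`, dummies
`I_k` for the two non-reference group levels (patients at baseline, and
at the second timepoint; controls are the reference), a subject random
intercept `b_s ~ N(0, σ_b²)` and noise `ε ~ N(0, σ²)`. Group *main*
effects are deliberately absent: the model removes covariate effects
(allowing them to differ by group) while leaving group structure in the
residuals, which all downstream stages consume. Residuals are *marginal*:
observed value minus the fitted fixed part only.

Three choices deserve emphasis:

- **Estimation is maximum likelihood** (statsmodels `MixedLM`,
  `reml=False`; a REML switch exists). ML keeps likelihoods comparable
  across models and is the simpler choice where the estimator is
  otherwise unspecified.
- **Covariates are grand-mean centred** before the interaction columns
  are built. With interaction-only group coding this is not cosmetic: an
  uncentred group-by-age column contains a constant group offset
  (age ≈ 66 ≫ its spread), so the fit would silently absorb most of any
  group mean difference — exactly the signal the residuals must keep.
  Centring makes the interaction columns orthogonal to group offsets; it
  also makes residuals invariant to shifting a covariate by a constant.
- **One observation per subject everywhere** makes σ_b unidentifiable;
  it is then fixed at zero with a warning and the fit reduces exactly to
  ordinary least squares (verified against a direct OLS solve to 1e-8).

Downstream analyses use the control and patient-baseline residual rows;
second-timepoint rows inform the mixed fit and are then dropped.

## Gaussian modelling and group comparison

Per region and group, the model is a single multivariate normal with the
maximum-likelihood estimators: arithmetic mean and covariance normalised
by S (a 1/(S−1) switch exists; the default follows the likelihood-optimal
definition). A ridge of `1e-8 · (trace/d) · I` is added only when the
estimated covariance is numerically singular; genuinely degenerate data
(S ≤ d, constant dimensions) is a hard error.

Group differences are assessed per distribution parameter — d means, d
variances, d(d−1)/2 covariances (j < k order) — as the plain difference,
control minus patient. Significance comes from re-estimating the
difference after randomly re-assigning the pooled data points to groups
(default 10 000 draws; when the number of distinct splits is at most the
permutation budget the null is enumerated exhaustively instead). The
two-tailed p-value is the plain fraction of null draws whose |Δ| reaches
the observed |Δ|, ties counting as exceedances; this convention can
produce p = 0 and is the default because it matches how such results are
conventionally reported, with a `(1+k)/(1+n)` smoothed variant available.
Reported p-values are Bonferroni-corrected over the 87 atlas regions,
per parameter — not over regions × parameters. Per-region RNG streams
derive from (master seed, region index), so results are independent of
execution order.

Calibration of the whole chain is verified empirically: on 1 000 null
regions (30 subjects per group, d = 3, 1 000 permutations) every
parameter's raw rejection rate at α = 0.05 falls within [0.035, 0.065].

## Mixture modelling and model selection

Bimodality is probed with a K = 2 Gaussian mixture fitted by EM.
Responsibilities are computed stably in log space; the M-step uses
weighted means/covariances and mixing proportions equal to mean
responsibility. Defaults: relative log-likelihood tolerance 1e-6,
max 500 iterations, 20 restarts (the first deterministic — a hard split
at the median of the first principal-axis projection; the rest random
soft responsibilities), ridge 1e-6·(trace/d)·I on near-singular
components; a component that stays degenerate triggers a logged
re-initialisation. The ascent property of EM (non-decreasing
log-likelihood trace) and the in-sample nesting of the single Gaussian
are asserted in tests.

Because the mixture always fits at least as well in sample, models are
compared by leave-one-out cross-validation: both are refitted on every
S−1 subset and evaluated on the held-out point; the summed held-out
log-likelihoods decide, ties going to the single Gaussian (parsimony).
K is fixed at 2 — at the study's sample sizes (about 30 per group) each
extra component would add d + d(d+1)/2 + 1 parameters, which the data
cannot support. Folds where either refit degenerates are dropped from
both sums and counted; a region with ≥ 10 % failed folds is flagged
inconclusive.

## Conformity scores

A patient's conformity in a region is the log-likelihood of their
residual data point under the patient-group Gaussian fitted on the full
patient sample (the evaluated subject included, matching the definition
of the score; a leave-one-out variant exists behind a flag). The score
is a monotone function of Mahalanobis distance from the group mean, so it
maps qualitatively different deviations — too thick, too thin, unusual
covariance pattern — onto a single "distance to the distribution" axis.

## Behavioural PLS

Imaging (S × M) and clinical (S × B, M ≥ B) matrices are z-scored per
column (ddof = 1) and the cross-covariance R = IᵀB decomposed by SVD.
Modes are ordered by singular value; squared singular values over their
sum give explained covariance fractions; a deterministic sign convention
(largest-magnitude clinical weight positive) fixes the SVD sign
indeterminacy. Mode significance: rows of the clinical matrix are
permuted (default 10 000 times) and the k-th observed singular value is
compared with the k-th null singular values (index-matched; a max-based
variant exists). As a single multivariate test, no further correction is
applied. Salience robustness: 80 % of subjects are resampled with
replacement (default 10 000 times; `frac=1.0` gives the conventional
bootstrap), each resample re-z-scored and re-decomposed, and each
solution aligned to the original — mode order and sign by maximal
absolute salience correlation (Hungarian assignment on the stacked
[U; V] correlation matrix), an alignment step the SVD's indeterminacies
make necessary. Percentile intervals at α/2 and 1−α/2 (α = 0.01) per
weight; a weight is significant when its interval excludes zero.
Missing head-tremor scores are mean-imputed with a logged count (a
drop-subject option exists).

Both imaging settings run on the same clinical matrix (ADL, TSTH, head
tremor 0-3, symptoms' duration, family history 0/1; B = 5): raw
concatenated residual morphometry (3·68 + 19 columns at full scale) and
per-region conformity scores (87 columns).

## Synthetic cohorts: what they emulate, and what not

The generator draws cohorts from exactly the generative model the
pipeline assumes: per-observation value = covariate part (grand-mean
centred design, matching the confound model) + persistent subject-level
group draw (Gaussian, or a mixture in designated regions) + subject
random intercept + observation noise; a second patient timepoint reuses
the subject-level terms plus an optional shift. Defaults mirror the
study conditions: 29 controls vs 34 patients, patients measured twice,
ages uniform on 49-83, balanced gender, Gaussian total grey-matter
volume; feature scales are realistic regional magnitudes (CT 2.5 ± 0.15
mm, SA 2500 ± 500 mm², MC 0.13 ± 0.01 mm⁻¹, volume 4000 ± 400 mm³) with
moderate CT/SA/MC correlations. Clinical marginals match the reported
patient summaries (ADL 29.6 ± 11.4, TSTH 20.4 ± 5.5, head tremor 1 ±
0.85 discretised to 0-3, duration 35.5 ± 18.3 years, family history
rate 0.68). A rank-one latent mode couples patient morphometry to the
clinical scores through unit-norm saliences u*, v*.

Not emulated: spatial dependence between regions (regions are drawn
independently), realistic between-region scale differences,
non-Gaussian feature noise, and any post-intervention effect beyond a
constant shift. Passing recovery tests therefore demonstrates that the
pipeline estimates what the model defines, under the model's own
assumptions — not that real morphometry satisfies those assumptions.

### The planted scenario

The packaged end-to-end scenario uses six regions (four cortical, two
subcortical) and plants one effect of each class, with effect sizes set
by a-priori power analysis so a single run detects each class with high
probability at its own family-wise threshold:

- a patient-group SA-variance increase (ratio 16) in one cortical region
  — at 29/34 subjects and the Bonferroni-corrected α over 87 regions, a
  two-tailed permutation test detects a ratio of 4 only ~33 % of the
  time, so a recovery run must plant a stronger effect;
- a variance-matched bimodal subcortical volume (components eight
  component-SDs apart, component variance shrunk so the mixture's total
  variance equals the control variance — the region then differs in
  shape only and lands in the bimodality class, not the variance class);
- a rank-one brain-behaviour mode loading negatively on MC and
  positively on CT columns (strength 7 noise-units per unit salience,
  chosen to keep the per-column variance inflation below what the
  variance test can resolve, again to keep effect classes disjoint).

## Numerical and reproducibility choices

Every stochastic stage derives its stream from one master seed via
`numpy.random.SeedSequence` spawn keys (per stage, per region, per CV
fold), so re-running a configuration reproduces every output byte for
byte and region-level results are independent of execution order.
Desk-scale defaults used by the tests and the acceptance script (reduced
permutation/bootstrap counts, 3-5 EM restarts, 400-1000 null regions)
are the problem sizes at which the calibration statements above were
established; the library defaults remain 10 000 permutations and
bootstrap draws and 20 restarts.

## Known limitations

- The permutation p-value's plain-fraction convention is mildly
  anti-conservative at very small α (it can return 0); combined with
  Bonferroni over 87 regions and nine parameters per cortical region, a
  large null study will occasionally show a corrected "significant"
  parameter. The smoothed variant avoids p = 0 at the cost of never
  reaching the strictest thresholds at a given permutation budget.
- Regions are modelled independently throughout; cross-regional
  dependence is neither modelled nor exploited.
- The mixture comparison considers K = 2 only, and the LOO decision is a
  point decision without an uncertainty measure.
- Bootstrap salience intervals inherit the usual caveats of resampling
  small samples (S ≈ 34 in the conformity setting): intervals are wide,
  and the 80 %-subsample convention widens them further relative to a
  full-size bootstrap.
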