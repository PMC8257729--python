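# Methods

This package studies how the total MRI-visible burden of cerebral small
vessel disease (SVD), measured once at mean age ~73, relates to nine-year
trajectories of cognitive ability measured at four triennial waves. Because
the cohort data it was designed around are available only on request, the
package ships a synthetic cohort generator with known ground truth; every
model, statistic, and pipeline stage is exercised and validated against that
generator.

## Models

### Measurement of SVD burden

A single latent SVD-burden factor is measured by four baseline markers: the
WMH/intracranial-volume ratio and the perivascular-space (PVS) count as
linear indicators, and lacunes and microbleeds (present/absent) as
probit-threshold indicators (a binary marker is 1 when a standard-normal
liability plus its loading times the factor exceeds a threshold tau).
Identification fixes the WMH loading at 1 and frees the factor variance;
binary residual variances are fixed at 1 with no free intercept.

The WMH ratio is log-transformed before z-scoring by default. The ratio is
strongly right-skewed (roughly log-normal with coefficient of variation near
1), and a linear factor loading is only plausible on the log scale; the
generator accordingly produces the ratio as a scaled log-normal whose log is
exactly linear in the SVD factor. `wmh_transform="none"` switches the
pipeline to the raw ratio.

### Factor-of-curves growth models

For each cognitive domain (processing speed, verbal memory, visuospatial
ability, or the general battery of all ten tests), each test's four waves
load on a latent intercept (loadings 1) and a latent slope with loadings
fixed at the average between-wave lags 0, 3.78, 6.83 and 9.55 years. The
per-test intercepts and slopes load on a second-order domain intercept and
slope (first test's loadings fixed at 1), with free per-test disturbance
variances and intercept-slope disturbance covariances. The SVD factor (or
the observed WMH ratio in the sensitivity variant) predicts the second-order
intercept and slope. Time-invariant covariates (sex, the vascular-risk
factor score, age-11 ability) enter as single-indicator latents regressed
into the second-order factors and covarying with the predictor and each
other; mean-centred age at each wave is a direct exogenous predictor of the
same wave's observed scores (one pooled coefficient across the z-scored
tests). Covariate steps are nested: none, +age+sex, +vascular risk,
+childhood ability.

All tests are oriented so higher = better (four-choice reaction time is
negated) and z-scored against the baseline-wave observed mean/SD, so latent
means and slopes are in baseline-SD units; standardized structural estimates
are invariant to this choice.

### Longitudinal bifactor model

The bifactor model splits every test's latent intercept (and slope) between
a general factor and one of three orthogonal domain factors: general and
domain factors are mutually uncorrelated (only the intercept-slope
covariance within each factor stays free), so the general and
domain-specific trajectories are measured independently of one another.
Second-order factors carry fixed unit residual variance with free loadings;
slope-factor means are free, intercept-factor means fixed at 0. The SVD
factor predicts all eight second-order factors simultaneously. After
fitting, each factor is re-oriented so its summed loadings are positive (the
likelihood is invariant under joint sign flips).

### Vascular-risk factor score

A one-factor CFA of hypertension, diabetes and smoking history (probit) plus
HbA1c, total cholesterol and systolic/diastolic blood pressure (linear,
z-scored) is fitted at baseline; each subject's covariate value is the
posterior mean of the factor given their observed indicators (the regression
method generalised to the mixed probit/linear model), centred to mean zero.

## Estimation

The engine computes the model-implied moments in LISREL form
(Sigma = Lambda (I-B)^-1 Psi (I-B)^-T Lambda^T + Theta) and maximises the
full-information maximum likelihood over subjects grouped by missing-data
pattern. With binary indicators, all of which must load on one latent, the
likelihood integrates over that latent with adaptive Gauss-Hermite
quadrature (21 nodes by default; the adaptation centres and scales the nodes
per subject using the Gaussian part of the latent posterior). The whole
likelihood is differentiated analytically (hand-written reverse-mode through
the matrix algebra and the quadrature); gradients agree with finite
differences to ~1e-8 in the test suite. Node positions' own parameter
dependence is ignored in the gradient, which is inconsequential at the
default accuracy (15- vs 41-node log-likelihoods agree to <1e-6).

Optimisation is L-BFGS-B with variances on the log scale (soft positivity),
a one-shot diagonal-Hessian preconditioner computed at the start point, and
optionally multiple jittered starts with best-likelihood selection. Slope
loadings are carried internally as wave-time/9.55 so slope-block parameters
share the intercept block's numerical scale (a pure reparameterization;
per-year quantities are recovered by dividing by the span, and standardized
estimates are unaffected). Non-positive-definite parameter points are
rejected with a smooth penalty that pushes the line search back toward the
last admissible point. Convergence requires an admissible point and either
optimizer success or a small gradient norm.

Standard errors are observed-information (central finite differences of the
analytic gradient at the optimum); the standardized solution rescales each
structural path by the model-implied total SDs of predictor and outcome and
carries delta-method SEs and Wald 95% CIs. Fit assessment uses the
likelihood ratio against a less-restrictive neighbour when binary
indicators are present (absolute indices are unavailable then), and RMSEA /
CFI / TLI / SRMR otherwise, with the saturated model fitted by EM and the
baseline as the free-means diagonal model. Benjamini-Hochberg FDR correction
is applied separately within the three model families (SVD-predictor FoC,
WMH-predictor FoC, bifactor). The slope R^2 attributable to the predictor is
the squared standardized path.

## Synthetic cohort generator

The generator forward-simulates the same structures the models estimate, at
n = 540 by default. Key default conditions (one global seed; all streams
derived from it):

* Baseline age 72.5 (SD 0.5) years; waves at +3.78, +6.83, +9.55 years with
  0.15-year jitter.
* Ten tests in three domains with plausible raw score scales; occasion-noise
  SDs are solved per test so each test's baseline variance is exactly 1 in
  the latent z metric, making generating slope means exact baseline-SD/year
  quantities. Reference tests (digit symbol, verbal paired associates, block
  design) have unit loadings so domain-model slope means recover the
  generating means one-to-one.
* General intercept SD 0.75; general slope mean -0.13 SD/year, SD 0.045;
  intercept-slope residual correlation -0.2; per-domain mean declines
  -0.16 / -0.005 / -0.08 SD/year via proportional offsets.
* SVD factor: standardized loadings 0.75 (log WMH), 0.40 (PVS), liability
  loadings 0.75 / 0.55 for lacunes / microbleeds with thresholds solved from
  the target prevalences 5.1% and 12.0%.
* Structural effects are specified as standardized paths and converted to raw
  scale internally (residual variances solved so total factor SDs match);
  scenario defaults put -0.201 (hierarchical) or -0.222 (bifactor, general
  slope only) on the SVD->slope path and -0.25 on the intercept path, with
  modest covariate effects (age-11 -> intercept 0.50, vascular -> slope
  -0.10, sex 0.05) and predictor correlations (SVD-age11 -0.15, and SVD-vascular
  kept small at 0.10, consistent with the near-stability of the SVD path
  across the published covariate steps).
* In the bifactor scenario, domain slope SDs (0.030 / 0.026 / 0.028 per
  year) are calibrated so the general factor carries ~55-65% of per-test
  slope variance and domains ~25-30%, matching the cohort's published
  decomposition of decline variance; domain-loading profiles deliberately
  differ from the g profiles (exactly proportional profiles would leave the
  bifactor rotation empirically indeterminate, which real batteries do not
  exhibit). Domain mean offsets ride the domain-specific channel when a
  domain factor exists so the fitted bifactor mean structure is exact.
* Attrition: monotone per-wave dropout with logistic probability in the
  standardized log WMH ratio (+0.35 per SD) and education (-0.25 per SD);
  per-wave base rates (14.3%, 19.7%, 19.4%) reproduce the published wave
  sizes 540 -> 463 -> 372 -> ~300, and intercepts are calibrated by
  quadrature so realized rates match despite the covariate dependence.
  Dropout depends only on fully observed baseline variables, so it is
  missing-at-random by construction for models containing those variables.

What the generator does not emulate: practice/retest effects, floor and
ceiling effects or other non-normal test distributions, non-linear
trajectories, measurement non-invariance over waves, intermittent (return
after skip) missingness, and real-world correlation between vascular risk
and attrition beyond the WMH/education channels. Passing recovery tests
therefore demonstrates that the estimation machinery is correct and well
calibrated under the study's design (sample size, wave spacing, attrition,
effect sizes) - not that the substantive findings would replicate in new
cohort data.

## Problem sizes used in validation

Recovery experiments in `scripts/acceptance.py` use n=540 cohorts with
attrition: 100 replicates for the fully adjusted general model (its mean is
reused for the quadratically sensitive slope-R^2 summary), 50 per other
hierarchical-model target and 25 for the bifactor target; per-fit runtimes
are roughly 0.3 s (single-domain measurement models) to 10 s (fully
adjusted bifactor), about 7-8 minutes in total. The test suite runs
reduced versions (5-6 replicates with 3.5-Monte-Carlo-SE tolerances), plus
oracle equivalences at n=120-800, a 300-replicate likelihood-ratio type-I
calibration, and a 40-replicate CI-coverage check. Bias of the recovered
standardized SVD->slope path at n=540 was checked against larger paired
designs (complete vs attrition cohorts, 100 paired replicates; n=2000 and
n=8000 single fits) and is below ~0.01 in absolute value.

## Known limitations

* Binary indicators must load on a single latent (one-dimensional
  quadrature); no WLSMV/polychoric estimation, robust corrections,
  multiple-group models, or nonlinear growth.
* Absolute fit indices are unavailable for models with binary indicators or
  exogenous direct regressors; the pipeline reports them for the
  WMH-predictor family at the covariate-free step only.
* The likelihood-ratio "correlational neighbour" frees the predictor's
  covariances with all first-order disturbances; other neighbour choices are
  possible and would change the degrees of freedom.
* Wald confidence intervals on standardized estimates (no bootstrap); factor
  scores are posterior means, whose shrinkage slightly attenuates
  downstream covariate adjustment, as with any estimated-score covariate.
* The bifactor model's split of slope variance between the general and
  domain factors is weakly identified at n=540: the maximum-likelihood
  SVD->general-slope path varies considerably more from replicate cohort to
  replicate cohort than the hierarchical models' paths, and occasional
  replicates produce extreme-but-global optima in which effect mass shifts
  between the general and domain channels. Replicate means remain close to
  the generating value; single-cohort bifactor path estimates deserve extra
  caution.
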