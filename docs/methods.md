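# Methods

## Overview

`brainpad-lab` implements a sex-stratified brain-aging analysis for
Parkinson's disease (PD) as a reusable pipeline. Chronological age is
predicted from structural-MRI tissue features by a linear support vector
regression (SVR); the prediction is bias-adjusted; the brain-predicted age
difference (Brain-PAD = adjusted predicted age − actual age) is compared
between male and female patients, regressed against clinical outcomes, and
related to local tissue density in a voxelwise analysis with permutation
family-wise-error (FWE) control. Because the MRI archives such studies
draw on are access-gated, the package ships a first-class synthetic-cohort
generator with known ground truth, so every stage can be validated by
parameter recovery and calibration rather than by comparison to gated data.

## Synthetic cohort model

Each subject carries a GM, WM and CSF probability map on a regular grid
(default 16×16×16 voxels at 8 mm, ellipsoidal brain mask of ≈2000 in-mask
voxels; a full-scale mask with exactly 3747 in-mask voxels per tissue is
available for schema checks). Maps are built as

    GM  = template + r · (age + gap) + sex offset (males) + scanner offset + noise
    WM  = template + 0.5 · r · (age + gap) + noise
    CSF = template − 1.5 · r · (age + gap) + noise

with `r` the GM atrophy rate (default −0.002 probability units/year,
uniform over the mask). CSF absorbs the GM and WM loss, so total
intracranial volume (TIV) is age-invariant per subject — TIV is a covariate
in the downstream models, not an outcome. Atrophy acts through the
*effective age* `age + gap`: a patient with latent gap *g* has the maps of
a healthy brain *g* years older, which makes the injected Brain-PAD a
well-defined recovery target. Noise is a spatially smooth Gaussian field
(white noise smoothed at 8 mm FWHM, rescaled to sd 0.02 in probability
units per tissue, scaled per scanner). Values are clipped to [0, 1];
on the rare voxels where independent per-tissue noise pushes GM+WM+CSF
above 1 the three tissues are rescaled to sum to one, preserving the
physical constraint at the cost of exact noise independence there.

Cohort composition defaults mirror the emulated study: healthy controls
53% female with ages uniform on 18–94; patients 34% female, uniform on
33–85; latent gaps `N(3.5, 2²)` years for males and `N(1.8, 2²)` for
females; healthy subjects have gap 0. Ages are uniform rather than
moment-matched normal because full support over the age range is what the
bias-adjustment machinery needs to be exercised against. Sex is Bernoulli
per subject, so realized group-by-sex counts vary binomially around their
expectations. Disease duration (months) is scan age minus diagnosis age
times twelve; time since diagnosis is uniform on 0.25–8 years.

Clinical outcomes are generated from the same three linear model families
the analysis later fits (motor; non-motor with UPDRS-III as an extra
predictor; mood with UPDRS-III and MoCA), with the latent gap standing in
the Brain-PAD slot and recorded generating coefficients. Default
coefficients put outcome means and spreads near published PD cohort
summaries (UPDRS-III ≈ 20 ± 9, MoCA ≈ 27 ± 2). Downstream families load
on the *underlying* score of an upstream outcome, not its recorded value,
so injected missingness (default 2% per outcome) does not cascade.
Outcomes exist only for patients. All draws come from named sub-streams of
the master seed (`_rng.rng_stream`), so any stage regenerates
bit-identically in isolation.

What the generator does **not** emulate: anatomy (no tissue classes with
realistic geometry), registration error, scanner physics beyond an
additive offset and a noise scale, nonlinear age trajectories, or
non-Gaussian gap distributions. Passing recovery tests therefore show the
*estimator chain* is consistent and calibrated under its stated
assumptions — not that those assumptions hold in real MRI data.

## Morphometry operators

Smoothing is Gaussian with σ = FWHM/(2√(2 ln 2)) per axis in mm and
zero-padded boundaries (tissue probability outside the head is zero);
this differs from SPM's implicit boundary handling but conserves tissue
mass. Resampling is volume-weighted block averaging to an integer
multiple of the source spacing, which preserves mean density (the
"modulated" VBM intent) and is exactly testable; interpolation and
upsampling are deliberately unsupported. Masks resample by majority vote
(ties count as in-mask). Tissue volumes are Σ(probability)·voxel volume
over the mask, in ml; TIV is their sum. The striatal binding ratio is
target/reference − 1. The 4-mm kernel is interpreted as FWHM (the CAT12
convention).

## Brain-age model

Features per subject: GM, WM, CSF in-mask voxel intensities, the three
total tissue volumes, TIV, sex (F=0, M=1), scanner vendor indicators and
field strength. Vendor uses drop-first one-hot coding with ≥2 levels; a
single-level cohort keeps its one (constant) indicator so the schema
always carries a vendor column (constant columns pass through z-scoring
with unit scale). The regressor is `sklearn.svm.SVR(kernel="linear")`
with C = 1, ε = 0.1 on features z-scored with training-set statistics —
the hyperparameters are ordinary defaults, exposed in the run config.
Accuracy is reported as MAE, RMSE and R², from 10-fold cross-validation
(seeded random partition, no stratification) on the training set and
directly on the held-out controls (90/10 split, train size = round(0.9·n)).
The deployed model is refit on the full training set after CV.

Bias adjustment: raw brain-age predictions regress toward the mean
(regression dilution), making Brain-PAD negatively correlated with age.
The offset `predicted − actual` is regressed on actual age by OLS,
`offset = α·age + β`, on the **training set only**; corrected predictions
subtract the fitted trend. By OLS orthogonality the training-set Brain-PAD
then has exactly zero mean and zero correlation with age (asserted to
1e-8); α and β are frozen and reused for the hold-out and patient sets,
whose mean Brain-PAD is therefore *not* constrained to zero — the patient
excess is the quantity of interest. The 95% CI on mean Brain-PAD is the
normal approximation mean ± 1.96·SE.

A note on an SVR subtlety: duplicating feature columns doubles the linear
kernel, which is equivalent to doubling C; predictions are invariant under
duplication only with a compensating C/2, which is what the test asserts.

## Propensity matching

To compare sexes at matched disease severity, the larger male group is
matched 1:1 to the female group on age, education, diagnosis age,
UPDRS-III total/rigidity/tremor, MoCA, REM and ESS. Scores are fitted
probabilities from a statsmodels logistic regression (constant covariates
dropped with a warning; non-convergence or perfect separation raises with
advice). Matching is greedy nearest-neighbour without replacement on the
linear predictor (logit of the score — standard practice, since logit
distances are comparable across the probability range), minority processed
in a seeded random order over *sorted* ids, so results are invariant to
input row order. Subjects missing any matching covariate are listwise
deleted first; the matched count is therefore the number of
complete-covariate minority subjects. Balance is reported pre- and
post-match as group means/SDs, pooled-variance t-tests and standardized
mean differences (SMD, pooled-SD denominator).

A limitation worth stating: with a majority/minority pool ratio under ~2
and 1:1 matching without replacement, very large uniform covariate shifts
cannot be balanced away by any matcher of this class; the ≥50% SMD
reduction the tests demonstrate holds under realistic modest imbalance
(~0.3 SD per covariate), not under arbitrary separation.

## Clinical regression battery

Each outcome is fit by OLS within each subgroup (all PD, females, males,
matched males) using its family's predictors; the sex term is dropped
automatically in single-sex subgroups. Listwise deletion is applied per
model (not per dataset), so n and residual df differ across models.
Classical homoskedastic standard errors, two-sided coefficient t-tests,
and the overall F-test are reported with adjusted R². The
Benjamini–Hochberg FDR adjustment is applied to the F-test p-values within
each family-by-subgroup table; coefficient p-values stay raw, mirroring
how such batteries are tabulated. BH output is order-invariant and never
below the raw p-value; it is *not* idempotent in general (a known property
of the step-up construction, e.g. (0.01, 0.5) → (0.02, 0.5) → (0.04, 0.5)),
so only the first two properties are asserted. Interaction terms
(sex × Brain-PAD) are intentionally absent: the sex contrast is carried by
the stratified fits and the matched-group t-test.

## Voxelwise analysis

Tissue density at every in-mask voxel is regressed on Brain-PAD with age,
sex and TIV as nuisance covariates; the per-voxel OLS t for the Brain-PAD
column is computed in one vectorised pass and verified against the tabular
OLS on single voxels to 1e-10. Voxels whose data are constant to rounding
precision get an undefined (NaN) t, with the count logged.

FWE control uses max-statistic permutation instead of random-field theory:
RFT needs smoothness-estimation machinery and delivers only asymptotic
control, while the permutation test is exact under exchangeability and
directly testable by simulation. Permutation follows the Freedman–Lane
scheme — residuals under the nuisance-only model are permuted and
recombined with the nuisance fit before the contrast t is recomputed —
which keeps the test valid in the presence of nuisance covariates. The
corrected p for a voxel is `(1 + #{max|t*| ≥ |t|}) / (n_perm + 1)`; it is
monotone in |t| by construction. Two-sided testing with positive and
negative clusters reported separately.

Clusters are 26-connected components of voxels passing the corrected-p
threshold, filtered by a minimum extent (the analysis-grid analogue of a
100-voxel VBM extent rule; configurable, default 10 voxels at the coarse
16³ grid), and summarised by size (voxels and ml), peak t, peak corrected
p, peak world-mm coordinate via the affine, and hemisphere from the sign
of world x. ROI follow-up reports the Pearson correlation between mean
in-cluster density and Brain-PAD per group.

## Pipeline, configuration, determinism

`pipeline.run_all` sequences simulate → smooth/resample → features →
CV + train → bias adjust → Brain-PAD per set → match → battery →
voxelwise, logging per-stage timings and failing with the stage name (a
`FAILED` marker is left beside partial outputs). Configuration is one YAML
file parsed strictly — unknown keys are errors naming their path — with a
content hash stamped into the report bundle. The master seed drives every
sub-stream; identical config + seed reproduce bit-identical CSV outputs.

## Problem sizes and numerical choices

Defaults are sized so a full study runs in seconds on one core: 300
training controls, 34 held-out, 373 patients, 16³ grid (~2000 mask
voxels, ~6000 features), 300–400 permutations for FWE. Calibration suites
use reduced sizes chosen for stable rates: 500 intercept-only replicates
(n = 60) for battery F-test calibration, 200 null datasets (n = 40, ~500
voxels, 200 permutations) for FWE calibration, 20 seeds for gap-recovery
and power checks. Tolerances: analytic identities at 1e-8–1e-10;
stochastic rates against binomial-width intervals; recovery of the
injected 3.5/1.8-year gaps within ±0.5 years on seed-averaged means.

## Known limitations

- The synthetic maps are far more informative about age than real MRI
  (training MAE well under a year at default noise); accuracy numbers on
  synthetic cohorts characterise the pipeline, not achievable real-data
  performance.
- The Gaussian latent-gap model and linear atrophy are assumptions of the
  generator, not findings.
- Block-average resampling requires integer spacing ratios.
- Anatomical labelling of clusters, TFCE, cluster-level (vs peak-level)
  inference, nonlinear age models and site harmonisation beyond
  vendor/field covariates are out of scope.
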