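# Methods

`serostack` implements a stacked-ensemble analysis for detecting pancreatic
ductal adenocarcinoma (PDAC) from serum biomarker panels drawn months to
years before clinical diagnosis, in a nested case-control design: each serum
sample carries a case/control label, the case samples a time-to-diagnosis
(YTD) at draw, ~101 biomarker concentrations, and clinical covariates (age at
draw, BMI, HRT use, OCP ever-use, diabetes). This note records the models,
the defaults and why, and the limits of what the synthetic-data tests show.

## Data model and time groups

Samples are rows of a delimited table; concentrations below an assay's limit
of detection arrive as a `low` token and are kept as flags until imputed.
The default imputation is **half the observed per-marker minimum**; a fixed
floor is available per marker. A marker observed only below LOD is an error,
not a guess.

YTD is discretised into single year groups 0-1, 1-2, 2-3, 3-4, 4+ as
**half-open intervals [a, b) in years**, so a draw exactly 2.0 years before
diagnosis belongs to 2-3 (the boundary moves up). Joined groups 0-1 … 0-4+
are unions of single-group prefixes. Controls have no diagnosis date; they
are eligible for — and shared across — every group's case-control
comparison, unless a per-group control allocation is supplied.

The train/test split (2/3 by default) stratifies on outcome, single
time-group, age and BMI quartile (quartiles computed on the combined table,
ties to the lower quartile), HRT, OCP and diabetes. Fully crossed strata at
this key list are mostly singletons at a few hundred samples, and
singleton-to-train assignment would drain the test set of cases; strata
smaller than `min_stratum=3` are therefore coarsened to (status, time-group)
before assignment. Within every final stratum the train fraction deviates
from the target by at most one sample. Longitudinal draws from one subject
are treated as independent rows by default (matching the study design the
pipeline reproduces); a subject-grouped split can be emulated by passing a
subject-level key.

## Synthetic cohorts

The generator emulates the discovery cohort's structure, not its data: 143
case subjects (a 35/143 fraction with 2-6 exactly annual longitudinal
draws; first draw uniform on (0, 70] months before diagnosis), 249 controls,
101 markers, all-female discovery arm. Marker log-concentrations are
equicorrelated Gaussians (one-factor copula, default correlation 0.2, SD 1)
and a case sample drawn t years pre-diagnosis has its log-mean shifted by
`delta_m * exp(-t / tau_m)` — an exponential rise toward diagnosis, the
simplest kinetic shape consistent with serological markers rising ahead of
presentation. No kinetic model is fitted anywhere; this is a stand-in whose
only job is to give the pipeline the qualitative structure it assumes
(separation growing toward diagnosis, LOD censoring at a per-marker control
quantile, covariate-outcome associations at configured odds ratios: HRT
0.41, OCP 1.47, diabetes 4.99, age +2.5 y, BMI +0.8 kg/m² by default).
Covariate odds ratios are recovered by the Firth engine within Monte-Carlo
error at n = 30,000 (a property test). The external-set generator samples
post-diagnosis cases (full marker shift), mixes sexes, and blanks
never-collected covariates.

What the generator does **not** emulate: assay plate effects and CV%,
marker-specific covariance structure, a Lewis-antigen-negative CA19-9
subpopulation, non-annual draw schedules, or any real effect sizes — the
paper-scale headline AUCs are not reproducible from it and are not claimed.
Passing tests show the machinery is correct and calibrated, not that the
clinical performance transfers.

## Firth-penalized logistic regression

Single-feature association, ranking and covariate odds ratios use logistic
regression maximizing the Jeffreys-prior penalized likelihood
`l(beta) + 0.5 log det I(beta)`, by modified-score Newton iterations with
step-halving (penalized likelihood never decreases on an accepted step).
Estimates stay finite under complete separation and zero cells; for a
saturated one-binary-covariate design the estimate equals the +1/2-on-every-
cell closed form, which the tests exercise on 200 random tables to 1e-6
relative error. P-values are penalized likelihood-ratio tests with each
coefficient profiled to zero (Wald is available, not default); confidence
intervals are profile-penalized-likelihood intervals found by Brent root
finding on the deviance at the chi-square(1) 0.95 cutoff, bracketed at
+/- 10 SE and expanded if needed. Convergence: max |score| < 1e-6 and
max |step| < 1e-6 within 50 iterations, up to 12 step-halvings. Covariates
are not standardized, so odds ratios are per natural unit. Feature ranking
is by ascending LRT p-value with deterministic name tie-break; a feature
whose fit fails ranks last with NA statistics and a warning rather than
aborting the scan.

## Base-learner layer

Ten classifier families, consumed from scikit-learn and xgboost behind a
family registry: boosted shallow trees (C5.0-style), RBF SVM, regularized
random forest, PCA + feed-forward network, RBF Gaussian-process classifier
(length-scale sampled, not optimized — the random search is the optimizer),
elastic-net logistic regression, bagged AdaBoost, gradient-boosted trees,
forward stepwise-AIC logistic regression, and Gaussian naive Bayes. The SVM
emits probabilities through an explicit Platt sigmoid fitted on the training
decision values rather than scikit-learn's internal cross-validated
calibration, which can return probabilities anti-correlated with the margin
on small oversampled folds and silently invert a downstream fitted stack.
Hyperparameter ranges are data, shipped as YAML; two profiles exist —
`default` (study-scale ranges) and `fast` (desk-scale, lighter ensembles)
used by the test suite and examples. Random search draws `n_search`
configurations per family (stepwise-AIC and naive Bayes have nothing to
sample and fit once); the shipped default is 25 draws, a desk-scale choice —
the study-scale protocol used 1000 and the knob goes that high.

Training is repeated stratified k-fold CV (base layer default 5x10) with
**minority oversampling applied inside training folds only**; validation
folds and the test set are never resampled, so out-of-fold probabilities are
leakage-free. A draw's fold that fails to fit scores AUC 0.5 with a warning
instead of being dropped. The winning draw (best mean CV AUC) is refit on
the full oversampled training set; its out-of-fold probabilities, averaged
across repeats and clipped to [1e-6, 1-1e-6] (so the geometric-mean stack is
always defined), become the stacking features. The ranked-feature panel scan
evaluates nested top-k panels in steps of 10 against the stacked CV AUC,
ties toward smaller panels. A brute-force baseline fits plain logistic
regression over all marker combinations up to size 3 under the same CV plan.

## Stacking

Four meta-learners: **BMA** (Bayesian model averaging of logistic
regressions over subsets of probability columns, weighted by exp(-BIC/2),
Occam's-window pruning at odds 20, weights renormalized to 1), **MEAN**,
**GEOMEAN**, **MAX** (parameter-free row-wise pooling, permutation-invariant
by construction; GEOMEAN <= MEAN <= MAX row-wise always), and **AVNNET**
(an averaged committee of five 5-unit single-hidden-layer networks,
permitted only in the STG2L architecture). Stacks consume probabilities on
the probability scale, not logits. BMA enumerates subsets exhaustively up to
a configurable size cap when there are at most 12 columns; wider matrices
(STG2L's 10 x G) are first screened to the 12 best single columns by BIC and
enumerated among those — a deliberate replacement for branch-and-bound
model search, adequate because posterior mass concentrates on few columns.
Meta-level CV is 10x10-fold without oversampling.

Architectures: **JTG2L** trains the 10 families on all samples of a joined
time-group (stack sees 10 columns); **STG2L** trains 10 families per single
group (stack sees 10 x G columns); **STG3L** stacks each single group's 10
columns with BMA first and then stacks the G group probabilities. For the
single-group architectures, a sample outside a group model's training subset
has no out-of-fold probability from it; the refit model's prediction fills
that cell, so meta-learning sees out-of-fold values exactly where leakage
was possible. Mixed time-group combinations (0-1 plus 1-4 and similar) are
deliberately not implemented. A frozen `StackModel` carries its base
learners, panel, training-derived LOW imputation values and column schema;
prediction aligns by column name and never refits.

## Evaluation

AUC is the tie-aware Mann-Whitney statistic (ties count 1/2), cross-checked
against brute-force pair counting. 95% CIs come from stratified bootstrap
(cases and controls resampled separately; percentile interval, not BCa;
default 2000 draws, the convention of the standard ROC tooling); an interval
crossing 0.5 marks the AUC insignificant. ROC curves are compared with a
paired stratified bootstrap of the AUC difference and a two-sided normal
p-value (zero bootstrap variance guards to p = 1). Operating points report
sensitivity, PPV, NPV and MCC at 90% specificity: the threshold maximizes
sensitivity subject to empirical specificity >= target **on the evaluation
set** (matching how such panels are usually reported); a training-derived
threshold mode is provided for prospective use. Controls exactly at the
threshold count negative; under that convention the specificity target is
always attainable at the maximum control score. MCC with a zero denominator
is 0. The cross-time-group matrix evaluates every joined-group model on
every joined test group (cases restricted to the group, all test controls
included). The prevalence rescan down-samples one class to a target case
fraction, re-measures the operating point over replicates, and reports the
analytic PPV `sens*p / (sens*p + (1-spec)(1-p))` alongside as a closed-form
cross-check. Classifier diversity is summarized by Cohen's kappa between
base-learner calls, each dichotomized at its own 90%-specificity threshold.

## Importance

Model-agnostic importance is the variability of the partial-dependence
function: clamp feature j to a grid of up to 20 quantile points (both levels
for binary features), average the model's case probability over the
empirical distribution of the other features, and take the SD of that
profile (half the range for two-level features). Rows are subsampled
(seeded) above 2000. Raw importances are scaled to max 1 within each
(learner, time-group) model and summarized per feature as the median scaled
importance across cells. Importance is computed on the training set.

## External validation with missing covariates

When an external cohort never collected binary covariates in the frozen
model's panel (HRT, OCP), performance is marginalized over random
allocations: each replicate draws yes/no for the women (men are fixed "no")
either at the discovery control-arm frequencies (HRT 0.11, OCP 0.51 — the
default, a documented guess) or uniformly at 0.5, scores the cohort, and
records AUC and the 90%-specificity metrics. The report gives medians, IQRs
and a bootstrap CI of the mean per metric. Low dispersion across replicates
shows the missing covariates do not dominate the panel; a test confirms
dispersion grows when a model leans on them.

## Pipeline and reproducibility

One YAML config drives simulate → split → rank → train-base → stack →
evaluate → importance → validate-external. Every stage records SHA-256
checksums of its config block and artifacts in `manifest.json`; unchanged
stages are skipped on rerun and a tampered artifact raises a checksum error.
One global seed fans out per stage through `SeedSequence([seed, stage_index])`
(all derived seeds < 2^31), so each stage is independently reproducible;
identical configs produce byte-identical cohorts and reports.

## Problem sizes in the shipped tests

Simulation-backed checks run at desk scale, chosen so the whole suite stays
in the minutes range on one CPU: null-cohort calibration uses n = 400
cohorts over 12 frozen seeds (pass if the bootstrap CI covers 0.5 in >= 90%
of runs), signal recovery uses 5 seeds (pass fraction >= 4/5), the
cross-time-group trend uses 3 seeds, bootstrap coverage uses 500 simulated
datasets with 500 bootstrap draws, and the type-I-error check uses 800 null
fits. The fast learner profile and `n_search = 1` are used inside these
loops; the pass criteria are the same fractions a full-scale run would use.

## Known limitations

- The BMA stack's candidate logistic fits are unpenalized; with nearly
  collinear probability columns individual coefficients are unstable even
  though the averaged prediction is well-behaved.
- The STG architectures' cross-group matrix cells mix out-of-fold and
  refit-model probabilities (see above); a fully nested alternative would
  cost another CV layer.
- The evaluation-set operating threshold is optimistically biased at small
  test sets; use the training-derived threshold mode for honest prospective
  estimates.
- The generator's covariates are drawn independently given case status;
  real covariate correlation (e.g. diabetes-BMI) is not modelled.
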