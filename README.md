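# serostack

Stacked ensemble learning for **pre-diagnostic serum-biomarker detection of
pancreatic ductal adenocarcinoma (PDAC)**.

PDAC is usually diagnosed too late for surgery. Prospectively collected
serum repositories make it possible to ask whether a panel of circulating
proteins (CA19-9, MUC16/CA125, THBS2, CEACAM5, VWF, IL6ST, …) plus clinical
covariates (age, BMI, HRT use, OCP use, diabetes) can flag future cases
months to years before clinical diagnosis. `serostack` re-implements that
analysis as a tested, reusable pipeline for anyone working with
nested case-control biomarker panels:

- **Cohort model & I/O** — delimited tables with below-LOD flags, years-to-
  diagnosis (YTD) time-grouping (single groups 0-1 … 4+, joined 0-1 … 0-4+),
  and a stratified train/test split.
- **Firth bias-reduced logistic regression** (written here, not wrapped) —
  the single-feature association engine. It maximizes the Jeffreys-prior
  penalized likelihood `l(β) + ½ log det I(β)`, stays finite under complete
  separation and zero cells, and reports profile-penalized-likelihood CIs
  and penalized-LRT p-values. For a 2×2 table it reduces to the
  add-½-to-every-cell closed form `OR = (a+½)(d+½) / ((b+½)(c+½))`.
- **Ten base-learner families** (boosted trees, RBF SVM, regularized random
  forest, PCA+neural net, Gaussian process, elastic net, bagged AdaBoost,
  gradient boosting, stepwise-AIC logistic, naive Bayes) trained by repeated
  stratified CV with minority oversampling inside training folds and random
  hyperparameter search; out-of-fold case probabilities feed the stack.
- **Stacked meta-learners** — BMA (BIC-weighted logistic model averaging
  with Occam's window), MEAN, GEOMEAN, MAX, AVNNET — in three architectures:
  JTG2L (joined time-group, 10 stack columns), STG2L (10 × G columns), STG3L
  (per-group BMA, then a top stack).
- **Evaluation** — Mann-Whitney AUC, stratified-bootstrap CIs, bootstrap ROC
  comparison, sensitivity/PPV/NPV/MCC at 90% specificity, cross-time-group
  matrices, prevalence rescans, Cohen-kappa learner diversity.
- **Importance** — partial-dependence variability (FIRM), scaled per model,
  median-aggregated across learners and time-groups.
- **External validation** — marginal performance under random allocation of
  never-collected covariates (e.g. HRT/OCP in a post-diagnosis cohort).
- **Synthetic cohorts** — a generator emulating the study structure
  (143 cases / 249 controls, longitudinal draws, marker effects growing
  toward diagnosis, LOD censoring), so everything is testable without
  access-controlled data.

See `docs/methods.md` for the models, defaults and limitations.

## Worked example

Covariate odds ratios from the discovery cohort's printed 2×2 counts
(`examples/01_covariate_odds_ratios.py`):

```text
HRT use at randomisation     OR = 0.41 (95% CI 0.23-0.70, p = 0.0011)
OCP use (ever)               OR = 1.47 (95% CI 1.02-2.13, p = 0.039)
Diabetes                     OR = 4.99 (95% CI 2.61-10.30, p = 3.1e-07)
```

Diabetes carries ~5-fold higher PDAC odds; HRT use is protective; all three
agree with the saturated-design closed form to far better than printed
precision.

An end-to-end JTG2L BMA stack on a synthetic cohort with five persistent
disease markers among 20 (`examples/03_jtg2l_stack.py`):

```text
test AUC = 0.972 (95% CI 0.948-0.991)
at 90% specificity: sensitivity 0.93, PPV 0.87, NPV 0.95, MCC 0.83
```

The AUC CI (stratified bootstrap) excludes 0.5; at the 90%-specificity
operating point 93% of held-out pre-diagnosis case samples are flagged.
These numbers describe the synthetic cohort, not clinical performance.

The other scripts in `examples/` cover ranking (`02`), feature importance
(`04`, the dominant simulated marker is scaled to 1 across learners) and
external validation with randomized missing covariates (`05`).

## Command line

```bash
serostack simulate --out cohort.csv --seed 1
serostack split    --cohort cohort.csv --out split.csv
serostack rank     --cohort cohort.csv --out ranking.csv
serostack train-base --cohort cohort.csv --ranking ranking.csv --out base/
serostack stack    --base base/ --arch jtg2l --stack bma --out model.joblib
serostack evaluate --model model.joblib --test test.csv --out report.json
serostack run      --config pipeline.yaml     # full pipeline, cached stages
```

`run` executes simulate → split → rank → train-base → stack → evaluate →
importance → validate-external from one YAML config, records checksums in a
manifest, and skips unchanged stages on rerun.

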