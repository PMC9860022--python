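"""Validate a frozen stack on an external cohort lacking HRT/OCP records.

The external set is post-diagnosis, mixed-sex, and never collected HRT or
OCP use.  Performance is marginalized over random yes/no allocations of the
missing covariates to the women (men are fixed 'no'); a narrow spread across
allocations shows the panel does not hinge on the missing covariates.
"""

from serostack import assign_time_groups, simulate_cohort, stratified_split
from serostack.external import marginal_validate
from serostack.learners import CVPlan, load_search_spaces
from serostack.simulate import MarkerEffect, SimulationConfig, simulate_external_set
from serostack.stacking import build_jtg2l

cfg = SimulationConfig(
    n_cases=100, n_controls=200, n_markers=10,
    effects=tuple(MarkerEffect(f"M{i:03d}", 0.8, 50.0) for i in range(1, 5)),
    seed=41,
)
cohort = assign_time_groups(simulate_cohort(cfg))
part = stratified_split(cohort, seed=42)
train = cohort.subset((part == "train").to_numpy())

panel = cohort.marker_cols[:6] + ["age", "hrt", "ocp", "diabetes"]
model = build_jtg2l(
    train, "0-4+", panel, "bma",
    plan=CVPlan(n_folds=4, n_repeats=1, seed=43), n_search=1, seed=43,
    spaces=load_search_spaces(profile="fast"), max_subset=2,
)

external = simulate_external_set(cfg, ("hrt", "ocp"), n_cases=17, n_controls=17)
report = marginal_validate(model, external, n_rand=200, seed=44)
med, iqr = report.medians, report.iqr
print(f"marginal AUC over 200 random HRT/OCP allocations: "
      f"median {med['auc']:.3f} (IQR {iqr['auc']:.3f})")
print(f"at 90% specificity: sensitivity {med['sensitivity']:.2f}, "
      f"PPV {med['ppv']:.2f}, NPV {med['npv']:.2f}")
mean, lo, hi = report.mean_ci.loc["auc"]
print(f"bootstrap mean AUC {mean:.3f} (95% CI {lo:.3f}-{hi:.3f})")
print("\nA small IQR relative to the AUC itself means the missing "
      "covariates barely move the prediction.")
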