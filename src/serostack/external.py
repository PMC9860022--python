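"""External validation under randomly imputed missing covariates.

When a frozen ensemble's panel contains covariates an external cohort never
collected (e.g. HRT and OCP use), marginal performance is estimated by
scoring many replicates of the cohort, each with the missing yes/no
covariates drawn at random for the women (men are always 'no'), and reporting
the distribution of AUC and fixed-specificity metrics across replicates.  A
small dispersion shows the missing covariates do not dominate the panel.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cohort import Cohort, CohortError
from .evaluation import metrics_at_specificity, roc_auc
from .stacking import StackModel, predict

__all__ = ["MarginalValidationReport", "marginal_validate", "DEFAULT_P_YES"]

# discovery-cohort control-arm marginal frequencies (HRT 48/249, OCP 127/249)
DEFAULT_P_YES = {"hrt": 0.11, "ocp": 0.51}


@dataclass
class MarginalValidationReport:
    metrics: pd.DataFrame  # one row per randomization
    medians: pd.Series
    iqr: pd.Series
    mean_ci: pd.DataFrame  # bootstrap CI of the mean per metric
    n_randomizations: int

    def to_dict(self) -> dict:
        return {
            "n_randomizations": self.n_randomizations,
            "median": self.medians.to_dict(),
            "iqr": self.iqr.to_dict(),
            "mean_ci": {k: list(v) for k, v in self.mean_ci.iterrows()},
        }


def marginal_validate(
    model: StackModel,
    external: Cohort,
    missing: tuple[str, ...] = ("hrt", "ocp"),
    n_rand: int = 1000,
    p_yes: dict | None = None,
    mode: str = "frequency",
    spec_target: float = 0.90,
    seed: int = 0,
    n_boot: int = 500,
) -> MarginalValidationReport:
    """Marginalize a frozen model's performance over random allocations of
    never-collected yes/no covariates.

    ``mode="frequency"`` draws each covariate at its discovery-cohort control
    frequency (or ``p_yes``); ``mode="uniform"`` draws at probability 0.5.
    Women get random draws; men are fixed to 'no'.
    """
    missing_in_panel = [c for c in missing if c in model.panel]
    for cov in missing_in_panel:
        if cov in external.df.columns and external.df[cov].notna().any():
            raise CohortError(f"covariate {cov!r} is present in the external cohort")
    # any other panel feature must be observed
    for f in model.panel:
        if f in missing_in_panel:
            continue
        if f not in external.df.columns or external.df[f].isna().all():
            raise CohortError(f"external cohort lacks model feature {f!r}")
    if not missing_in_panel:
        raise CohortError(
            "no randomizable covariates: model panel contains none of "
            f"{list(missing)}"
        )
    p_yes = {**DEFAULT_P_YES, **(p_yes or {})}
    y = external.status.to_numpy()
    sex = external.df.get("sex", pd.Series("female", index=external.df.index))
    women = (sex.astype(str).str.lower() != "male").to_numpy()

    rng = np.random.default_rng(seed)
    rows = []
    for _ in range(n_rand):
        df = external.df.copy()
        for cov in missing_in_panel:
            p = 0.5 if mode == "uniform" else float(p_yes[cov])
            alloc = np.where(rng.random(len(df)) < p, "yes", "no")
            alloc[~women] = "no"
            df[cov] = alloc
        replicate = Cohort(df, list(external.marker_cols), external.low_mask.copy())
        scores = predict(model, replicate)
        thr, sens, ppv, npv, mcc = metrics_at_specificity(scores, y, spec_target)
        rows.append(
            {"auc": roc_auc(scores, y), "sensitivity": sens, "ppv": ppv,
             "npv": npv, "mcc": mcc}
        )
    metrics = pd.DataFrame(rows)
    medians = metrics.median()
    iqr = metrics.quantile(0.75) - metrics.quantile(0.25)
    # bootstrap CI of the mean of each metric across randomizations
    idx = rng.integers(0, len(metrics), size=(n_boot, len(metrics)))
    ci_rows = {}
    for col in metrics.columns:
        v = metrics[col].to_numpy()
        means = v[idx].mean(axis=1)
        ci_rows[col] = (float(v.mean()), *np.quantile(means, [0.025, 0.975]))
    mean_ci = pd.DataFrame(ci_rows, index=["mean", "ci_low", "ci_high"]).T
    return MarginalValidationReport(metrics, medians, iqr, mean_ci, n_rand)
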