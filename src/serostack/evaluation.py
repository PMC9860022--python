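"""ROC/AUC evaluation with stratified bootstrap inference.

AUC is the tie-aware Mann-Whitney statistic: the probability that a random
case scores above a random control, counting ties as 1/2.  Confidence
intervals resample cases and controls separately (stratified bootstrap,
percentile interval); ROC curves are compared with a paired bootstrap test.
Operating-point metrics (sensitivity, PPV, NPV, MCC) are reported at a fixed
specificity, by default 90%, the screening-literature convention.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import cohen_kappa_score

__all__ = [
    "PerformanceReport",
    "roc_auc",
    "auc_ci_stratified_bootstrap",
    "compare_roc_bootstrap",
    "metrics_at_specificity",
    "metrics_at_threshold",
    "performance_report",
    "cross_time_group_matrix",
    "prevalence_rescan",
    "pairwise_kappa",
]


@dataclass
class PerformanceReport:
    auc: float
    auc_ci: tuple[float, float]
    significant: bool  # CI excludes 0.5
    threshold: float
    sensitivity: float
    ppv: float
    npv: float
    mcc: float
    spec_target: float
    n_cases: int
    n_controls: int
    group: str | None = None
    extras: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        d = {
            "auc": self.auc,
            "auc_ci_low": self.auc_ci[0],
            "auc_ci_high": self.auc_ci[1],
            "significant": self.significant,
            "threshold": self.threshold,
            "sensitivity": self.sensitivity,
            "ppv": self.ppv,
            "npv": self.npv,
            "mcc": self.mcc,
            "spec_target": self.spec_target,
            "n_cases": self.n_cases,
            "n_controls": self.n_controls,
            "group": self.group,
        }
        d.update(self.extras)
        return d


def _check_classes(y):
    y = np.asarray(y, dtype=int)
    if y.min() == y.max():
        raise ValueError("both outcome classes are required")
    return y


def roc_auc(scores, y) -> float:
    """Tie-aware Mann-Whitney AUC."""
    y = _check_classes(y)
    scores = np.asarray(scores, dtype=float)
    n1 = int(y.sum())
    n0 = len(y) - n1
    ranks = stats.rankdata(scores)
    return float((ranks[y == 1].sum() - n1 * (n1 + 1) / 2.0) / (n1 * n0))


def _auc_matrix(case_scores: np.ndarray, ctrl_scores: np.ndarray) -> np.ndarray:
    """Row-wise AUC for matrices of resampled case/control scores."""
    n1 = case_scores.shape[1]
    n0 = ctrl_scores.shape[1]
    both = np.concatenate([case_scores, ctrl_scores], axis=1)
    ranks = stats.rankdata(both, axis=1)
    return (ranks[:, :n1].sum(axis=1) - n1 * (n1 + 1) / 2.0) / (n1 * n0)


def auc_ci_stratified_bootstrap(
    scores, y, n_boot: int = 2000, level: float = 0.95, seed: int = 0
) -> tuple[float, float]:
    """Percentile bootstrap CI for the AUC, resampling within each class."""
    if n_boot < 100:
        raise ValueError("n_boot must be at least 100")
    y = _check_classes(y)
    scores = np.asarray(scores, dtype=float)
    rng = np.random.default_rng(seed)
    case = scores[y == 1]
    ctrl = scores[y == 0]
    ci = rng.integers(0, len(case), size=(n_boot, len(case)))
    ki = rng.integers(0, len(ctrl), size=(n_boot, len(ctrl)))
    aucs = _auc_matrix(case[ci], ctrl[ki])
    alpha = (1.0 - level) / 2.0
    lo, hi = np.quantile(aucs, [alpha, 1.0 - alpha])
    return float(lo), float(hi)


def compare_roc_bootstrap(scores_a, scores_b, y, n_boot: int = 2000, seed: int = 0) -> float:
    """Paired stratified bootstrap test for AUC difference; two-sided p."""
    y = _check_classes(y)
    a = np.asarray(scores_a, dtype=float)
    b = np.asarray(scores_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired scores must share samples")
    rng = np.random.default_rng(seed)
    case_idx = np.flatnonzero(y == 1)
    ctrl_idx = np.flatnonzero(y == 0)
    ci = case_idx[rng.integers(0, len(case_idx), size=(n_boot, len(case_idx)))]
    ki = ctrl_idx[rng.integers(0, len(ctrl_idx), size=(n_boot, len(ctrl_idx)))]
    diffs = _auc_matrix(a[ci], a[ki]) - _auc_matrix(b[ci], b[ki])
    sd = diffs.std(ddof=1)
    if sd == 0.0:
        return 1.0
    d_obs = roc_auc(a, y) - roc_auc(b, y)
    return float(2.0 * stats.norm.sf(abs(d_obs) / sd))


def metrics_at_specificity(scores, y, spec_target: float = 0.90):
    """Operating point maximizing sensitivity subject to specificity >= target.

    A sample is called positive when its score exceeds the threshold, so
    controls exactly at the threshold count as negative.  Returns
    (threshold, sensitivity, ppv, npv, mcc).
    """
    y = _check_classes(y)
    scores = np.asarray(scores, dtype=float)
    case = scores[y == 1]
    ctrl = scores[y == 0]
    n0 = len(ctrl)
    # candidate thresholds: control order statistics (specificity changes there)
    cand = np.unique(ctrl)
    specs = np.searchsorted(np.sort(ctrl), cand, side="right") / n0
    ok = specs >= spec_target
    if not ok.any():
        thr = np.inf
        warnings.warn("specificity target unreachable; no positive calls made")
    else:
        thr = float(cand[ok][0])  # lowest admissible threshold = max sensitivity
    tp = int((case > thr).sum())
    fn = len(case) - tp
    fp = int((ctrl > thr).sum())
    tn = n0 - fp
    sens = tp / len(case)
    ppv = tp / (tp + fp) if tp + fp else 0.0
    npv = tn / (tn + fn) if tn + fn else 0.0
    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    mcc = (tp * tn - fp * fn) / np.sqrt(denom) if denom else 0.0
    return thr, sens, ppv, npv, float(mcc)


def metrics_at_threshold(scores, y, threshold: float):
    """Confusion metrics at a pre-specified (e.g. training-derived) cutoff."""
    y = _check_classes(y)
    scores = np.asarray(scores, dtype=float)
    case = scores[y == 1]
    ctrl = scores[y == 0]
    tp = int((case > threshold).sum())
    fn = len(case) - tp
    fp = int((ctrl > threshold).sum())
    tn = len(ctrl) - fp
    sens = tp / len(case)
    ppv = tp / (tp + fp) if tp + fp else 0.0
    npv = tn / (tn + fn) if tn + fn else 0.0
    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    mcc = (tp * tn - fp * fn) / np.sqrt(denom) if denom else 0.0
    return sens, ppv, npv, float(mcc)


def performance_report(
    scores,
    y,
    spec_target: float = 0.90,
    n_boot: int = 2000,
    seed: int = 0,
    group: str | None = None,
    threshold: float | None = None,
) -> PerformanceReport:
    """Full report; pass ``threshold`` to evaluate at a training-derived
    cutoff instead of re-optimizing the operating point on this data."""
    auc = roc_auc(scores, y)
    lo, hi = auc_ci_stratified_bootstrap(scores, y, n_boot=n_boot, seed=seed)
    if threshold is None:
        thr, sens, ppv, npv, mcc = metrics_at_specificity(scores, y, spec_target)
    else:
        thr = threshold
        sens, ppv, npv, mcc = metrics_at_threshold(scores, y, threshold)
    y = np.asarray(y, dtype=int)
    return PerformanceReport(
        auc=auc,
        auc_ci=(lo, hi),
        significant=not (lo <= 0.5 <= hi),
        threshold=thr,
        sensitivity=sens,
        ppv=ppv,
        npv=npv,
        mcc=mcc,
        spec_target=spec_target,
        n_cases=int(y.sum()),
        n_controls=int((1 - y).sum()),
        group=group,
    )


def cross_time_group_matrix(
    models: dict, test_cohort, joined_groups=None, n_boot: int = 500, seed: int = 0
) -> pd.DataFrame:
    """Train-group x eval-group performance matrix.

    ``models`` maps joined-group label -> fitted stack model.  Entry (g, h)
    evaluates model g on the test cases of joined group h together with all
    test controls.  Empty evaluation groups yield NA with a warning.
    Cell values are PerformanceReport objects.
    """
    from .stacking import predict  # deferred: avoids an import cycle

    joined_groups = list(joined_groups or models.keys())
    out = pd.DataFrame(index=list(models.keys()), columns=joined_groups, dtype=object)
    for g, model in models.items():
        for h in joined_groups:
            sub = test_cohort.time_group_subset(h)
            y = sub.status.to_numpy()
            if y.sum() == 0 or (1 - y).sum() == 0:
                warnings.warn(f"evaluation group {h!r} has one class only; NA entry")
                out.loc[g, h] = None
                continue
            scores = predict(model, sub)
            out.loc[g, h] = performance_report(
                scores, y, n_boot=n_boot, seed=seed, group=h
            )
    return out


def analytic_ppv(sens: float, spec: float, prevalence: float) -> float:
    return sens * prevalence / (sens * prevalence + (1 - spec) * (1 - prevalence))


def prevalence_rescan(
    scores,
    y,
    prevalences,
    n_rep: int = 100,
    spec_target: float = 0.90,
    seed: int = 0,
) -> pd.DataFrame:
    """Re-estimate operating-point metrics at shifted disease prevalence.

    For each target prevalence the test set is down-sampled (in whichever
    class is over-represented) ``n_rep`` times and the metrics recomputed.
    The analytic PPV sens*p / (sens*p + (1-spec)*(1-p)) at the full-data
    operating point is reported alongside as a cross-check.
    """
    y = _check_classes(y)
    scores = np.asarray(scores, dtype=float)
    rng = np.random.default_rng(seed)
    case = scores[y == 1]
    ctrl = scores[y == 0]
    n1, n0 = len(case), len(ctrl)
    _, sens0, _, _, _ = metrics_at_specificity(scores, y, spec_target)
    rows = []
    for p in prevalences:
        if not 0 < p < 1:
            raise ValueError(f"prevalence {p} out of range")
        # keep the larger class count feasible by down-sampling one class
        if p <= n1 / (n1 + n0):
            keep1 = max(2, int(round(p / (1 - p) * n0)))
            keep0 = n0
        else:
            keep0 = max(2, int(round((1 - p) / p * n1)))
            keep1 = n1
        if keep1 > n1 or keep0 > n0:
            raise ValueError(f"prevalence {p} not achievable by down-sampling")
        for _ in range(n_rep):
            s1 = case[rng.choice(n1, size=keep1, replace=False)]
            s0 = ctrl[rng.choice(n0, size=keep0, replace=False)]
            sub_scores = np.concatenate([s1, s0])
            sub_y = np.concatenate([np.ones(keep1, int), np.zeros(keep0, int)])
            _, sens, ppv, npv, mcc = metrics_at_specificity(sub_scores, sub_y, spec_target)
            rows.append(
                {
                    "prevalence": p,
                    "auc": roc_auc(sub_scores, sub_y),
                    "sensitivity": sens,
                    "ppv": ppv,
                    "npv": npv,
                    "mcc": mcc,
                    "ppv_analytic": analytic_ppv(sens0, spec_target, p),
                }
            )
    return pd.DataFrame(rows)


def pairwise_kappa(P: pd.DataFrame, y, spec_target: float = 0.90) -> pd.DataFrame:
    """Cohen's kappa between base-learner calls dichotomized at fixed specificity.

    Each probability column gets its own threshold at ``spec_target``; the
    kappa of every column pair measures classifier diversity (low kappa =
    diverse ensemble).  Constant columns give NA off-diagonal entries.
    """
    if P.shape[1] < 2:
        raise ValueError("need at least two probability columns")
    y = _check_classes(y)
    calls = {}
    for col in P.columns:
        thr, *_ = metrics_at_specificity(P[col].to_numpy(), y, spec_target)
        calls[col] = (P[col].to_numpy() > thr).astype(int)
    cols = list(P.columns)
    out = pd.DataFrame(np.eye(len(cols)), index=cols, columns=cols)
    for i, a in enumerate(cols):
        for j in range(i + 1, len(cols)):
            b = cols[j]
            if calls[a].std() == 0 or calls[b].std() == 0:
                k = np.nan
            else:
                k = cohen_kappa_score(calls[a], calls[b])
            out.iloc[i, j] = out.iloc[j, i] = k
    return out
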