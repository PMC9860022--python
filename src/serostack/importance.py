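"""Model-agnostic feature importance via partial-dependence variability (FIRM).

For a fitted classifier and a feature j, the partial-dependence function
f_bar(x_j) is the model's mean case probability when x_j is clamped to a grid
value and all other features keep their empirical joint distribution.  The
raw importance is the standard deviation of f_bar over the grid (half the
range for two-level features): a feature the model ignores scores 0.  Raw
importances are scaled to [0, 1] within each (learner, time-group) model by
dividing by the model's maximum, and summarized per feature as the median
scaled importance across all (learner, group) cells.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .learners import TrainedLearner, predict_proba1

__all__ = ["firm_importance", "model_importances", "scale_and_aggregate"]


def _pd_profile(model, X: np.ndarray, j: int, grid: np.ndarray) -> np.ndarray:
    work = X.copy()
    out = np.empty(len(grid))
    for g, value in enumerate(grid):
        work[:, j] = value
        out[g] = predict_proba1(model, work).mean()
    return out


def firm_importance(
    learner: TrainedLearner,
    X: pd.DataFrame,
    feature: str,
    grid_size: int = 20,
    max_rows: int = 2000,
    seed: int = 0,
) -> float:
    """Raw FIRM importance of one feature for one trained base learner.

    ``X`` must carry the learner's feature panel (training data by default).
    Rows are subsampled (seeded) above ``max_rows`` to bound the averaging.
    """
    if feature not in learner.panel:
        raise KeyError(f"feature {feature!r} not in the model panel")
    Xa = X[learner.panel].to_numpy(dtype=float)
    if len(Xa) > max_rows:
        rng = np.random.default_rng(seed)
        Xa = Xa[rng.choice(len(Xa), size=max_rows, replace=False)]
    j = learner.panel.index(feature)
    levels = np.unique(Xa[:, j])
    if len(levels) <= 1:
        return 0.0
    if len(levels) == 2:
        profile = _pd_profile(learner.model, Xa, j, levels)
        return float(np.ptp(profile) / 2.0)
    qs = np.linspace(0.0, 1.0, grid_size)
    grid = np.unique(np.quantile(Xa[:, j], qs))
    profile = _pd_profile(learner.model, Xa, j, grid)
    return float(np.std(profile))


def model_importances(
    learner: TrainedLearner, X: pd.DataFrame, grid_size: int = 20, seed: int = 0
) -> pd.Series:
    """Raw importances of every panel feature for one model."""
    vals = {
        f: firm_importance(learner, X, f, grid_size=grid_size, seed=seed)
        for f in learner.panel
    }
    return pd.Series(vals, name=learner.family)


def scale_and_aggregate(raw: dict) -> pd.DataFrame:
    """Scale raw importances within each (learner, group) model and summarize.

    ``raw`` maps (learner_family, group) -> Series of raw importances per
    feature.  Output: one row per feature, one column per (learner, group)
    holding the scaled importance, plus a ``median_importance`` column (the
    per-feature median across cells).  All-zero models stay at 0 with a
    warning.
    """
    if not raw:
        raise ValueError("need at least one model's importances")
    cols = {}
    for key, series in raw.items():
        label = "@".join(key) if isinstance(key, tuple) else str(key)
        mx = float(series.max())
        if mx <= 0:
            warnings.warn(f"model {label}: all importances zero")
            cols[label] = series.astype(float)
        else:
            cols[label] = series.astype(float) / mx
    table = pd.DataFrame(cols)
    table["median_importance"] = table.median(axis=1)
    return table.sort_values("median_importance", ascending=False)
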