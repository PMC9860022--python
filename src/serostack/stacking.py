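"""Meta-learners and stacking architectures.

Base-learner case probabilities are combined by one of four stacks:

* **BMA** — Bayesian model averaging over logistic regressions on subsets of
  the probability columns, weighted by exp(-BIC/2) with Occam's-window
  pruning; the only fitted (schema-bound) stack.
* **MEAN / GEOMEAN / MAX** — parameter-free row-wise pooling.
* **AVNNET** — a committee of small feed-forward networks averaged over
  random initializations (single-time-group architecture only).

Three architectures assemble the probability matrix:

* **JTG2L** (joined time group, 2 layers): 10 learners trained on all samples
  of a joined group; the stack sees 10 columns.
* **STG2L** (single time groups, 2 layers): 10 learners per single group; the
  stack sees 10 x G concatenated columns.
* **STG3L** (3 layers): a BMA stack per single group first, then a top stack
  over the G group-level probabilities.

Stacking inputs are out-of-fold probabilities wherever a sample belonged to a
model's training subset, so meta-learning never sees resubstitution scores;
rows outside a single-group model's subset are filled with the refit model's
predictions to align the concatenated matrix.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from sklearn.linear_model import LogisticRegression
from sklearn.neural_network import MLPClassifier
from sklearn.preprocessing import StandardScaler

from .cohort import Cohort, CohortError, TimeGroupScheme, build_design, impute_low
from .evaluation import roc_auc
from .learners import (
    FAMILIES,
    PROB_CLIP,
    CVPlan,
    make_cv_plan,
    predict_proba1,
    train_layer,
)

__all__ = [
    "BaseLayer",
    "StackModel",
    "BMAStack",
    "PoolingStack",
    "AVNNetStack",
    "fit_bma_stack",
    "fit_pooling_stack",
    "fit_stack",
    "train_base_layer",
    "fit_stack_model",
    "build_jtg2l",
    "build_stg2l",
    "build_stg3l",
    "predict",
    "meta_cv_auc",
]


class BMAStack:
    """BIC-weighted average of logistic regressions over column subsets."""

    def __init__(self, occam_odds: float = 20.0, max_subset: int | None = None,
                 screen_top: int = 12):
        self.occam_odds = occam_odds
        self.max_subset = max_subset
        self.screen_top = screen_top

    @staticmethod
    def _bic_fit(X, y):
        lr = LogisticRegression(C=np.inf, max_iter=1000)
        lr.fit(X, y)
        p = np.clip(lr.predict_proba(X)[:, 1], 1e-12, 1 - 1e-12)
        ll = float(np.sum(y * np.log(p) + (1 - y) * np.log(1 - p)))
        k = X.shape[1] + 1
        return k * np.log(len(y)) - 2 * ll, lr

    def fit(self, P: pd.DataFrame, y):
        y = np.asarray(y, dtype=int)
        if len(np.unique(y)) < 2:
            raise ValueError("both classes required to fit a BMA stack")
        self.schema_ = list(P.columns)
        cols = list(P.columns)
        Pa = P.to_numpy(dtype=float)
        if not ((Pa >= 0) & (Pa <= 1)).all():
            raise ValueError("probability matrix entries must lie in [0, 1]")
        # exhaustive enumeration is feasible up to ~12 columns; beyond that,
        # screen to the best single columns by BIC first
        if len(cols) > self.screen_top:
            singles = sorted(
                range(len(cols)), key=lambda j: self._bic_fit(Pa[:, [j]], y)[0]
            )[: self.screen_top]
            pool = [cols[j] for j in singles]
        else:
            pool = cols
        max_size = self.max_subset or len(pool)
        candidates = []
        for size in range(1, min(max_size, len(pool)) + 1):
            candidates.extend(combinations(pool, size))
        fits, bics = [], []
        for subset in candidates:
            idx = [cols.index(c) for c in subset]
            try:
                bic, lr = self._bic_fit(Pa[:, idx], y)
            except Exception:  # noqa: BLE001 - skip pathological subsets
                continue
            fits.append((list(subset), idx, lr))
            bics.append(bic)
        if not fits:
            raise RuntimeError("every candidate logistic fit failed")
        bics = np.asarray(bics)
        w = np.exp(-0.5 * (bics - bics.min()))
        # Occam's window: drop models too implausible relative to the best
        keep = (w.max() / w) <= self.occam_odds
        w = w[keep] / w[keep].sum()
        self.models_ = [f for f, k in zip(fits, keep) if k]
        self.weights_ = w
        self.bic_ = bics[keep]
        return self

    def predict(self, P: pd.DataFrame) -> np.ndarray:
        Pa = P[self.schema_].to_numpy(dtype=float)
        out = np.zeros(len(P))
        for (subset, idx, lr), w in zip(self.models_, self.weights_):
            cols = [self.schema_.index(c) for c in subset]
            out += w * lr.predict_proba(Pa[:, cols])[:, 1]
        return np.clip(out, 0.0, 1.0)

    def column_weight(self, column: str) -> float:
        """Total posterior weight on models containing ``column``."""
        return float(
            sum(w for (subset, _i, _m), w in zip(self.models_, self.weights_)
                if column in subset)
        )


class PoolingStack:
    """Parameter-free row-wise pooling: MEAN, GEOMEAN or MAX."""

    def __init__(self, kind: str):
        kind = kind.lower()
        if kind not in ("mean", "geomean", "max"):
            raise ValueError(f"unknown pooling kind {kind!r}")
        self.kind = kind

    def fit(self, P: pd.DataFrame, y=None):
        self.schema_ = list(P.columns)
        return self

    def predict(self, P: pd.DataFrame) -> np.ndarray:
        Pa = P[self.schema_].to_numpy(dtype=float)
        if self.kind == "mean":
            return Pa.mean(axis=1)
        if self.kind == "geomean":
            return np.exp(np.log(np.clip(Pa, PROB_CLIP, 1.0)).mean(axis=1))
        return Pa.max(axis=1)


class AVNNetStack:
    """Averaged committee of small feed-forward networks (STG2L only)."""

    def __init__(self, n_nets: int = 5, hidden: int = 5, seed: int = 0):
        self.n_nets = n_nets
        self.hidden = hidden
        self.seed = seed

    def fit(self, P: pd.DataFrame, y):
        self.schema_ = list(P.columns)
        self.scaler_ = StandardScaler().fit(P.to_numpy(dtype=float))
        X = self.scaler_.transform(P.to_numpy(dtype=float))
        self.nets_ = []
        for i in range(self.n_nets):
            net = MLPClassifier(
                hidden_layer_sizes=(self.hidden,),
                max_iter=300,
                tol=1e-3,
                random_state=self.seed + i,
            )
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                net.fit(X, np.asarray(y, dtype=int))
            self.nets_.append(net)
        return self

    def predict(self, P: pd.DataFrame) -> np.ndarray:
        X = self.scaler_.transform(P[self.schema_].to_numpy(dtype=float))
        return np.mean([predict_proba1(net, X) for net in self.nets_], axis=0)


def fit_bma_stack(P: pd.DataFrame, y, occam_odds: float = 20.0,
                  max_subset: int | None = None) -> BMAStack:
    return BMAStack(occam_odds=occam_odds, max_subset=max_subset).fit(P, y)


def fit_pooling_stack(P: pd.DataFrame, kind: str) -> PoolingStack:
    return PoolingStack(kind).fit(P)


def fit_stack(P: pd.DataFrame, y, kind: str, seed: int = 0, occam_odds: float = 20.0,
              max_subset: int | None = None):
    kind = kind.lower()
    if kind == "bma":
        return fit_bma_stack(P, y, occam_odds=occam_odds, max_subset=max_subset)
    if kind == "avnnet":
        return AVNNetStack(seed=seed).fit(P, y)
    return fit_pooling_stack(P, kind)


def meta_cv_auc(P: pd.DataFrame, y, kind: str, plan: CVPlan | None = None,
                seed: int = 0, **stack_kwargs) -> np.ndarray:
    """Cross-validated AUCs of a stack refitted per meta fold (no oversampling)."""
    plan = plan or CVPlan(n_folds=10, n_repeats=10, oversample=False)
    y = np.asarray(y, dtype=int)
    aucs = []
    for _, _, tr, va in make_cv_plan(y, plan):
        stack = fit_stack(P.iloc[tr], y[tr], kind, seed=seed, **stack_kwargs)
        p = stack.predict(P.iloc[va])
        if len(np.unique(y[va])) == 2:
            aucs.append(roc_auc(p, y[va]))
    return np.asarray(aucs)


@dataclass
class BaseLayer:
    """A trained base-learner layer plus the matrix its stack trains on."""

    architecture: str  # jtg2l | stg
    joined_group: str
    panel: list[str]
    low_impute: dict
    groups: list[str]  # single groups for stg, [joined_group] for jtg2l
    base: dict  # column name -> (TrainedLearner, group)
    group_masks: dict  # group -> boolean row mask over P's rows
    P: pd.DataFrame  # stack training matrix
    y: np.ndarray
    sample_ids: list[str]
    scheme: TimeGroupScheme = field(default_factory=TimeGroupScheme)


@dataclass
class StackModel:
    """A frozen ensemble: base learners, their stack, and provenance."""

    architecture: str  # jtg2l | stg2l | stg3l
    stack_kind: str
    group: str  # joined training group ("0-4+" for STG*)
    panel: list[str]
    low_impute: dict
    base: dict  # column name -> (TrainedLearner, group trained on)
    stack: object
    group_stacks: dict = field(default_factory=dict)  # STG3L: group -> BMAStack
    meta_cv_aucs: np.ndarray | None = None
    scheme: TimeGroupScheme = field(default_factory=TimeGroupScheme)

    @property
    def meta_cv_auc(self) -> float | None:
        if self.meta_cv_aucs is None:
            return None
        return float(np.nanmean(self.meta_cv_aucs))


def _prepare_training(cohort: Cohort, panel):
    """Impute LOW by half-min on the training cohort, remembering the values."""
    low_impute = {}
    for m in cohort.marker_cols:
        if m not in panel or not cohort.low_mask[m].any():
            continue
        observed = cohort.df[m].dropna()
        if observed.empty:
            raise CohortError(f"marker {m!r}: all values below LOD")
        low_impute[m] = float(observed.min()) / 2.0
    return impute_low(cohort), low_impute


def train_base_layer(
    train_cohort: Cohort,
    architecture: str,
    panel: list[str],
    joined_group: str = "0-4+",
    plan: CVPlan = CVPlan(),
    n_search: int = 25,
    families=FAMILIES,
    seed: int = 0,
    scheme: TimeGroupScheme = TimeGroupScheme(),
    spaces: dict | None = None,
) -> BaseLayer:
    """Train the base layer for an architecture.

    ``architecture`` is "jtg2l" (one layer on the joined group) or "stg"
    (one layer per single time-group; shared by STG2L and STG3L).
    """
    if architecture == "jtg2l":
        sub = train_cohort.time_group_subset(joined_group, scheme)
        y = sub.status.to_numpy()
        if y.sum() == 0 or (1 - y).sum() == 0:
            raise CohortError(f"joined group {joined_group!r} lacks one class")
        sub, low_impute = _prepare_training(sub, panel)
        X = build_design(sub, panel)
        learners = train_layer(X, y, plan, n_search, families, spaces, seed=seed)
        P = pd.DataFrame(
            {f"{fam}@{joined_group}": tl.oof for fam, tl in learners.items()},
            index=sub.df.index,
        ).clip(PROB_CLIP, 1 - PROB_CLIP)
        base = {f"{fam}@{joined_group}": (tl, joined_group) for fam, tl in learners.items()}
        masks = {joined_group: np.ones(len(y), dtype=bool)}
        return BaseLayer("jtg2l", joined_group, list(panel), low_impute,
                         [joined_group], base, masks, P, y,
                         sub.df["sample_id"].tolist(), scheme)
    if architecture != "stg":
        raise ValueError(f"unknown base-layer architecture {architecture!r}")

    full, low_impute = _prepare_training(train_cohort, panel)
    if "time_group" not in full.df.columns:
        raise CohortError("assign_time_groups must be called before stacking")
    y = full.status.to_numpy()
    X_full = build_design(full, panel).to_numpy(dtype=float)
    groups = [g for g in scheme.single_names if (full.df["time_group"] == g).any()]
    if not groups:
        raise CohortError("no single time-group contains cases")
    base, masks, blocks = {}, {}, []
    for gi, g in enumerate(groups):
        mask = ((full.df["status"] == 0) | (full.df["time_group"] == g)).to_numpy()
        sub = full.subset(mask)
        ysub = sub.status.to_numpy()
        if ysub.sum() == 0:
            raise CohortError(f"single time-group {g!r} has no cases")
        X = build_design(sub, panel)
        learners = train_layer(X, ysub, plan, n_search, families, spaces, seed=seed + gi)
        cols = {}
        for fam, tl in learners.items():
            vals = np.empty(len(y))
            vals[mask] = tl.oof
            if (~mask).any():
                vals[~mask] = predict_proba1(tl.model, X_full[~mask])
            cols[f"{fam}@{g}"] = np.clip(vals, PROB_CLIP, 1 - PROB_CLIP)
            base[f"{fam}@{g}"] = (tl, g)
        blocks.append(pd.DataFrame(cols, index=full.df.index))
        masks[g] = mask
    P = pd.concat(blocks, axis=1)
    return BaseLayer("stg", "0-4+", list(panel), low_impute, groups, base,
                     masks, P, y, full.df["sample_id"].tolist(), scheme)


def fit_stack_model(
    layer: BaseLayer,
    architecture: str,
    stack_kind: str = "bma",
    seed: int = 0,
    occam_odds: float = 20.0,
    max_subset: int | None = None,
    meta_plan: CVPlan | None = None,
    compute_meta_cv: bool = False,
) -> StackModel:
    """Fit the meta-learner(s) of an architecture on a trained base layer."""
    kind = stack_kind.lower()
    if kind == "avnnet" and architecture != "stg2l":
        raise ValueError("AVNNET is reserved for the STG2L architecture")
    kwargs = {"occam_odds": occam_odds, "max_subset": max_subset}
    group_stacks = {}
    if architecture in ("jtg2l", "stg2l"):
        if (architecture == "jtg2l") != (layer.architecture == "jtg2l"):
            raise ValueError("base layer does not match the requested architecture")
        P_top = layer.P
    elif architecture == "stg3l":
        if layer.architecture != "stg":
            raise ValueError("STG3L needs a single-time-group base layer")
        mid = {}
        for g in layer.groups:
            cols = [c for c in layer.P.columns if c.endswith(f"@{g}")]
            mask = layer.group_masks[g]
            gstack = fit_bma_stack(layer.P.loc[mask, cols], layer.y[mask], **kwargs)
            group_stacks[g] = gstack
            mid[f"bma@{g}"] = gstack.predict(layer.P[cols])
        P_top = pd.DataFrame(mid, index=layer.P.index).clip(PROB_CLIP, 1 - PROB_CLIP)
    else:
        raise ValueError(f"unknown architecture {architecture!r}")
    stack = fit_stack(P_top, layer.y, kind, seed=seed, **kwargs)
    meta = None
    if compute_meta_cv:
        meta = meta_cv_auc(P_top, layer.y, kind, meta_plan, seed=seed, **kwargs)
    return StackModel(architecture, kind, layer.joined_group, list(layer.panel),
                      dict(layer.low_impute), dict(layer.base), stack,
                      group_stacks=group_stacks, meta_cv_aucs=meta,
                      scheme=layer.scheme)


def build_jtg2l(train_cohort: Cohort, joined_group: str, panel: list[str],
                stack_kind: str = "bma", plan: CVPlan = CVPlan(),
                n_search: int = 25, families=FAMILIES, seed: int = 0,
                spaces: dict | None = None, **stack_opts) -> StackModel:
    """Joined-time-group two-layer ensemble, end to end."""
    layer = train_base_layer(train_cohort, "jtg2l", panel, joined_group,
                             plan, n_search, families, seed, spaces=spaces)
    return fit_stack_model(layer, "jtg2l", stack_kind, seed=seed, **stack_opts)


def build_stg2l(train_cohort: Cohort, panel: list[str], stack_kind: str = "bma",
                plan: CVPlan = CVPlan(), n_search: int = 25, families=FAMILIES,
                seed: int = 0, scheme: TimeGroupScheme = TimeGroupScheme(),
                spaces: dict | None = None, **stack_opts) -> StackModel:
    """Single-time-group two-layer ensemble: 10 x G concatenated columns."""
    layer = train_base_layer(train_cohort, "stg", panel, "0-4+", plan,
                             n_search, families, seed, scheme, spaces=spaces)
    return fit_stack_model(layer, "stg2l", stack_kind, seed=seed, **stack_opts)


def build_stg3l(train_cohort: Cohort, panel: list[str], top_stack_kind: str = "bma",
                plan: CVPlan = CVPlan(), n_search: int = 25, families=FAMILIES,
                seed: int = 0, scheme: TimeGroupScheme = TimeGroupScheme(),
                spaces: dict | None = None, **stack_opts) -> StackModel:
    """Three-layer ensemble: per-group BMA stacks, then a top stack."""
    layer = train_base_layer(train_cohort, "stg", panel, "0-4+", plan,
                             n_search, families, seed, scheme, spaces=spaces)
    return fit_stack_model(layer, "stg3l", top_stack_kind, seed=seed, **stack_opts)


def base_probability_matrix(model: StackModel, cohort: Cohort) -> pd.DataFrame:
    """Score a (new) cohort with every base learner of a frozen model."""
    df = cohort.df.copy()
    low_mask = cohort.low_mask.copy()
    for m in [c for c in model.panel if c in cohort.marker_cols]:
        flagged = low_mask[m].to_numpy()
        if not flagged.any():
            continue
        if m in model.low_impute:
            value = model.low_impute[m]
        else:
            # marker never seen LOW in training: half the new cohort's minimum
            observed = df[m].dropna()
            if observed.empty:
                raise CohortError(f"marker {m!r}: all values below LOD")
            value = float(observed.min()) / 2.0
        col = df[m].to_numpy(dtype=float)
        col[flagged] = value
        df[m] = col
        low_mask[m] = False
    work = Cohort(df, list(cohort.marker_cols), low_mask)
    X = build_design(work, model.panel).to_numpy(dtype=float)
    cols = {
        name: predict_proba1(tl.model, X) for name, (tl, _g) in model.base.items()
    }
    return pd.DataFrame(cols, index=cohort.df.index)


def predict(model: StackModel, cohort: Cohort) -> np.ndarray:
    """Case probability for each sample of a new cohort; no refitting."""
    P = base_probability_matrix(model, cohort)
    if model.architecture == "stg3l":
        mid = {}
        for g, gstack in model.group_stacks.items():
            mid[f"bma@{g}"] = gstack.predict(P[list(gstack.schema_)])
        P = pd.DataFrame(mid, index=cohort.df.index).clip(PROB_CLIP, 1 - PROB_CLIP)
    return model.stack.predict(P)
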