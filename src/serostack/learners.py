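"""The heterogeneous base-learner layer.

Ten classifier families — boosted shallow trees (C5.0-style), RBF-kernel SVM,
regularized random forest, PCA + feed-forward network, RBF Gaussian-process
classifier, elastic-net logistic regression, bagged adaptive boosting,
gradient-boosted trees, stepwise-AIC logistic regression and Gaussian naive
Bayes — each trained by repeated stratified k-fold cross-validation with
minority-class oversampling inside training folds only, and tuned by random
hyperparameter search.  The out-of-fold case probabilities of the winning
draw, averaged over repeats, become the meta-learner's feature space, so no
training sample is ever scored by a model that saw it.

The underlying classifiers are consumed from scikit-learn / xgboost; the
bespoke machinery here is the resampling, oversampling, search, feature-space
scanning and probability bookkeeping around them.
"""

from __future__ import annotations

import warnings
import zlib
from dataclasses import dataclass
from importlib import resources as importlib_resources
from itertools import combinations

import numpy as np
import pandas as pd
import yaml
from sklearn.base import BaseEstimator, ClassifierMixin, clone
from sklearn.decomposition import PCA
from sklearn.ensemble import (
    AdaBoostClassifier,
    BaggingClassifier,
    RandomForestClassifier,
)
from sklearn.gaussian_process import GaussianProcessClassifier
from sklearn.gaussian_process.kernels import RBF
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold
from sklearn.naive_bayes import GaussianNB
from sklearn.neural_network import MLPClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier
from xgboost import XGBClassifier

from .evaluation import roc_auc

__all__ = [
    "FAMILIES",
    "CVPlan",
    "TrainedLearner",
    "load_search_spaces",
    "make_cv_plan",
    "oversample_minority",
    "sample_params",
    "build_estimator",
    "tune_and_train",
    "train_layer",
    "scan_feature_space",
    "bruteforce_combo_scan",
    "predict_proba1",
]

FAMILIES = (
    "c50",
    "svm_rbf",
    "rrf",
    "nnet_pca",
    "gausspr",
    "glmnet",
    "adabag",
    "xgboost",
    "glm_stepaic",
    "naive_bayes",
)

PROB_CLIP = 1e-6  # keeps the geometric-mean stack defined at exact 0/1


@dataclass(frozen=True)
class CVPlan:
    n_folds: int = 10
    n_repeats: int = 5
    oversample: bool = True
    seed: int = 0


@dataclass
class TrainedLearner:
    family: str
    params: dict
    model: object  # refit on the full (oversampled) training set
    panel: list[str]
    cv_aucs: np.ndarray  # winning draw, one AUC per repeat x fold
    oof: np.ndarray  # out-of-fold probabilities, averaged over repeats

    @property
    def mean_cv_auc(self) -> float:
        return float(np.nanmean(self.cv_aucs))


def load_search_spaces(path=None, profile: str = "default") -> dict:
    """Hyperparameter ranges; ``profile`` is "default" (study scale) or
    "fast" (desk scale), or pass an explicit YAML path."""
    if path is not None:
        with open(path) as fh:
            return yaml.safe_load(fh)
    name = "learners.yaml" if profile == "default" else "learners_fast.yaml"
    ref = importlib_resources.files("serostack.resources").joinpath(name)
    return yaml.safe_load(ref.read_text())


def sample_params(space: dict, rng: np.random.Generator) -> dict:
    out = {}
    for name, rule in (space or {}).items():
        lo, hi = rule["low"], rule["high"]
        kind = rule["type"]
        if kind == "int":
            out[name] = int(rng.integers(lo, hi + 1))
        elif kind == "uniform":
            out[name] = float(rng.uniform(lo, hi))
        elif kind == "loguniform":
            out[name] = float(np.exp(rng.uniform(np.log(lo), np.log(hi))))
        else:
            raise ValueError(f"unknown range type {kind!r} for {name!r}")
    return out


class PlattSVC(BaseEstimator, ClassifierMixin):
    """RBF SVM with explicit Platt calibration of the decision function.

    SVC(probability=True) calibrates by an internal CV that can produce
    probabilities anti-correlated with the decision function on small,
    oversampled training folds; fitting the sigmoid on the training decision
    values keeps the probability orientation consistent with the margin.
    """

    def __init__(self, C: float = 1.0, gamma: float = "scale",
                 random_state: int | None = None):
        self.C = C
        self.gamma = gamma
        self.random_state = random_state

    def fit(self, X, y):
        y = np.asarray(y)
        self.classes_ = np.unique(y)
        self._svc = SVC(C=self.C, gamma=self.gamma, probability=False,
                        random_state=self.random_state)
        self._svc.fit(X, y)
        d = self._svc.decision_function(X)
        self._platt = LogisticRegression(max_iter=500)
        self._platt.fit(d[:, None], y)
        return self

    def predict_proba(self, X):
        d = self._svc.decision_function(np.asarray(X, dtype=float))
        return self._platt.predict_proba(d[:, None])

    def predict(self, X):
        return self._svc.predict(np.asarray(X, dtype=float))


class StepwiseAICLogit(BaseEstimator, ClassifierMixin):
    """Forward stepwise logistic regression selecting features by AIC."""

    def __init__(self, max_features: int = 10, random_state: int | None = None):
        self.max_features = max_features
        self.random_state = random_state

    def _aic(self, X, y) -> tuple[float, LogisticRegression]:
        lr = LogisticRegression(C=np.inf, max_iter=500)
        lr.fit(X, y)
        p = np.clip(lr.predict_proba(X)[:, 1], 1e-12, 1 - 1e-12)
        ll = float(np.sum(y * np.log(p) + (1 - y) * np.log(1 - p)))
        return 2 * (X.shape[1] + 1) - 2 * ll, lr

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        self.classes_ = np.unique(y)
        n, p = X.shape
        selected: list[int] = []
        # intercept-only AIC
        p1 = np.clip(y.mean(), 1e-12, 1 - 1e-12)
        best_aic = 2 - 2 * float(
            n * (p1 * np.log(p1) + (1 - p1) * np.log(1 - p1))
        )
        self._model = None
        while len(selected) < min(self.max_features, p):
            trial = [
                (j, *self._aic(X[:, selected + [j]], y))
                for j in range(p)
                if j not in selected
            ]
            j, aic, model = min(trial, key=lambda t: t[1])
            if aic >= best_aic - 1e-9:
                break
            selected.append(j)
            best_aic, self._model = aic, model
        self.selected_ = selected
        self._prior = y.mean()
        return self

    def predict_proba(self, X):
        X = np.asarray(X, dtype=float)
        if self._model is None:
            p = np.full(X.shape[0], self._prior)
        else:
            p = self._model.predict_proba(X[:, self.selected_])[:, 1]
        return np.column_stack([1 - p, p])

    def predict(self, X):
        return (self.predict_proba(X)[:, 1] > 0.5).astype(int)


def build_estimator(family: str, params: dict, seed: int = 0):
    """Instantiate a classifier for one family with sampled hyperparameters."""
    scaled = lambda est: Pipeline([("scale", StandardScaler()), ("clf", est)])
    if family == "c50":
        return AdaBoostClassifier(
            estimator=DecisionTreeClassifier(max_depth=params.get("max_depth", 2)),
            n_estimators=params.get("n_estimators", 50),
            learning_rate=params.get("learning_rate", 0.5),
            random_state=seed,
        )
    if family == "svm_rbf":
        return scaled(
            PlattSVC(
                C=params.get("C", 1.0),
                gamma=params.get("gamma", "scale"),
                random_state=seed,
            )
        )
    if family == "rrf":
        return RandomForestClassifier(
            n_estimators=params.get("n_estimators", 100),
            max_features=params.get("max_features", 0.5),
            min_samples_leaf=params.get("min_samples_leaf", 2),
            random_state=seed,
            n_jobs=1,
        )
    if family == "nnet_pca":
        return Pipeline(
            [
                ("scale", StandardScaler()),
                ("pca", PCA(n_components=params.get("n_components", 0.8), random_state=seed)),
                (
                    "clf",
                    MLPClassifier(
                        hidden_layer_sizes=(params.get("hidden", 5),),
                        alpha=params.get("alpha", 1e-3),
                        max_iter=200,
                        tol=1e-3,
                        random_state=seed,
                    ),
                ),
            ]
        )
    if family == "gausspr":
        # fixed sampled length-scale: kernel optimization is delegated to the
        # random search itself
        return scaled(
            GaussianProcessClassifier(
                kernel=RBF(length_scale=params.get("length_scale", 1.0)),
                optimizer=None,
                random_state=seed,
            )
        )
    if family == "glmnet":
        return scaled(
            LogisticRegression(
                solver="saga",
                C=params.get("C", 1.0),
                l1_ratio=params.get("l1_ratio", 0.5),
                max_iter=2000,
                random_state=seed,
            )
        )
    if family == "adabag":
        return BaggingClassifier(
            estimator=AdaBoostClassifier(
                n_estimators=params.get("n_estimators", 25), random_state=seed
            ),
            n_estimators=params.get("n_bags", 10),
            random_state=seed,
            n_jobs=1,
        )
    if family == "xgboost":
        return XGBClassifier(
            n_estimators=params.get("n_estimators", 100),
            max_depth=params.get("max_depth", 3),
            learning_rate=params.get("learning_rate", 0.1),
            subsample=params.get("subsample", 1.0),
            random_state=seed,
            n_jobs=1,
            verbosity=0,
            eval_metric="logloss",
        )
    if family == "glm_stepaic":
        return scaled(StepwiseAICLogit(random_state=seed))
    if family == "naive_bayes":
        return GaussianNB()
    raise ValueError(f"unknown base-learner family {family!r}")


def predict_proba1(model, X) -> np.ndarray:
    """Case probability, clipped away from 0/1."""
    X = np.asarray(X, dtype=float)
    proba = model.predict_proba(X)
    classes = list(getattr(model, "classes_", [0, 1]))
    col = classes.index(1) if 1 in classes else 1
    return np.clip(proba[:, col], PROB_CLIP, 1.0 - PROB_CLIP)


def make_cv_plan(y, plan: CVPlan) -> list[tuple[int, int, np.ndarray, np.ndarray]]:
    """Stratified fold assignments: (repeat, fold, train_idx, val_idx)."""
    y = np.asarray(y, dtype=int)
    counts = np.bincount(y, minlength=2)
    if counts.min() < plan.n_folds:
        raise ValueError(
            f"smallest class has {counts.min()} samples < {plan.n_folds} folds; "
            "use fewer folds"
        )
    folds = []
    for rep in range(plan.n_repeats):
        skf = StratifiedKFold(
            n_splits=plan.n_folds, shuffle=True, random_state=plan.seed + 1000 * rep
        )
        for k, (tr, va) in enumerate(skf.split(np.zeros(len(y)), y)):
            folds.append((rep, k, tr, va))
    return folds


def oversample_minority(X: np.ndarray, y: np.ndarray, rng: np.random.Generator):
    """Duplicate minority rows (with replacement) until class counts match."""
    y = np.asarray(y, dtype=int)
    counts = np.bincount(y, minlength=2)
    if counts.min() == 0:
        raise ValueError("oversampling needs both classes present")
    if counts[0] == counts[1]:
        return X, y
    minority = int(np.argmin(counts))
    idx_min = np.flatnonzero(y == minority)
    extra = rng.choice(idx_min, size=counts.max() - counts.min(), replace=True)
    keep = np.concatenate([np.arange(len(y)), extra])
    return X[keep], y[keep]


def _cv_probabilities(est, X, y, folds, oversample, rng) -> tuple[np.ndarray, np.ndarray]:
    """Out-of-fold probabilities (n, n_repeats) and per-fold AUCs."""
    n_repeats = max(f[0] for f in folds) + 1
    oof = np.full((len(y), n_repeats), np.nan)
    aucs = []
    for rep, _, tr, va in folds:
        Xtr, ytr = X[tr], y[tr]
        if oversample:
            Xtr, ytr = oversample_minority(Xtr, ytr, rng)
        model = clone(est)
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                model.fit(Xtr, ytr)
            p = predict_proba1(model, X[va])
        except Exception as exc:  # noqa: BLE001 - a failed fold scores 0.5
            warnings.warn(f"fold fit failed ({exc}); scoring fold as AUC 0.5")
            p = np.full(len(va), 0.5)
        oof[va, rep] = p
        if len(np.unique(y[va])) == 2:
            aucs.append(roc_auc(p, y[va]))
        else:
            aucs.append(np.nan)
    return oof, np.asarray(aucs)


def tune_and_train(
    family: str,
    X: pd.DataFrame,
    y,
    plan: CVPlan = CVPlan(),
    n_search: int = 25,
    spaces: dict | None = None,
    seed: int = 0,
) -> TrainedLearner:
    """Random hyperparameter search under repeated CV; returns the best draw
    refit on the full (oversampled) training set with its out-of-fold
    probabilities retained for stacking."""
    if X.shape[1] == 0:
        raise ValueError("empty feature panel")
    spaces = spaces or load_search_spaces()
    space = spaces.get(family, {})
    rng = np.random.default_rng([seed, zlib.crc32(family.encode()) % (2**31)])
    panel = list(X.columns)
    Xa = X.to_numpy(dtype=float)
    ya = np.asarray(y, dtype=int)
    folds = make_cv_plan(ya, plan)

    n_draws = n_search if space else 1  # families without hyperparameters: single fit
    best = None
    for d in range(n_draws):
        params = sample_params(space, rng)
        est = build_estimator(family, params, seed=int(rng.integers(2**31)))
        oof, aucs = _cv_probabilities(est, Xa, ya, folds, plan.oversample, rng)
        mean_auc = float(np.nanmean(aucs))
        if best is None or mean_auc > best[0]:
            best = (mean_auc, params, est, oof, aucs)
    _, params, est, oof, aucs = best
    Xfull, yfull = (Xa, ya)
    if plan.oversample:
        Xfull, yfull = oversample_minority(Xa, ya, rng)
    final = clone(est)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        final.fit(Xfull, yfull)
    oof_mean = np.nanmean(oof, axis=1)
    return TrainedLearner(family, params, final, panel, aucs, oof_mean)


def train_layer(
    X: pd.DataFrame,
    y,
    plan: CVPlan = CVPlan(),
    n_search: int = 25,
    families=FAMILIES,
    spaces: dict | None = None,
    seed: int = 0,
) -> dict[str, TrainedLearner]:
    """Train every base-learner family on one panel; keyed by family name."""
    return {
        fam: tune_and_train(fam, X, y, plan, n_search, spaces, seed=seed)
        for fam in families
    }


def scan_feature_space(ranking: pd.DataFrame, builder, step: int = 10):
    """Evaluate nested top-k feature panels (k = step, 2*step, ..., all).

    ``builder`` maps a feature list to a mean CV AUC (typically the stacked
    meta CV AUC).  Returns (best_k, {k: auc}); ties break toward smaller k.
    """
    features = ranking["feature"].tolist()
    if not features:
        raise ValueError("empty ranking")
    ks = list(range(step, len(features), step)) + [len(features)]
    ks = sorted(set(min(k, len(features)) for k in ks))
    aucs = {k: float(builder(features[:k])) for k in ks}
    best_k = max(ks, key=lambda k: (aucs[k], -k))
    return best_k, aucs


def bruteforce_combo_scan(
    X: pd.DataFrame, y, max_size: int = 3, plan: CVPlan = CVPlan(), seed: int = 0
) -> pd.DataFrame:
    """Exhaustive small-panel logistic-regression baseline.

    Fits a plain logistic regression for every marker combination of size
    1..max_size under the CV plan and ranks combinations by mean CV AUC.
    """
    markers = list(X.columns)
    if len(markers) > 60:
        warnings.warn(
            f"{len(markers)} markers -> {sum(1 for _ in combinations(markers, max_size))}+ fits"
        )
    ya = np.asarray(y, dtype=int)
    folds = make_cv_plan(ya, plan)
    rng = np.random.default_rng(seed)
    rows = []
    for size in range(1, max_size + 1):
        for combo in combinations(markers, size):
            Xa = X[list(combo)].to_numpy(dtype=float)
            est = Pipeline(
                [("scale", StandardScaler()), ("clf", LogisticRegression(max_iter=500))]
            )
            try:
                _, aucs = _cv_probabilities(est, Xa, ya, folds, plan.oversample, rng)
                auc = float(np.nanmean(aucs))
            except Exception:  # noqa: BLE001
                auc = np.nan
            rows.append({"combination": "+".join(combo), "size": size, "cv_auc": auc})
    out = pd.DataFrame(rows)
    out["_a"] = out["cv_auc"].fillna(-np.inf)
    out = out.sort_values(["_a", "combination"], ascending=[False, True], kind="mergesort")
    return out.drop(columns="_a").reset_index(drop=True)
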