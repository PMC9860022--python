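"""Firth bias-reduced logistic regression.

Maximizes the Jeffreys-prior penalized log-likelihood

    l*(beta) = l(beta) + 1/2 * log det I(beta),      I(beta) = X' W X,

by modified-score Newton iterations with step-halving.  The penalty keeps
estimates finite under complete or quasi-complete separation and under zero
cells in contingency tables, which is why it is the standard single-marker
association engine for small case-control panels.  For a saturated
one-binary-covariate design the estimate has the closed form obtained by
adding 1/2 to every cell of the 2x2 table.

Inference follows the penalized likelihood: p-values are penalized
likelihood-ratio tests (each coefficient profiled to zero) and confidence
intervals are profile-penalized-likelihood intervals solved at the chi2(1)
cutoff.  Wald statistics are available but are not the default.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import linalg, optimize, special, stats

from .cohort import Cohort, build_design

__all__ = ["FirthFit", "FirthError", "firth_fit", "firth_fit_2x2", "rank_features"]

_CHI2_95 = stats.chi2.ppf(0.95, 1)


class FirthError(RuntimeError):
    """Non-convergence or invalid design."""

    def __init__(self, message, last_beta=None):
        super().__init__(message)
        self.last_beta = last_beta


@dataclass
class FirthFit:
    names: list[str]
    beta: np.ndarray
    se: np.ndarray
    ci_low: np.ndarray  # log-odds scale
    ci_high: np.ndarray
    p_values: np.ndarray
    loglik: float
    converged: bool
    iterations: int

    @property
    def odds_ratios(self) -> np.ndarray:
        return np.exp(self.beta)

    @property
    def or_ci(self) -> np.ndarray:
        return np.exp(np.column_stack([self.ci_low, self.ci_high]))

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "beta": self.beta,
                "se": self.se,
                "or": np.exp(self.beta),
                "ci_low": np.exp(self.ci_low),
                "ci_high": np.exp(self.ci_high),
                "p": self.p_values,
            },
            index=self.names,
        )


def _penalized_parts(X, y, beta):
    """Return (penalized loglik, modified score, full information matrix)."""
    eta = X @ beta
    p = special.expit(eta)
    w = np.clip(p * (1.0 - p), 1e-12, None)
    XW = X * np.sqrt(w)[:, None]
    info = XW.T @ XW
    sign, logdet = np.linalg.slogdet(info)
    if sign <= 0:
        return -np.inf, None, info
    # hat diagonal of W^(1/2) X I^(-1) X' W^(1/2)
    try:
        inv_info = linalg.inv(info)
    except linalg.LinAlgError:
        return -np.inf, None, info
    h = np.einsum("ij,jk,ik->i", XW, inv_info, XW)
    ll = np.sum(y * eta - np.logaddexp(0.0, eta)) + 0.5 * logdet
    score = X.T @ (y - p + h * (0.5 - p))
    return ll, score, info


def _fit_core(X, y, free, beta0, tol, max_iter, max_halvings=12):
    """Newton iterations over the ``free`` coefficient subset.

    Fixed coefficients (not in ``free``) are held at their beta0 values, so
    the same routine does full fits and profile fits.
    """
    beta = beta0.copy()
    ll, score, info = _penalized_parts(X, y, beta)
    it = 0
    converged = False
    for it in range(1, max_iter + 1):
        if score is None:
            raise FirthError("singular information matrix", beta)
        sub_info = info[np.ix_(free, free)]
        sub_score = score[free]
        try:
            delta = linalg.solve(sub_info, sub_score, assume_a="pos")
        except linalg.LinAlgError as exc:
            raise FirthError(f"information matrix not invertible: {exc}", beta)
        # step-halving: accept only improving penalized loglik; the strict
        # inequality breaks symmetric overshoot limit cycles near the optimum
        step = 1.0
        improved = False
        for _ in range(max_halvings + 1):
            cand = beta.copy()
            cand[free] += step * delta
            ll_new, score_new, info_new = _penalized_parts(X, y, cand)
            if ll_new > ll or (ll_new >= ll and np.max(np.abs(step * delta)) < tol):
                improved = True
                break
            step *= 0.5
        if not improved:
            # no step size improves: we are at the optimum to machine precision
            converged = np.max(np.abs(score[free])) < max(tol, 1e-3)
            break
        beta, ll, score, info = cand, ll_new, score_new, info_new
        if np.max(np.abs(score[free])) < tol and np.max(np.abs(step * delta)) < tol:
            converged = True
            break
    return beta, ll, info, converged, it


def _prepare_design(X, names, add_intercept):
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    if names is None:
        names = [f"x{j}" for j in range(X.shape[1])]
    names = list(names)
    # drop constant non-intercept columns
    keep = [j for j in range(X.shape[1]) if np.ptp(X[:, j]) > 0]
    dropped = [names[j] for j in range(X.shape[1]) if j not in keep]
    X = X[:, keep]
    names = [names[j] for j in keep]
    if add_intercept:
        X = np.column_stack([np.ones(X.shape[0]), X])
        names = ["(Intercept)"] + names
    if np.linalg.matrix_rank(X) < X.shape[1]:
        # name the first column linearly dependent on its predecessors
        for j in range(1, X.shape[1]):
            if np.linalg.matrix_rank(X[:, : j + 1]) < j + 1:
                raise FirthError(f"collinear design column: {names[j]!r}")
    return X, names, dropped


def firth_fit(
    X,
    y,
    names=None,
    add_intercept: bool = True,
    tol: float = 1e-6,
    max_iter: int = 50,
    ci: bool = True,
    p_method: str = "plrt",
) -> FirthFit:
    """Fit a Firth-penalized logistic regression.

    Parameters
    ----------
    X : array-like or DataFrame (n, p)
        Covariates; an intercept column is prepended unless ``add_intercept``
        is False.
    y : array-like of {0, 1}
    ci, p_method : profile-penalized-likelihood CIs and LRT p-values by
        default; ``p_method="wald"`` switches the p-values only.
    """
    if isinstance(X, pd.DataFrame):
        names = list(X.columns)
        X = X.to_numpy(dtype=float)
    y = np.asarray(y, dtype=float)
    if not np.isin(y, (0.0, 1.0)).all():
        raise FirthError("outcome must be binary 0/1")
    if y.min() == y.max():
        warnings.warn("degenerate fit: only one outcome class present")
    X, names, _ = _prepare_design(X, names, add_intercept)
    n, k = X.shape
    free = np.arange(k)
    beta, ll, info, converged, iters = _fit_core(X, y, free, np.zeros(k), tol, max_iter)
    if not converged:
        raise FirthError(f"no convergence in {max_iter} iterations", beta)
    se = np.sqrt(np.diag(linalg.inv(info)))

    p_values = np.full(k, np.nan)
    ci_low = np.full(k, np.nan)
    ci_high = np.full(k, np.nan)
    for j in range(k):
        others = np.array([i for i in range(k) if i != j])

        def profile_ll(value, _j=j, _others=others):
            b0 = beta.copy()
            b0[_j] = value
            if _others.size:
                b, pll, _, _, _ = _fit_core(X, y, _others, b0, tol, max_iter)
            else:
                pll, _, _ = _penalized_parts(X, y, b0)
            return pll

        if p_method == "wald":
            z = beta[j] / se[j]
            p_values[j] = 2.0 * stats.norm.sf(abs(z))
        else:
            lr = max(0.0, 2.0 * (ll - profile_ll(0.0)))
            p_values[j] = stats.chi2.sf(lr, 1)
        if ci:
            ci_low[j], ci_high[j] = _profile_ci(profile_ll, ll, beta[j], se[j])

    return FirthFit(names, beta, se, ci_low, ci_high, p_values, ll, converged, iters)


def _profile_ci(profile_ll, ll_max, bhat, se, level_drop=_CHI2_95, tol=1e-6):
    """Endpoints where the penalized profile deviance equals the chi2 cutoff."""

    def g(b):
        return 2.0 * (ll_max - profile_ll(b)) - level_drop

    out = []
    for direction in (-1.0, 1.0):
        width = max(se, 1e-3)
        lo, hi = bhat, bhat + direction * 10.0 * width
        # expand until the cutoff is bracketed
        for _ in range(10):
            if g(hi) > 0:
                break
            hi += direction * 10.0 * width
        else:
            out.append(direction * np.inf)
            continue
        a, b = sorted((lo, hi))
        root = optimize.brentq(g, a, b, xtol=tol, rtol=8.9e-16)
        out.append(root)
    return out[0], out[1]


def firth_fit_2x2(
    exposed_cases: int, exposed_controls: int, unexposed_cases: int, unexposed_controls: int
) -> FirthFit:
    """Firth fit of case status on a single binary exposure given 2x2 counts."""
    y = np.concatenate(
        [
            np.ones(exposed_cases),
            np.zeros(exposed_controls),
            np.ones(unexposed_cases),
            np.zeros(unexposed_controls),
        ]
    )
    x = np.concatenate(
        [
            np.ones(exposed_cases + exposed_controls),
            np.zeros(unexposed_cases + unexposed_controls),
        ]
    )
    return firth_fit(x[:, None], y, names=["exposure"])


def rank_features(
    cohort: Cohort, features: list[str], ci: bool = False, **fit_kwargs
) -> pd.DataFrame:
    """Univariate Firth association scan, ranked by ascending p-value.

    Each feature is fitted alone (intercept + feature).  Features whose fit
    fails are kept with NA statistics and rank last.  Ties in p break by
    feature name, so the ranking is deterministic.  ``ci=True`` adds
    profile-penalized-likelihood odds-ratio intervals (slower).
    """
    y = cohort.status.to_numpy()
    records = []
    for f in features:
        try:
            x = build_design(cohort, [f])
            fit = firth_fit(x, y, ci=ci, **fit_kwargs)
            j = fit.names.index(f)
            records.append(
                {
                    "feature": f,
                    "beta": fit.beta[j],
                    "or": float(np.exp(fit.beta[j])),
                    "ci_low": float(np.exp(fit.ci_low[j])),
                    "ci_high": float(np.exp(fit.ci_high[j])),
                    "p": fit.p_values[j],
                    "converged": fit.converged,
                }
            )
        except Exception as exc:  # noqa: BLE001 - scan must not abort
            warnings.warn(f"feature {f!r} failed to fit: {exc}")
            records.append(
                {"feature": f, "beta": np.nan, "or": np.nan, "ci_low": np.nan,
                 "ci_high": np.nan, "p": np.nan, "converged": False}
            )
    out = pd.DataFrame.from_records(records)
    out["_p"] = out["p"].fillna(np.inf)
    out = out.sort_values(["_p", "feature"], kind="mergesort").drop(columns="_p")
    return out.reset_index(drop=True)
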