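"""Lasso-based feature selection with a cross-validated regularization path.

The selection step solves, for each penalty value lambda,

    min_{b0, b}  (1/2N) * sum_i (y_i - b0 - x_i' b)^2  +  lambda * ||b||_1

by cyclic coordinate descent with soft-thresholding, over a glmnet-style
descending log-spaced lambda grid with warm starts.  The operating lambda
is chosen by k-fold cross-validated mean squared prediction error
(Gaussian deviance); the selected feature set is the support of the
coefficient vector at that lambda.  An optional random-forest
permutation-importance ranker is provided as an alternative.

Columns are z-scored internally (training folds only during CV) so the
penalty treats features comparably; coefficients are reported on the
standardized scale and the support is scale-free.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestRegressor
from sklearn.inspection import permutation_importance
from sklearn.model_selection import KFold


def _soft_threshold(z: float, g: float) -> float:
    if z > g:
        return z - g
    if z < -g:
        return z + g
    return 0.0


def lasso_fit(
    X: np.ndarray,
    y: np.ndarray,
    lam: float,
    beta0: np.ndarray | None = None,
    tol: float = 1e-7,
    max_iter: int = 10_000,
) -> tuple[float, np.ndarray]:
    """Coordinate-descent lasso solution (intercept unpenalized).

    ``X`` is expected column-standardized; ``beta0`` is an optional warm
    start.  Iterates until the objective decreases by less than ``tol``.
    Returns (intercept, coefficients).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if not (np.all(np.isfinite(X)) and np.all(np.isfinite(y))):
        raise ValueError("non-finite values in X or y")
    if lam < 0:
        raise ValueError("lambda must be >= 0")
    n, p = X.shape
    if n < 2:
        raise ValueError("need at least 2 observations")

    beta = np.zeros(p) if beta0 is None else beta0.astype(float).copy()
    ybar = y.mean()
    col_sq = (X**2).sum(axis=0) / n  # = 1 for z-scored columns, kept general

    def objective(b: np.ndarray) -> float:
        r = y - ybar - X @ b
        return 0.5 * np.mean(r**2) + lam * np.abs(b).sum()

    resid = y - ybar - X @ beta
    prev_obj = objective(beta)
    for _ in range(max_iter):
        for j in range(p):
            if col_sq[j] == 0:
                beta[j] = 0.0
                continue
            bj = beta[j]
            # partial residual correlation
            rho = (X[:, j] @ resid) / n + col_sq[j] * bj
            new = _soft_threshold(rho, lam) / col_sq[j]
            if new != bj:
                resid -= X[:, j] * (new - bj)
                beta[j] = new
        obj = objective(beta)
        if prev_obj - obj < tol:
            break
        prev_obj = obj
    intercept = ybar  # X centered => intercept decouples
    return float(intercept), beta


def lambda_max(X: np.ndarray, y: np.ndarray) -> float:
    """Smallest lambda at which all coefficients are zero."""
    n = len(y)
    return float(np.max(np.abs(X.T @ (y - y.mean()))) / n)


def default_lambda_grid(X: np.ndarray, y: np.ndarray, n: int = 100) -> np.ndarray:
    """glmnet-style descending log grid from lambda_max down to 1e-4 * lambda_max."""
    lmax = lambda_max(X, y)
    if lmax == 0:
        lmax = 1.0
    return np.geomspace(lmax, 1e-4 * lmax, n)


def _standardize(X: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    mu = X.mean(axis=0)
    sd = X.std(axis=0, ddof=0)
    sd_safe = np.where(sd == 0, 1.0, sd)
    return (X - mu) / sd_safe, mu, sd_safe


@dataclass
class LassoPath:
    """Lambda grid, coefficient path, CV deviance curve and selection."""

    lambdas: np.ndarray                    # descending
    coefs: np.ndarray                      # (p, n_lambda), standardized scale
    intercepts: np.ndarray                 # per lambda
    cv_deviance: np.ndarray                # mean held-out squared error per lambda
    n_nonzero: np.ndarray
    best_index: int
    feature_names: list[str] = field(default_factory=list)
    fold_assignment: np.ndarray | None = None

    @property
    def best_lambda(self) -> float:
        return float(self.lambdas[self.best_index])

    @property
    def selected_features(self) -> list[str]:
        support = np.flatnonzero(self.coefs[:, self.best_index] != 0)
        if self.feature_names:
            return [self.feature_names[j] for j in support]
        return [str(j) for j in support]

    def to_dict(self) -> dict:
        return {
            "lambdas": self.lambdas.tolist(),
            "cv_deviance": self.cv_deviance.tolist(),
            "n_nonzero": self.n_nonzero.tolist(),
            "best_lambda": self.best_lambda,
            "selected_features": self.selected_features,
        }


def fit_lasso_path(
    X: np.ndarray, lambdas: np.ndarray, y: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Warm-started coefficient path over a descending lambda grid."""
    p = X.shape[1]
    coefs = np.zeros((p, len(lambdas)))
    intercepts = np.zeros(len(lambdas))
    warm = np.zeros(p)
    for i, lam in enumerate(lambdas):
        b0, warm = lasso_fit(X, y, lam, beta0=warm)
        coefs[:, i] = warm
        intercepts[i] = b0
    return intercepts, coefs


def cv_deviance_curve(
    X: np.ndarray | pd.DataFrame,
    y: np.ndarray,
    lambdas: np.ndarray | None = None,
    k: int = 5,
    seed: int = 0,
) -> LassoPath:
    """Cross-validated deviance over the lambda grid; select the minimizer.

    Standardization statistics are computed on the training folds only.
    Ties at the minimum break toward the larger lambda (sparser model).
    """
    names = list(X.columns) if isinstance(X, pd.DataFrame) else []
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(y)
    if k > n:
        raise ValueError(f"k={k} folds exceed {n} observations")

    Xs, _, _ = _standardize(X)
    if lambdas is None:
        lambdas = default_lambda_grid(Xs, y)
    lambdas = np.asarray(lambdas, dtype=float)

    kf = KFold(n_splits=k, shuffle=True, random_state=seed)
    fold_of = np.empty(n, dtype=int)
    sq_err = np.zeros((n, len(lambdas)))
    for fold, (tr, te) in enumerate(kf.split(Xs)):
        fold_of[te] = fold
        Xtr_s, mu, sd = _standardize(X[tr])
        Xte_s = (X[te] - mu) / sd
        _, coefs = fit_lasso_path(Xtr_s, lambdas, y[tr])
        preds = y[tr].mean() + Xte_s @ coefs  # (n_te, n_lambda)
        sq_err[te] = (y[te][:, None] - preds) ** 2
    cv_dev = sq_err.mean(axis=0)

    intercepts, full_coefs = fit_lasso_path(Xs, lambdas, y)
    # ties toward larger lambda: argmin on a descending grid returns the
    # first (largest-lambda) minimizer
    best = int(np.argmin(cv_dev))
    return LassoPath(
        lambdas=lambdas,
        coefs=full_coefs,
        intercepts=intercepts,
        cv_deviance=cv_dev,
        n_nonzero=(full_coefs != 0).sum(axis=0),
        best_index=best,
        feature_names=names,
        fold_assignment=fold_of,
    )


def rank_features_rf(
    X: pd.DataFrame,
    y: np.ndarray,
    n_trees: int = 500,
    seed: int = 0,
    top: int | None = None,
) -> list[str]:
    """Permutation-importance ranking by a random forest, descending.

    ``top`` truncates the ranking (e.g. 25 for a top-25 shortlist).
    """
    y = np.asarray(y, dtype=float)
    if len(y) < 5:
        raise ValueError("need at least 5 observations")
    if np.all(y == y[0]):
        raise ValueError("constant response; ranking undefined")
    rf = RandomForestRegressor(n_estimators=n_trees, random_state=seed)
    rf.fit(X.values, y)
    imp = permutation_importance(
        rf, X.values, y, n_repeats=10, random_state=seed
    ).importances_mean
    order = np.argsort(-imp, kind="stable")
    ranked = [X.columns[i] for i in order]
    return ranked[:top] if top else ranked
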