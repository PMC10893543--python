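"""Cross-validated regression of MoCA scores on selected ERP features.

Four regressors are compared on pooled k-fold held-out predictions:

* ``MR_logit`` — a linear model on the logit of y/30.  MoCA scores are
  bounded on [0, 30], so a straight linear fit can predict impossible
  scores; the logit link keeps back-transformed predictions inside the
  scale.  Boundary scores are shrunk by half a point before the logit.
* ``ER`` — ensemble regression: least-squares boosted regression trees
  by default (bagging via ``hyper={"kind": "bagging"}``).
* ``SVR`` — epsilon-insensitive RBF support-vector regression on
  z-scored inputs.
* ``RR`` — ridge regression with the penalty chosen by inner
  cross-validation over a log grid.

Fold assignment depends only on (n, k, seed), so all methods are scored
on identical folds and comparisons are paired.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit, logit
from sklearn.ensemble import GradientBoostingRegressor, RandomForestRegressor
from sklearn.linear_model import Ridge
from sklearn.model_selection import GridSearchCV, KFold
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVR as _SVR

METHODS = ("MR_logit", "ER", "SVR", "RR")

MOCA_MAX = 30.0


def score(residuals: np.ndarray) -> tuple[float, float]:
    """(RMSE, MAE) of a residual vector."""
    r = np.asarray(residuals, dtype=float)
    if r.size == 0:
        raise ValueError("no residuals")
    return float(np.sqrt(np.mean(r**2))), float(np.mean(np.abs(r)))


@dataclass
class RegressionResult:
    """Pooled k-fold predictions and error scores for one method."""

    method: str
    y_true: np.ndarray
    y_pred: np.ndarray
    fold_assignment: np.ndarray
    hyperparameters: dict = field(default_factory=dict)

    @property
    def residuals(self) -> np.ndarray:
        return self.y_true - self.y_pred

    @property
    def rmse(self) -> float:
        return score(self.residuals)[0]

    @property
    def mae(self) -> float:
        return score(self.residuals)[1]

    def to_dict(self) -> dict:
        return {
            "method": self.method,
            "rmse": self.rmse,
            "mae": self.mae,
            "y_true": self.y_true.tolist(),
            "y_pred": self.y_pred.tolist(),
            "fold_assignment": self.fold_assignment.tolist(),
            "hyperparameters": {k: str(v) for k, v in self.hyperparameters.items()},
        }


class _LogitLinear:
    """Linear least squares on logit(y/30), back-transformed by 30*logistic."""

    def __init__(self, shrink: float = 0.5):
        self.shrink = shrink

    def fit(self, X: np.ndarray, y: np.ndarray) -> "_LogitLinear":
        if np.any(y < 0) or np.any(y > MOCA_MAX):
            raise ValueError("MR_logit requires y in [0, 30]")
        # boundary clamping: 0 -> 0.5, 30 -> 29.5 (half-point shrinkage)
        yc = np.clip(y, self.shrink, MOCA_MAX - self.shrink)
        z = logit(yc / MOCA_MAX)
        A = np.column_stack([np.ones(len(y)), X])
        self.coef_, *_ = np.linalg.lstsq(A, z, rcond=None)
        return self

    def predict(self, X: np.ndarray) -> np.ndarray:
        A = np.column_stack([np.ones(len(X)), X])
        return MOCA_MAX * expit(A @ self.coef_)


def _make_estimator(method: str, hyper: dict, seed: int):
    hyper = dict(hyper or {})
    if method == "MR_logit":
        return _LogitLinear(shrink=hyper.get("shrink", 0.5))
    if method == "ER":
        kind = hyper.pop("kind", "boosting")
        if kind == "boosting":
            return GradientBoostingRegressor(
                n_estimators=hyper.get("n_estimators", 100),
                max_depth=hyper.get("max_depth", 3),
                learning_rate=hyper.get("learning_rate", 0.1),
                random_state=seed,
            )
        return RandomForestRegressor(
            n_estimators=hyper.get("n_estimators", 100),
            random_state=seed,
        )
    if method == "SVR":
        return make_pipeline(
            StandardScaler(),
            _SVR(
                kernel=hyper.get("kernel", "rbf"),
                C=hyper.get("C", 1.0),
                epsilon=hyper.get("epsilon", 0.1),
            ),
        )
    if method == "RR":
        if "alpha" in hyper:  # fixed penalty bypasses the inner search
            return make_pipeline(StandardScaler(), Ridge(alpha=hyper["alpha"]))
        alphas = hyper.get("alphas", np.logspace(-4, 4, 25))
        inner_k = hyper.get("inner_k", 5)
        return GridSearchCV(
            make_pipeline(StandardScaler(), Ridge()),
            {"ridge__alpha": alphas},
            cv=inner_k,
            scoring="neg_mean_squared_error",
        )
    raise ValueError(f"unknown method {method!r}; choose from {METHODS}")


def fit_predict_cv(
    X: np.ndarray,
    y: np.ndarray,
    method: str,
    k: int = 5,
    seed: int = 0,
    hyper: dict | None = None,
) -> RegressionResult:
    """Pooled k-fold held-out predictions for one regression method."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(y)
    if X.shape[0] != n:
        raise ValueError("X and y are misaligned")
    if k > n:
        raise ValueError(f"k={k} exceeds n={n}")

    kf = KFold(n_splits=k, shuffle=True, random_state=seed)
    y_pred = np.empty(n)
    fold_of = np.empty(n, dtype=int)
    for fold, (tr, te) in enumerate(kf.split(X)):
        est = _make_estimator(method, hyper or {}, seed)
        # adapt the inner ridge CV to tiny training folds
        if method == "RR" and isinstance(est, GridSearchCV):
            est.cv = min(est.cv, len(tr))
        est.fit(X[tr], y[tr])
        y_pred[te] = est.predict(X[te])
        fold_of[te] = fold
    return RegressionResult(
        method=method,
        y_true=y,
        y_pred=y_pred,
        fold_assignment=fold_of,
        hyperparameters=hyper or {},
    )


def compare_methods(
    X: np.ndarray,
    y: np.ndarray,
    methods: tuple[str, ...] = METHODS,
    k: int = 5,
    seed: int = 0,
    hyper: dict[str, dict] | None = None,
) -> dict[str, RegressionResult]:
    """Run several methods on identical folds."""
    hyper = hyper or {}
    return {
        m: fit_predict_cv(X, y, m, k=k, seed=seed, hyper=hyper.get(m))
        for m in methods
    }
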