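"""Gaussian-process Bayesian optimization with Expected Improvement.

Tunes the CNN's three hyperparameters (convolutional filter size, dropout
rate, number of epochs) over a discrete candidate grid in three stages:

1. pre-sample — five configurations drawn uniformly without repetition,
   each scored by cross-validated RMSE of the network;
2. kernel comparison — five GP kernels (Matern, RBF, Rational Quadratic,
   ExpSineSquared, DotProduct) are fitted to the evaluated (config, loss)
   pairs and ranked by the sum of squared errors of the posterior mean at
   the training inputs; the minimum-SSE kernel is kept;
3. exploration — fifteen rounds of: fit the GP to all evaluations,
   compute EI on the not-yet-evaluated candidates, evaluate the argmax.

The EI acquisition, with f+ the lowest loss observed so far:

    Z  = (f+ - mu(x)) / sigma(x)
    EI = (f+ - mu(x)) * Phi(Z) + sigma(x) * phi(Z)    if sigma(x) > 0
    EI = 0                                            if sigma(x) = 0

This is the improvement-for-minimization convention.  A literal mode
with the sign flipped (Z = (mu - f+)/sigma) is available via
``mode="literal"`` for comparison; under argmax-EI selection it steers
toward high predicted loss and is not the default.

GP regression itself delegates to scikit-learn; the acquisition,
no-repetition bookkeeping, kernel comparison and loop logic live here.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable

import numpy as np
from scipy.stats import norm
from sklearn.gaussian_process import GaussianProcessRegressor
from sklearn.gaussian_process.kernels import (
    RBF,
    DotProduct,
    ExpSineSquared,
    Matern,
    RationalQuadratic,
)

#: kernel comparison candidates, in canonical order (also the tie-break order)
KERNEL_ORDER = ("Matern", "RBF", "RationalQuadratic", "ExpSineSquared", "DotProduct")


def _make_kernel(name: str):
    return {
        "Matern": Matern(),
        "RBF": RBF(),
        "RationalQuadratic": RationalQuadratic(),
        "ExpSineSquared": ExpSineSquared(),
        "DotProduct": DotProduct(),
    }[name]


def expected_improvement(
    mu: np.ndarray, sigma: np.ndarray, f_best: float, mode: str = "min"
) -> np.ndarray:
    """EI acquisition for candidate posterior means/SDs.

    ``mode="min"`` (default): improvement below the incumbent best loss.
    ``mode="literal"``: the sign-flipped variant (Z = (mu - f+)/sigma).
    EI is exactly 0 wherever sigma == 0.
    """
    mu = np.atleast_1d(np.asarray(mu, dtype=float))
    sigma = np.atleast_1d(np.asarray(sigma, dtype=float))
    if np.any(sigma < 0):
        raise ValueError("sigma must be >= 0")
    if mode == "min":
        diff = f_best - mu
    elif mode == "literal":
        diff = mu - f_best
    else:
        raise ValueError("mode must be 'min' or 'literal'")
    ei = np.zeros_like(mu)
    pos = sigma > 0
    z = diff[pos] / sigma[pos]
    ei[pos] = diff[pos] * norm.cdf(z) + sigma[pos] * norm.pdf(z)
    return ei


@dataclass
class SearchSpace:
    """Discrete candidate grid per hyperparameter."""

    filter_size: tuple[int, ...] = (3, 5, 7, 9)
    dropout_rate: tuple[float, ...] = (0.1, 0.15, 0.2, 0.25, 0.3, 0.35, 0.4, 0.45, 0.5, 0.55, 0.6)
    epochs: tuple[int, ...] = (10, 20, 30, 40, 50, 60, 70, 80, 90, 100)

    def grid(self) -> list[tuple]:
        return [
            (f, d, e)
            for f in self.filter_size
            for d in self.dropout_rate
            for e in self.epochs
        ]

    def normalize(self, configs: np.ndarray) -> np.ndarray:
        """Map configs onto [0,1]^3 for the GP (comparable length scales)."""
        lo = np.array([min(self.filter_size), min(self.dropout_rate), min(self.epochs)], float)
        hi = np.array([max(self.filter_size), max(self.dropout_rate), max(self.epochs)], float)
        span = np.where(hi > lo, hi - lo, 1.0)
        return (np.asarray(configs, float) - lo) / span


@dataclass
class BoState:
    """Evaluated configurations, losses, chosen kernel and EI trace."""

    space: SearchSpace
    configs: list[tuple] = field(default_factory=list)
    losses: list[float] = field(default_factory=list)
    phase: str = "presample"
    kernel_name: str | None = None
    kernel_sse: dict[str, float] = field(default_factory=dict)
    ei_trace: list[float] = field(default_factory=list)
    exhausted: bool = False

    @property
    def f_best(self) -> float:
        return float(np.min(self.losses))

    @property
    def best_config(self) -> tuple:
        return self.configs[int(np.argmin(self.losses))]

    def remaining(self) -> list[tuple]:
        seen = set(self.configs)
        return [c for c in self.space.grid() if c not in seen]

    def to_dict(self) -> dict:
        return {
            "configs": [list(c) for c in self.configs],
            "losses": self.losses,
            "phase": self.phase,
            "kernel": self.kernel_name,
            "kernel_sse": self.kernel_sse,
            "ei_trace": self.ei_trace,
            "best_config": list(self.best_config),
            "f_best": self.f_best,
        }


Objective = Callable[[tuple], float]


def presample(
    space: SearchSpace, objective: Objective, n: int = 5, seed: int = 0
) -> BoState:
    """Evaluate n distinct uniformly drawn configurations."""
    grid = space.grid()
    if n > len(grid):
        raise ValueError(f"space has {len(grid)} configs, cannot presample {n}")
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(grid), size=n, replace=False)
    state = BoState(space=space)
    for i in idx:
        cfg = grid[i]
        state.configs.append(cfg)
        state.losses.append(float(objective(cfg)))
    state.phase = "kernel_compare"
    return state


def _fit_gp(state: BoState, kernel) -> GaussianProcessRegressor:
    X = state.space.normalize(np.array(state.configs, dtype=float))
    y = np.array(state.losses)
    gp = GaussianProcessRegressor(
        kernel=kernel, alpha=1e-10, normalize_y=True, n_restarts_optimizer=2,
        random_state=0,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        gp.fit(X, y)
    return gp


def compare_kernels(
    state: BoState, kernels: tuple[str, ...] = KERNEL_ORDER
) -> BoState:
    """Score each kernel by training-input SSE of the GP posterior mean.

    A kernel whose fit fails records infinite SSE rather than aborting.
    Ties break by position in ``kernels``.
    """
    if len(state.configs) < 2:
        raise ValueError("need at least 2 evaluated configs to compare kernels")
    X = state.space.normalize(np.array(state.configs, dtype=float))
    y = np.array(state.losses)
    sses: dict[str, float] = {}
    for name in kernels:
        try:
            gp = _fit_gp(state, _make_kernel(name))
            pred = gp.predict(X)
            sses[name] = float(np.sum((pred - y) ** 2))
        except Exception:
            sses[name] = float("inf")
    best = min(kernels, key=lambda k: (sses[k], kernels.index(k)))
    state.kernel_sse = sses
    state.kernel_name = best
    state.phase = "explore"
    return state


def bo_explore(
    state: BoState,
    objective: Objective,
    n_iter: int = 15,
    mode: str = "min",
) -> BoState:
    """Argmax-EI exploration; never re-evaluates a configuration.

    Stops early (flagged) if the candidate grid is exhausted.  Ties in EI
    break by first occurrence in grid order.
    """
    if state.kernel_name is None:
        raise ValueError("choose a kernel before exploring (compare_kernels)")
    for _ in range(n_iter):
        remaining = state.remaining()
        if not remaining:
            state.exhausted = True
            break
        gp = _fit_gp(state, _make_kernel(state.kernel_name))
        Xc = state.space.normalize(np.array(remaining, dtype=float))
        mu, sigma = gp.predict(Xc, return_std=True)
        ei = expected_improvement(mu, sigma, state.f_best, mode=mode)
        pick = int(np.argmax(ei))  # argmax returns the first maximizer
        state.ei_trace.append(float(ei[pick]))
        cfg = remaining[pick]
        state.configs.append(cfg)
        state.losses.append(float(objective(cfg)))
    return state


def optimize(
    space: SearchSpace,
    objective: Objective,
    n_presample: int = 5,
    n_iter: int = 15,
    seed: int = 0,
    mode: str = "min",
) -> BoState:
    """Full pre-sample -> kernel comparison -> exploration pipeline."""
    state = presample(space, objective, n=n_presample, seed=seed)
    state = compare_kernels(state)
    return bo_explore(state, objective, n_iter=n_iter, mode=mode)
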