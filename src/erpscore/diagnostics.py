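"""Residual diagnostics for adjudicating between regression models.

A low RMSE alone does not make a trustworthy model: its residuals should
look like exchangeable noise.  Two standard graphical checks are computed
as data (and optionally rendered):

* QQ-against-normal — ordered standardized residuals against normal
  quantiles at plotting positions (i - 0.5)/n; linearity indicates
  normally distributed residuals.  Backed by a Shapiro-Wilk test.
* residual-vs-fitted — residual spread and sign should be patternless
  over the fitted value (homoscedasticity).  Quantified by the Pearson
  correlation of |residual| with fitted value and a runs test on residual
  signs ordered by fitted value.

Decisions are reported together with their statistics, never as bare
booleans, since the thresholds are conventional surrogates for what is
usually judged by eye.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats


def qq_data(residuals: np.ndarray) -> np.ndarray:
    """(theoretical normal quantile, ordered standardized residual) pairs.

    Plotting positions (i - 0.5)/n.  Location-scale equivariant in the
    sample coordinate: standardization uses the residuals' own mean/SD.
    """
    r = np.asarray(residuals, dtype=float)
    n = len(r)
    if n < 3:
        raise ValueError("need at least 3 residuals for a QQ plot")
    sd = r.std(ddof=1)
    z = (r - r.mean()) / sd if sd > 0 else r - r.mean()
    sample_q = np.sort(z)
    theo_q = stats.norm.ppf((np.arange(1, n + 1) - 0.5) / n)
    return np.column_stack([theo_q, sample_q])


def _runs_test(signs: np.ndarray) -> tuple[float, float]:
    """Wald-Wolfowitz runs test on a boolean sequence; (z, p)."""
    n1 = int(signs.sum())
    n2 = len(signs) - n1
    if n1 == 0 or n2 == 0:
        return 0.0, 1.0
    runs = 1 + int(np.sum(signs[1:] != signs[:-1]))
    n = n1 + n2
    mu = 2.0 * n1 * n2 / n + 1.0
    var = 2.0 * n1 * n2 * (2.0 * n1 * n2 - n) / (n**2 * (n - 1.0))
    if var <= 0:
        return 0.0, 1.0
    z = (runs - mu) / np.sqrt(var)
    p = 2.0 * stats.norm.sf(abs(z))
    return float(z), float(p)


@dataclass
class ResidualDiagnostics:
    """QQ data, residual-vs-fitted data and numeric surrogate checks."""

    qq_pairs: np.ndarray                 # (n, 2)
    fitted: np.ndarray
    residuals: np.ndarray
    shapiro_stat: float
    shapiro_p: float
    normality_ok: bool
    abs_corr: float                      # corr(|residual|, fitted)
    abs_corr_p: float
    runs_z: float
    runs_p: float
    pattern_ok: bool
    alpha: float
    degenerate: bool = False             # constant residuals: tests undefined

    def to_dict(self) -> dict:
        return {
            "shapiro_stat": self.shapiro_stat,
            "shapiro_p": self.shapiro_p,
            "normality_ok": bool(self.normality_ok),
            "abs_corr": self.abs_corr,
            "abs_corr_p": self.abs_corr_p,
            "runs_z": self.runs_z,
            "runs_p": self.runs_p,
            "pattern_ok": bool(self.pattern_ok),
            "alpha": self.alpha,
            "degenerate": self.degenerate,
        }


def check_residuals(
    fitted: np.ndarray, residuals: np.ndarray, alpha: float = 0.05
) -> ResidualDiagnostics:
    """Numeric surrogate for by-eye QQ and residual-vs-fitted inspection."""
    fitted = np.asarray(fitted, dtype=float)
    r = np.asarray(residuals, dtype=float)
    if len(r) < 8:
        raise ValueError("need at least 8 residuals for decisions")
    if r.std(ddof=1) == 0:
        return ResidualDiagnostics(
            qq_pairs=qq_data(r),
            fitted=fitted,
            residuals=r,
            shapiro_stat=float("nan"),
            shapiro_p=float("nan"),
            normality_ok=False,
            abs_corr=0.0,
            abs_corr_p=1.0,
            runs_z=0.0,
            runs_p=1.0,
            pattern_ok=True,
            alpha=alpha,
            degenerate=True,
        )
    sw_stat, sw_p = stats.shapiro(r)
    ac, ac_p = stats.pearsonr(np.abs(r), fitted)
    order = np.argsort(fitted, kind="stable")
    rz, rp = _runs_test(r[order] > np.median(r))
    return ResidualDiagnostics(
        qq_pairs=qq_data(r),
        fitted=fitted,
        residuals=r,
        shapiro_stat=float(sw_stat),
        shapiro_p=float(sw_p),
        normality_ok=bool(sw_p > alpha),
        abs_corr=float(ac),
        abs_corr_p=float(ac_p),
        runs_z=rz,
        runs_p=rp,
        pattern_ok=bool(ac_p > alpha and rp > alpha),
        alpha=alpha,
    )


def plot_diagnostics(diag: ResidualDiagnostics, path_prefix: str) -> list[str]:
    """Render QQ and residual-vs-fitted plots to ``<prefix>_{qq,rvf}.png``."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    paths = []
    fig, ax = plt.subplots(figsize=(4, 4))
    ax.plot(diag.qq_pairs[:, 0], diag.qq_pairs[:, 1], "o", ms=4)
    lim = np.abs(diag.qq_pairs).max() * 1.1
    ax.plot([-lim, lim], [-lim, lim], "k--", lw=1)
    ax.set_xlabel("theoretical quantiles")
    ax.set_ylabel("sample quantiles")
    fig.tight_layout()
    p = f"{path_prefix}_qq.png"
    fig.savefig(p, dpi=100)
    plt.close(fig)
    paths.append(p)

    fig, ax = plt.subplots(figsize=(4, 4))
    ax.plot(diag.fitted, diag.residuals, "o", ms=4)
    ax.axhline(0, color="k", lw=1, ls="--")
    ax.set_xlabel("fitted")
    ax.set_ylabel("residual")
    fig.tight_layout()
    p = f"{path_prefix}_rvf.png"
    fig.savefig(p, dpi=100)
    plt.close(fig)
    paths.append(p)
    return paths
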