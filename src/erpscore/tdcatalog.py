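"""Catalog of 107 per-window time-domain characteristics.

Each entry is a named pure function mapping a 1-D window of samples to a
scalar.  The catalog spans the three families used for highly comparative
time-series characterisation: signal statistics (moments, order statistics,
proportions within k standard deviations of the mean), correlation
properties (autocorrelations at fixed lags and their summaries, partial
autocorrelations, trend and difference statistics) and entropies /
complexity measures (histogram, spectral, permutation, approximate and
sample entropies, Lempel-Ziv).

The catalog is a versioned registry: entry names and order are stable
across runs, and there are exactly 107 entries.  Degenerate inputs
(constant windows, windows shorter than an embedding) fall back to
documented finite values — a characteristic never returns NaN or inf.
Fallback conventions: ratio-type statistics return 0 when their
denominator vanishes; "proportion within k SD" is 1 for a constant window
(every sample is within zero deviation of the mean); sample entropy is
capped when no template matches exist.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable

import numpy as np
from scipy import signal as _sig
from scipy import stats as _stats

CATALOG_VERSION = "1.0"

Characteristic = Callable[[np.ndarray], float]


# ---------------------------------------------------------------------------
# helpers (all guard against degenerate inputs)
# ---------------------------------------------------------------------------

def _sd(x: np.ndarray) -> float:
    return float(np.std(x, ddof=1)) if len(x) > 1 else 0.0


def _acf(x: np.ndarray, lag: int) -> float:
    n = len(x)
    if lag >= n:
        return 0.0
    xc = x - x.mean()
    denom = float(np.dot(xc, xc))
    if denom == 0:
        return 0.0
    return float(np.dot(xc[:-lag], xc[lag:]) / denom)


def _acf_vector(x: np.ndarray, max_lag: int) -> np.ndarray:
    return np.array([_acf(x, k) for k in range(1, max_lag + 1)])


def _pacf(x: np.ndarray, lag: int) -> float:
    """Partial autocorrelation via Durbin-Levinson on the biased ACF."""
    if lag >= len(x):
        return 0.0
    r = np.concatenate([[1.0], _acf_vector(x, lag)])
    phi = np.zeros((lag + 1, lag + 1))
    phi[1, 1] = r[1]
    for k in range(2, lag + 1):
        num = r[k] - np.dot(phi[k - 1, 1:k], r[1:k][::-1])
        den = 1.0 - np.dot(phi[k - 1, 1:k], r[1:k])
        if abs(den) < 1e-12:
            return 0.0
        phi[k, k] = num / den
        for j in range(1, k):
            phi[k, j] = phi[k - 1, j] - phi[k, k] * phi[k - 1, k - j]
    v = phi[lag, lag]
    return float(v) if np.isfinite(v) else 0.0


def _periodogram(x: np.ndarray) -> np.ndarray:
    xc = x - x.mean()
    f = np.abs(np.fft.rfft(xc)) ** 2
    return f


def _perm_entropy(x: np.ndarray, order: int) -> float:
    n = len(x)
    if n < order + 1:
        return 0.0
    patterns: dict[tuple, int] = {}
    for i in range(n - order + 1):
        key = tuple(np.argsort(x[i : i + order], kind="stable"))
        patterns[key] = patterns.get(key, 0) + 1
    counts = np.array(list(patterns.values()), dtype=float)
    p = counts / counts.sum()
    h = -np.sum(p * np.log(p))
    return float(h / math.log(math.factorial(order)))


def _embed_count(x: np.ndarray, m: int, r: float, exclude_self: bool) -> int:
    n = len(x) - m + 1
    if n <= 0:
        return 0
    emb = np.lib.stride_tricks.sliding_window_view(x, m)
    d = np.max(np.abs(emb[:, None, :] - emb[None, :, :]), axis=2)
    within = d <= r
    total = int(within.sum())
    if exclude_self:
        total -= n
    return total


#: entropy estimators embed pairwise distances (O(n^2)); long windows are
#: truncated to this many samples to keep them tractable
_ENTROPY_MAX_N = 1000


def _approx_entropy(x: np.ndarray, m: int) -> float:
    x = x[:_ENTROPY_MAX_N]
    n = len(x)
    r = 0.2 * _sd(x)
    if n < m + 2 or r == 0:
        return 0.0

    def phi(mm: int) -> float:
        nn = n - mm + 1
        emb = np.lib.stride_tricks.sliding_window_view(x, mm)
        d = np.max(np.abs(emb[:, None, :] - emb[None, :, :]), axis=2)
        c = (d <= r).sum(axis=1) / nn  # self-match included -> c >= 1/nn
        return float(np.mean(np.log(c)))

    return phi(m) - phi(m + 1)


def _sample_entropy(x: np.ndarray, m: int) -> float:
    x = x[:_ENTROPY_MAX_N]
    n = len(x)
    r = 0.2 * _sd(x)
    if n < m + 2 or r == 0:
        return 0.0
    b = _embed_count(x[: n - 1], m, r, exclude_self=True)
    a = _embed_count(x, m + 1, r, exclude_self=True)
    if b == 0:
        return 0.0
    if a == 0:
        return float(np.log(b + 1))  # capped: no (m+1)-matches observed
    return float(-np.log(a / b))


def _lempel_ziv(x: np.ndarray) -> float:
    med = np.median(x)
    s = "".join("1" if v > med else "0" for v in x)
    n = len(s)
    if n < 2:
        return 0.0
    phrases, i, k = 0, 0, 1
    seen: set[str] = set()
    while i + k <= n:
        sub = s[i : i + k]
        if sub in seen:
            k += 1
        else:
            seen.add(sub)
            phrases += 1
            i += k
            k = 1
    if i < n:
        phrases += 1
    return float(phrases * math.log2(n) / n)


def _runs_longest_above(x: np.ndarray) -> float:
    above = x > x.mean()
    best = cur = 0
    for a in above:
        cur = cur + 1 if a else 0
        best = max(best, cur)
    return best / len(x)


def _statav(x: np.ndarray, k: int) -> float:
    n = len(x)
    seg = n // k
    sd = _sd(x)
    if seg < 2 or sd == 0:
        return 0.0
    means = [x[i * seg : (i + 1) * seg].mean() for i in range(k)]
    return float(np.std(means, ddof=1) / sd)


def _hjorth_mobility(x: np.ndarray) -> float:
    sd = _sd(x)
    if sd == 0 or len(x) < 3:
        return 0.0
    return _sd(np.diff(x)) / sd


# ---------------------------------------------------------------------------
# registry construction
# ---------------------------------------------------------------------------

def _build_entries() -> list[tuple[str, Characteristic]]:
    e: list[tuple[str, Characteristic]] = []

    def add(name: str, fn: Characteristic) -> None:
        e.append((name, fn))

    # --- distribution statistics (20) ---
    add("mean", lambda x: float(np.mean(x)))
    add("std", lambda x: _sd(x))
    add("variance", lambda x: _sd(x) ** 2)
    add("skewness", lambda x: float(_stats.skew(x)) if _sd(x) > 0 else 0.0)
    add("kurtosis", lambda x: float(_stats.kurtosis(x)) if _sd(x) > 0 else 0.0)
    add("min", lambda x: float(np.min(x)))
    add("max", lambda x: float(np.max(x)))
    add("range", lambda x: float(np.ptp(x)))
    add("median", lambda x: float(np.median(x)))
    add("mad", lambda x: float(np.median(np.abs(x - np.median(x)))))
    add("iqr", lambda x: float(np.subtract(*np.percentile(x, [75, 25]))))
    add("rms", lambda x: float(np.sqrt(np.mean(x**2))))
    add("abs_mean", lambda x: float(np.mean(np.abs(x))))
    add("trimmed_mean_10", lambda x: float(_stats.trim_mean(x, 0.1)))
    add("cv", lambda x: _sd(x) / abs(np.mean(x)) if np.mean(x) != 0 else 0.0)
    add("mean_minus_median", lambda x: float(np.mean(x) - np.median(x)))
    add("max_abs", lambda x: float(np.max(np.abs(x))))
    add("mean_square", lambda x: float(np.mean(x**2)))
    add(
        "crest_factor",
        lambda x: float(np.max(np.abs(x)) / np.sqrt(np.mean(x**2)))
        if np.any(x != 0)
        else 0.0,
    )
    add(
        "abs_dev_skewness",
        lambda x: float(_stats.skew(np.abs(x - x.mean()))) if _sd(x) > 0 else 0.0,
    )

    # --- quantiles (10) ---
    for q in (1, 5, 10, 25, 40, 60, 75, 90, 95, 99):
        add(f"quantile_{q:02d}", lambda x, q=q: float(np.percentile(x, q)))

    # --- proportions within k standard deviations of the mean (6) ---
    # constant window: |x - mean| = 0 <= 0, so the proportion is 1 by design
    for k in (0.5, 1.0, 1.5, 2.0, 2.5, 3.0):
        add(
            f"prop_within_{k:.1f}sd".replace(".", "p"),
            lambda x, k=k: float(
                np.mean(np.abs(x - x.mean()) <= k * np.std(x, ddof=1))
            )
            if len(x) > 1
            else 1.0,
        )

    # --- positional / sign proportions (6) ---
    add("prop_above_mean", lambda x: float(np.mean(x > x.mean())))
    add("prop_positive", lambda x: float(np.mean(x > 0)))
    add("argmax_frac", lambda x: float(np.argmax(x) / max(len(x) - 1, 1)))
    add("argmin_frac", lambda x: float(np.argmin(x) / max(len(x) - 1, 1)))
    add(
        "prop_above_mean_plus_sd",
        lambda x: float(np.mean(x > x.mean() + np.std(x, ddof=1))) if len(x) > 1 else 0.0,
    )
    add(
        "prop_below_mean_minus_sd",
        lambda x: float(np.mean(x < x.mean() - np.std(x, ddof=1))) if len(x) > 1 else 0.0,
    )

    # --- successive-difference statistics (9) ---
    add("mean_abs_diff", lambda x: float(np.mean(np.abs(np.diff(x)))))
    add("rms_diff", lambda x: float(np.sqrt(np.mean(np.diff(x) ** 2))))
    add("max_abs_diff", lambda x: float(np.max(np.abs(np.diff(x)))))
    add("diff_sd", lambda x: _sd(np.diff(x)))
    add("diff_skewness", lambda x: float(_stats.skew(np.diff(x))) if _sd(np.diff(x)) > 0 else 0.0)
    add("diff_kurtosis", lambda x: float(_stats.kurtosis(np.diff(x))) if _sd(np.diff(x)) > 0 else 0.0)

    def _trev(x: np.ndarray) -> float:
        d = np.diff(x)
        m2 = np.mean(d**2)
        return float(np.mean(d**3) / m2**1.5) if m2 > 0 else 0.0

    add("time_rev_asymmetry", _trev)
    add(
        "zero_cross_rate",
        lambda x: float(np.mean(np.signbit(x[:-1]) != np.signbit(x[1:]))),
    )
    add(
        "mean_cross_rate",
        lambda x: float(
            np.mean((x[:-1] - x.mean() > 0) != (x[1:] - x.mean() > 0))
        ),
    )

    # --- trend (5) ---
    def _trend(x: np.ndarray) -> tuple[float, float]:
        t = np.arange(len(x), dtype=float)
        if _sd(x) == 0:
            return 0.0, 0.0
        slope, intercept = np.polyfit(t, x, 1)
        fit = slope * t + intercept
        ss_res = float(np.sum((x - fit) ** 2))
        ss_tot = float(np.sum((x - x.mean()) ** 2))
        r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 0.0
        return float(slope), r2

    add("trend_slope", lambda x: _trend(x)[0])
    add("trend_r2", lambda x: _trend(x)[1])
    add("sd_detrended", lambda x: _sd(x - np.polyval(np.polyfit(np.arange(len(x)), x, 1), np.arange(len(x)))))
    add(
        "half_mean_diff",
        lambda x: float(x[len(x) // 2 :].mean() - x[: len(x) // 2].mean()),
    )

    def _half_sd_contrast(x: np.ndarray) -> float:
        s1 = _sd(x[: len(x) // 2])
        s2 = _sd(x[len(x) // 2 :])
        return (s2 - s1) / (s2 + s1) if s1 + s2 > 0 else 0.0

    add("half_sd_contrast", _half_sd_contrast)

    # --- stationarity (2) ---
    add("statav_2", lambda x: _statav(x, 2))
    add("statav_5", lambda x: _statav(x, 5))

    # --- autocorrelation at fixed lags (12) ---
    for lag in range(1, 13):
        add(f"acf_lag_{lag:02d}", lambda x, lag=lag: _acf(x, lag))

    # --- autocorrelation of absolute deviations (3) ---
    for lag in range(1, 4):
        add(
            f"abs_acf_lag_{lag}",
            lambda x, lag=lag: _acf(np.abs(x - x.mean()), lag),
        )

    # --- autocorrelation of squared deviations (3) ---
    for lag in range(1, 4):
        add(
            f"sq_acf_lag_{lag}",
            lambda x, lag=lag: _acf((x - x.mean()) ** 2, lag),
        )

    # --- partial autocorrelation (3) ---
    for lag in range(1, 4):
        add(f"pacf_lag_{lag}", lambda x, lag=lag: _pacf(x, lag))

    # --- ACF summaries (6) ---
    def _first_crossing(x: np.ndarray, level: float) -> float:
        # searched up to 100 lags; 1.0 means "no crossing within range"
        n = min(len(x), 100)
        for lag in range(1, n):
            if _acf(x, lag) <= level:
                return lag / n
        return 1.0

    add("acf_first_zero_frac", lambda x: _first_crossing(x, 0.0))
    add("acf_first_1e_frac", lambda x: _first_crossing(x, 1.0 / math.e))
    add("sum_abs_acf_10", lambda x: float(np.sum(np.abs(_acf_vector(x, 10)))))
    add("sum_sq_acf_10", lambda x: float(np.sum(_acf_vector(x, 10) ** 2)))

    def _ar1(x: np.ndarray) -> tuple[float, float]:
        if len(x) < 3 or _sd(x) == 0:
            return 0.0, 0.0
        a, b = x[:-1], x[1:]
        va = float(np.var(a))
        if va == 0:
            return 0.0, 0.0
        coef = float(np.cov(a, b)[0, 1] / va)
        resid = b - (b.mean() + coef * (a - a.mean()))
        ratio = _sd(resid) / _sd(x)
        return coef, ratio

    add("ar1_coef", lambda x: _ar1(x)[0])
    add("ar1_resid_ratio", lambda x: _ar1(x)[1])

    # --- entropies & complexity (12) ---
    def _hist_entropy(x: np.ndarray, bins: int) -> float:
        if _sd(x) == 0:
            return 0.0
        counts, _ = np.histogram(x, bins=bins)
        p = counts[counts > 0] / counts.sum()
        return float(-np.sum(p * np.log(p)) / math.log(bins))

    for bins in (5, 10, 20):
        add(f"hist_entropy_{bins}bins", lambda x, bins=bins: _hist_entropy(x, bins))

    def _spectral_entropy(x: np.ndarray) -> float:
        p = _periodogram(x)[1:]  # drop DC (mean removed anyway)
        tot = p.sum()
        if tot == 0 or len(p) < 2:
            return 0.0
        q = p / tot
        q = q[q > 0]
        return float(-np.sum(q * np.log(q)) / math.log(len(p)))

    add("spectral_entropy", _spectral_entropy)
    for order in (3, 4, 5):
        add(f"perm_entropy_o{order}", lambda x, order=order: _perm_entropy(x, order))
    add("approx_entropy_m1", lambda x: _approx_entropy(x, 1))
    add("approx_entropy_m2", lambda x: _approx_entropy(x, 2))
    add("sample_entropy_m2", lambda x: _sample_entropy(x, 2))
    add("lempel_ziv", _lempel_ziv)

    def _petrosian(x: np.ndarray) -> float:
        d = np.diff(x)
        nd = int(np.sum(np.signbit(d[:-1]) != np.signbit(d[1:])))
        n = len(x)
        if nd == 0:
            return 1.0
        return float(math.log10(n) / (math.log10(n) + math.log10(n / (n + 0.4 * nd))))

    add("petrosian_fd", _petrosian)

    def _hjorth_complexity(x: np.ndarray) -> float:
        m = _hjorth_mobility(x)
        if m == 0 or len(x) < 4:
            return 0.0
        m2 = _hjorth_mobility(np.diff(x))
        return m2 / m if m > 0 else 0.0

    add("hjorth_complexity", _hjorth_complexity)

    # --- local structure / runs (6) ---
    def _n_local_extrema(x: np.ndarray, kind: str) -> float:
        if len(x) < 3:
            return 0.0
        y = x if kind == "max" else -x
        idx, _ = _sig.find_peaks(y)
        return len(idx) / len(x)

    add("local_maxima_frac", lambda x: _n_local_extrema(x, "max"))
    add("local_minima_frac", lambda x: _n_local_extrema(x, "min"))
    add("longest_run_above_mean_frac", _runs_longest_above)
    add(
        "binary_transition_rate",
        lambda x: float(np.mean((x[:-1] > np.median(x)) != (x[1:] > np.median(x)))),
    )
    add("hjorth_mobility", _hjorth_mobility)

    def _rescaled_range(x: np.ndarray) -> float:
        sd = _sd(x)
        if sd == 0:
            return 0.0
        c = np.cumsum(x - x.mean())
        return float(np.ptp(c) / (len(x) * sd))

    add("rescaled_range", _rescaled_range)

    # --- coarse spectral shape (3) ---
    def _dominant_freq_frac(x: np.ndarray) -> float:
        p = _periodogram(x)[1:]
        if p.sum() == 0 or len(p) < 2:
            return 0.0
        return float((np.argmax(p) + 1) / len(p))

    def _spectral_centroid_frac(x: np.ndarray) -> float:
        p = _periodogram(x)[1:]
        tot = p.sum()
        if tot == 0 or len(p) < 2:
            return 0.0
        idx = np.arange(1, len(p) + 1)
        return float(np.sum(idx * p) / (tot * len(p)))

    def _low_half_power_frac(x: np.ndarray) -> float:
        p = _periodogram(x)[1:]
        tot = p.sum()
        if tot == 0 or len(p) < 2:
            return 0.0
        return float(p[: len(p) // 2].sum() / tot)

    add("dominant_freq_frac", _dominant_freq_frac)
    add("spectral_centroid_frac", _spectral_centroid_frac)
    add("low_half_power_frac", _low_half_power_frac)

    return e


@dataclass
class TdCatalog:
    """Ordered, versioned registry of scalar window characteristics."""

    entries: list[tuple[str, Characteristic]] = field(default_factory=_build_entries)
    version: str = CATALOG_VERSION

    def __post_init__(self) -> None:
        names = [n for n, _ in self.entries]
        if len(names) != len(set(names)):
            raise ValueError("catalog contains duplicate names")

    @property
    def names(self) -> list[str]:
        return [n for n, _ in self.entries]

    def __len__(self) -> int:
        return len(self.entries)


_DEFAULT: TdCatalog | None = None


def default_catalog() -> TdCatalog:
    global _DEFAULT
    if _DEFAULT is None:
        _DEFAULT = TdCatalog()
        assert len(_DEFAULT) == 107, f"catalog has {len(_DEFAULT)} entries, expected 107"
    return _DEFAULT


def compute_td_characteristics(
    window: np.ndarray, catalog: TdCatalog | None = None
) -> np.ndarray:
    """Evaluate every catalog characteristic on one window.

    Returns one finite value per entry, in catalog order.  Raises on
    windows with fewer than 2 samples.
    """
    x = np.asarray(window, dtype=float)
    if x.ndim != 1 or len(x) < 2:
        raise ValueError("window must be 1-D with at least 2 samples")
    if catalog is None:
        catalog = default_catalog()
    out = np.empty(len(catalog))
    for i, (_, fn) in enumerate(catalog.entries):
        v = fn(x)
        out[i] = v if np.isfinite(v) else 0.0  # safety net; fallbacks cover known cases
    return out
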