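"""Candidate feature vector (CFV) construction from grand-average ERPs.

Two feature families feed the multi-trial regression:

* the prominent-point block — for each stimulus, peak amplitude, peak
  latency and interval mean of the four canonical auditory deflections
  (Pa, P1, N1, P2, defined as extrema in the 25-35, 60-80, 90-110 and
  150-250 ms windows; N1 is a negative deflection) plus the four relative
  band powers (delta/theta/alpha/beta), i.e. 16 features per stimulus and
  80 over five stimuli;

* windowed time-domain dynamics — 107 catalog characteristics computed in
  25 ms windows with 50 % overlap across the whole epoch, summarised as
  the slope and coefficient of variation of each characteristic between
  adjacent windows, then screened for between-group separation.

Feature names encode their provenance
(``<stimulus>|prominent|<component>|<kind>``,
``<stimulus>|band_power|<band>``,
``<stimulus>|td|<char>|w<i>|slope|cv``) and parse back losslessly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal as _sig

from .preprocess import ErpWaveform
from .tdcatalog import TdCatalog, compute_td_characteristics, default_catalog

#: default search windows (ms) for the prominent points
DEFAULT_WINDOWS: dict[str, tuple[float, float]] = {
    "Pa": (25.0, 35.0),
    "P1": (60.0, 80.0),
    "N1": (90.0, 110.0),
    "P2": (150.0, 250.0),
}

#: standard clinical EEG rhythm bands (Hz)
DEFAULT_BANDS: dict[str, tuple[float, float]] = {
    "delta": (0.5, 4.0),
    "theta": (4.0, 8.0),
    "alpha": (8.0, 13.0),
    "beta": (13.0, 30.0),
}


@dataclass
class ProminentPoint:
    """One detected ERP deflection."""

    label: str
    window_ms: tuple[float, float]
    peak_amplitude: float   # uV
    peak_latency: float     # ms
    interval_mean: float    # uV


def detect_prominent_points(
    erp: ErpWaveform,
    windows: dict[str, tuple[float, float]] | None = None,
    n1_negative: bool = True,
) -> dict[str, ProminentPoint]:
    """Locate Pa, P1, N1 and P2 in their search windows.

    Positive components are the argmax in their window; N1 the argmin
    (toggle via ``n1_negative``).  Ties break toward the earliest latency
    (guaranteed by argmax/argmin returning the first occurrence).
    """
    if windows is None:
        windows = DEFAULT_WINDOWS
    t = erp.times
    if t[-1] < max(hi for _, hi in windows.values()):
        raise ValueError(
            f"ERP ends at {t[-1]:.0f} ms; must cover the latest search window"
        )
    out: dict[str, ProminentPoint] = {}
    for label, (lo, hi) in windows.items():
        mask = (t >= lo) & (t <= hi)
        idx = np.flatnonzero(mask)
        seg = erp.data[idx]
        if label == "N1" and n1_negative:
            k = int(np.argmin(seg))
        else:
            k = int(np.argmax(seg))
        out[label] = ProminentPoint(
            label=label,
            window_ms=(lo, hi),
            peak_amplitude=float(seg[k]),
            peak_latency=float(t[idx[k]]),
            interval_mean=float(seg.mean()),
        )
    return out


def relative_band_powers(
    erp: ErpWaveform, bands: dict[str, tuple[float, float]] | None = None
) -> dict[str, float]:
    """Periodogram power per rhythm band, normalized over the band union."""
    if bands is None:
        bands = DEFAULT_BANDS
    freqs, psd = _sig.periodogram(erp.data, fs=erp.fs)
    raw = {}
    for name, (lo, hi) in bands.items():
        mask = (freqs >= lo) & (freqs < hi)
        raw[name] = float(psd[mask].sum())
    total = sum(raw.values())
    if total == 0:
        raise ValueError("zero total band power")
    return {name: p / total for name, p in raw.items()}


def per_stimulus_prominent_block(
    erp: ErpWaveform,
    stimulus: str,
    windows: dict[str, tuple[float, float]] | None = None,
    bands: dict[str, tuple[float, float]] | None = None,
) -> dict[str, float]:
    """The 16 prominent-point features of one stimulus, named."""
    pts = detect_prominent_points(erp, windows)
    powers = relative_band_powers(erp, bands)
    feats: dict[str, float] = {}
    for label, p in pts.items():
        feats[f"{stimulus}|prominent|{label}|amplitude"] = p.peak_amplitude
        feats[f"{stimulus}|prominent|{label}|latency"] = p.peak_latency
        feats[f"{stimulus}|prominent|{label}|interval_mean"] = p.interval_mean
    for band, p in powers.items():
        feats[f"{stimulus}|band_power|{band}"] = p
    return feats


def sliding_windows(
    n_samples: int, fs: float, win_ms: float = 25.0, overlap: float = 0.5
) -> list[tuple[int, int]]:
    """Start/stop sample slices of overlapping windows over a signal.

    Windows start at the signal start; the last incomplete window is
    dropped; count = floor((L - win) / step) + 1 with step = win*(1-overlap).
    """
    win = int(round(win_ms * fs / 1000.0))
    step = win * (1.0 - overlap)
    if step <= 0:
        raise ValueError("overlap must be < 1 (non-positive step)")
    if win >= n_samples:
        raise ValueError("window longer than signal")
    out = []
    i = 0
    while True:
        start = int(np.floor(i * step))
        if start + win > n_samples:
            break
        out.append((start, start + win))
        i += 1
    return out


def slope_cv_dynamics(
    trajectory: np.ndarray, step_ms: float
) -> tuple[np.ndarray, np.ndarray]:
    """Slope and coefficient of variation of adjacent window-value pairs.

    For each pair (f_t, f_{t+1}): slope = (f_{t+1} - f_t) / step_ms and
    CV = sd / |mean| of the pair.  CV is 0 for an equal pair with zero
    mean and NaN (missing, error-flagged) for an unequal pair whose mean
    is zero.
    """
    f = np.asarray(trajectory, dtype=float)
    if len(f) < 2:
        raise ValueError("need at least two windows for dynamics")
    a, b = f[:-1], f[1:]
    slopes = (b - a) / step_ms
    means = (a + b) / 2.0
    sds = np.abs(b - a) / np.sqrt(2.0)  # sd of a 2-point sample (ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        cvs = sds / np.abs(means)
    zero_mean = means == 0
    cvs[zero_mean & (a == b)] = 0.0
    cvs[zero_mean & (a != b)] = np.nan  # flagged missing
    return slopes, cvs


def td_dynamics_features(
    erp: ErpWaveform,
    stimulus: str,
    catalog: TdCatalog | None = None,
    win_ms: float = 25.0,
    overlap: float = 0.5,
) -> dict[str, float]:
    """Slope/CV dynamics of every catalog characteristic for one ERP."""
    if catalog is None:
        catalog = default_catalog()
    wins = sliding_windows(len(erp.data), erp.fs, win_ms, overlap)
    if len(wins) < 2:
        raise ValueError("need at least two windows")
    step_ms = win_ms * (1.0 - overlap)
    values = np.array(
        [compute_td_characteristics(erp.data[a:b], catalog) for a, b in wins]
    )  # (n_windows, 107)
    feats: dict[str, float] = {}
    for ci, cname in enumerate(catalog.names):
        slopes, cvs = slope_cv_dynamics(values[:, ci], step_ms)
        for wi in range(len(slopes)):
            feats[f"{stimulus}|td|{cname}|w{wi:02d}|slope"] = slopes[wi]
            feats[f"{stimulus}|td|{cname}|w{wi:02d}|cv"] = cvs[wi]
    return feats


def build_feature_table(
    erps: dict[tuple[str, str], ErpWaveform],
    include_td: bool = True,
    windows: dict[str, tuple[float, float]] | None = None,
    bands: dict[str, tuple[float, float]] | None = None,
    catalog: TdCatalog | None = None,
    win_ms: float = 25.0,
    overlap: float = 0.5,
) -> pd.DataFrame:
    """Assemble the full candidate feature table.

    ``erps`` maps (subject, stimulus) to a processed grand-average ERP.
    Rows are subjects, columns are named features.
    """
    rows: dict[str, dict[str, float]] = {}
    for (subject, stimulus), erp in sorted(erps.items()):
        row = rows.setdefault(subject, {})
        row.update(per_stimulus_prominent_block(erp, stimulus, windows, bands))
        if include_td:
            row.update(td_dynamics_features(erp, stimulus, catalog, win_ms, overlap))
    table = pd.DataFrame.from_dict(rows, orient="index")
    table.index.name = "subject"
    return table.sort_index()


@dataclass
class ScreeningResult:
    """Outcome of the between-group separation screen."""

    retained: list[str]
    separation: pd.Series       # per-feature standardized separation
    cutoff: float
    n_keep: int | None = None


def screen_td_features(
    table: pd.DataFrame,
    groups: pd.Series,
    cutoff: float = 0.8,
    n_keep: int | None = None,
) -> ScreeningResult:
    """Automated surrogate for by-eye feature screening.

    Retains time-domain dynamics features whose between-group mean
    separation divided by the pooled within-group standard deviation
    exceeds ``cutoff`` (or, when ``n_keep`` is given, the top ``n_keep``
    by that ratio).  Prominent-point and band-power features are always
    retained.  Deterministic given data and settings.
    """
    groups = groups.loc[table.index]
    labels = groups.unique()
    if len(labels) != 2:
        raise ValueError("screening needs exactly two groups")
    ga = table[groups == labels[0]]
    gb = table[groups == labels[1]]
    if len(ga) < 2 or len(gb) < 2:
        raise ValueError("need at least 2 subjects per group")

    td_cols = [c for c in table.columns if "|td|" in c]
    base_cols = [c for c in table.columns if "|td|" not in c]

    mean_a, mean_b = ga[td_cols].mean(), gb[td_cols].mean()
    var_a, var_b = ga[td_cols].var(ddof=1), gb[td_cols].var(ddof=1)
    na, nb = len(ga), len(gb)
    pooled = np.sqrt(((na - 1) * var_a + (nb - 1) * var_b) / (na + nb - 2))
    with np.errstate(divide="ignore", invalid="ignore"):
        sep = (mean_a - mean_b).abs() / pooled
    # 0/0 (constant feature) -> zero separation, never retained; a nonzero
    # mean difference with zero within-group spread ranks as +inf (perfect)
    sep = sep.fillna(0.0)

    if n_keep is not None:
        keep = list(sep.sort_values(ascending=False, kind="stable").index[:n_keep])
    else:
        keep = list(sep.index[sep > cutoff])
    retained = base_cols + keep
    return ScreeningResult(retained=retained, separation=sep, cutoff=cutoff, n_keep=n_keep)
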