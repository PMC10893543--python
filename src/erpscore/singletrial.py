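"""Single-trial branch: time-frequency images and grouped CNN evaluation.

Each filtered, onset-to-response trial becomes a short-time spectral
power image on a 0-100 Hz band, log-scaled, resampled to a fixed small
shape so trials of different (response-time-dependent) lengths batch
together, and z-scored per image.  Every image carries its subject's
MoCA score as the regression label; cross-validation folds are grouped
by subject so no subject contributes to both the training and the test
side of a fold (which would leak the label).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage, signal

from .nn import CnnRegressor, CnnSpec
from .preprocess import EpochSet
from .regression import score


@dataclass
class TfImage:
    """Fixed-shape log-power spectrogram of one trial."""

    power: np.ndarray          # (n_freq_bins, n_time_bins), z-scored log power
    freqs: np.ndarray          # Hz, upper bound <= f_max
    subject: str
    stimulus: str
    trial: int
    label: float               # the subject's MoCA score
    normalization: str = "log-zscore"


def compute_tf_image(
    trial: np.ndarray,
    fs: float,
    f_max: float = 100.0,
    out_shape: tuple[int, int] = (32, 32),
    subject: str = "",
    stimulus: str = "",
    trial_index: int = 0,
    label: float = float("nan"),
) -> TfImage:
    """Short-time spectral power of one trial on a fixed image grid.

    The spectrogram window adapts to the trial length (an eighth of the
    trial, at least 8 samples, 75 % overlap); frequencies above ``f_max``
    are discarded; the power matrix is log10-scaled, resampled to
    ``out_shape`` by spline interpolation and z-scored.  Deterministic.
    """
    x = np.asarray(trial, dtype=float)
    if len(x) < 16:
        raise ValueError(
            f"trial too short for time-frequency analysis "
            f"(subject={subject!r}, stimulus={stimulus!r}, trial={trial_index})"
        )
    nperseg = max(8, min(len(x) // 8 * 2, 256))
    freqs, _, sxx = signal.spectrogram(
        x, fs=fs, nperseg=nperseg, noverlap=int(nperseg * 0.75), detrend="constant"
    )
    keep = freqs <= f_max
    sxx = sxx[keep]
    freqs = freqs[keep]
    if sxx.shape[1] < 2 or sxx.shape[0] < 2:
        raise ValueError("trial too short for the requested grid")
    logp = np.log10(sxx + 1e-12)
    zoom = (out_shape[0] / logp.shape[0], out_shape[1] / logp.shape[1])
    img = ndimage.zoom(logp, zoom, order=1)
    sd = img.std()
    img = (img - img.mean()) / (sd if sd > 0 else 1.0)
    return TfImage(
        power=img,
        freqs=freqs,
        subject=subject,
        stimulus=stimulus,
        trial=trial_index,
        label=label,
    )


def epochs_to_tf_images(
    epochs: EpochSet,
    label: float,
    f_max: float = 100.0,
    out_shape: tuple[int, int] = (32, 32),
) -> list[TfImage]:
    """TF images for every trial of a (filtered, truncated) epoch set.

    Uses per-trial valid lengths when present; trials too short for the
    transform are skipped (they are logged implicitly by their absence).
    """
    images = []
    for ti in range(epochs.n_trials):
        row = epochs.data[ti]
        if epochs.trial_lengths is not None:
            row = row[: epochs.trial_lengths[ti]]
        try:
            images.append(
                compute_tf_image(
                    row,
                    epochs.fs,
                    f_max=f_max,
                    out_shape=out_shape,
                    subject=epochs.subject,
                    stimulus=epochs.stimulus,
                    trial_index=ti,
                    label=label,
                )
            )
        except ValueError:
            continue
    return images


def _group_folds(groups: np.ndarray, k: int, seed: int) -> list[tuple[np.ndarray, np.ndarray]]:
    """Subject-grouped k-fold split: shuffle subjects, deal them round-robin."""
    uniq = np.unique(groups)
    if len(uniq) < k:
        raise ValueError(f"only {len(uniq)} subjects for k={k} grouped folds")
    rng = np.random.default_rng(seed)
    order = rng.permutation(uniq)
    folds = [order[i::k] for i in range(k)]
    out = []
    for f in folds:
        te = np.isin(groups, f)
        out.append((np.flatnonzero(~te), np.flatnonzero(te)))
    return out


def train_eval_cnn(
    images: np.ndarray,
    labels: np.ndarray,
    subjects: np.ndarray,
    spec: CnnSpec,
    k: int = 5,
    seed: int = 0,
) -> tuple[float, float]:
    """Subject-grouped k-fold CV of the CNN; pooled held-out (RMSE, MAE)."""
    images = np.asarray(images, dtype=float)
    labels = np.asarray(labels, dtype=float)
    subjects = np.asarray(subjects)
    if images.ndim != 3:
        raise ValueError("images must be (n, height, width)")
    if not (len(images) == len(labels) == len(subjects)):
        raise ValueError("images, labels and subjects are misaligned")
    preds = np.empty(len(labels))
    for fold, (tr, te) in enumerate(_group_folds(subjects, k, seed)):
        net = CnnRegressor(spec, images.shape[1:], seed=seed * 1000 + fold)
        net.fit(images[tr], labels[tr])
        preds[te] = net.predict(images[te])
    return score(labels - preds)


def make_objective(
    images: np.ndarray,
    labels: np.ndarray,
    subjects: np.ndarray,
    k: int = 5,
    seed: int = 0,
):
    """CV-RMSE objective over (filter_size, dropout, epochs) configs for BO."""

    def objective(cfg: tuple) -> float:
        f, d, e = cfg
        spec = CnnSpec(filter_size=int(f), dropout_rate=float(d), epochs=int(e))
        rmse, _ = train_eval_cnn(images, labels, subjects, spec, k=k, seed=seed)
        return rmse

    return objective
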