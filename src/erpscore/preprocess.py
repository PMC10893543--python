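"""Epoch containers and ERP preprocessing.

The multi-trial branch turns raw single-channel EEG epochs into an
artifact-free, baseline-corrected, low-pass-filtered grand-average ERP:

1. baseline correction by the subtraction method (pre-stimulus mean),
2. amplitude-threshold artifact rejection (trials exceeding +/-50 uV),
3. grand averaging across surviving trials,
4. zero-phase band-pass filtering to 0-30 Hz.

The single-trial branch instead keeps individual trials, rejecting those
with implausible response times (outside 0.2-1.5 s) or a peak-to-peak
range above 100 uV, and truncates each kept trial to the interval from
stimulus onset to the response.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import signal


@dataclass
class EpochSet:
    """Trials x samples matrix of single-channel EEG for one subject/stimulus.

    Amplitudes are in microvolts.  ``onset_index`` is the sample index of
    stimulus onset; the time axis runs from ``-t_pre`` to ``+t_post`` ms with
    inclusive endpoints, so ``n_samples == round((t_pre + t_post) * fs / 1000) + 1``.

    ``trial_lengths`` is only set after response-time truncation: entry i is
    the number of valid post-onset samples of trial i (the rest is padding).
    """

    subject: str
    stimulus: str
    data: np.ndarray          # (n_trials, n_samples), uV
    fs: float                 # Hz
    onset_index: int
    t_pre: float              # ms
    t_post: float             # ms
    trial_lengths: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("data must be 2-D (trials x samples)")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("data contains non-finite values")
        if not 0 <= self.onset_index < self.data.shape[1]:
            raise ValueError("onset_index outside sample range")

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def times(self) -> np.ndarray:
        """Time axis in ms relative to stimulus onset (pre-stimulus negative)."""
        return (np.arange(self.n_samples) - self.onset_index) * 1000.0 / self.fs


@dataclass
class ErpWaveform:
    """A grand-average ERP with its time axis and provenance."""

    data: np.ndarray          # (n_samples,), uV
    fs: float
    times: np.ndarray         # ms relative to onset
    n_trials_averaged: int
    filter_band: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        if self.data.shape != self.times.shape:
            raise ValueError("data and time axis lengths differ")
        if self.n_trials_averaged < 1:
            raise ValueError("n_trials_averaged must be >= 1")


@dataclass
class RejectionReport:
    """Bookkeeping for a trial-rejection pass."""

    n_input: int
    n_rejected_amplitude: int = 0
    n_rejected_rt: int = 0
    kept_indices: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=int))

    @property
    def n_kept(self) -> int:
        return len(self.kept_indices)

    @property
    def all_rejected(self) -> bool:
        return self.n_kept == 0

    def to_dict(self) -> dict:
        return {
            "n_input": int(self.n_input),
            "n_rejected_amplitude": int(self.n_rejected_amplitude),
            "n_rejected_rt": int(self.n_rejected_rt),
            "n_kept": int(self.n_kept),
            "kept_indices": [int(i) for i in self.kept_indices],
        }


def baseline_correct(epochs: EpochSet) -> EpochSet:
    """Subtract each trial's pre-stimulus mean from the whole trial.

    Requires a non-empty pre-stimulus window (``t_pre > 0``); afterwards the
    pre-stimulus mean of every trial is zero to float precision.
    """
    if epochs.t_pre <= 0 or epochs.onset_index == 0:
        raise ValueError("baseline correction needs a pre-stimulus window (t_pre > 0)")
    # pre-stimulus region: samples strictly before onset
    base = epochs.data[:, : epochs.onset_index].mean(axis=1, keepdims=True)
    return replace(epochs, data=epochs.data - base)


def reject_amplitude(
    epochs: EpochSet, threshold_uv: float = 50.0
) -> tuple[EpochSet, RejectionReport]:
    """Drop trials with any sample strictly exceeding +/-threshold_uv.

    "Strictly": a sample exactly at the threshold is kept.  An empty result
    is allowed and flagged in the report rather than raised.
    """
    if threshold_uv <= 0:
        raise ValueError("threshold must be positive")
    bad = np.any(np.abs(epochs.data) > threshold_uv, axis=1)
    kept = np.flatnonzero(~bad)
    report = RejectionReport(
        n_input=epochs.n_trials,
        n_rejected_amplitude=int(bad.sum()),
        kept_indices=kept,
    )
    return replace(epochs, data=epochs.data[kept]), report


def grand_average(epochs: EpochSet) -> ErpWaveform:
    """Element-wise arithmetic mean across trials."""
    if epochs.n_trials == 0:
        raise ValueError("cannot average zero trials")
    return ErpWaveform(
        data=epochs.data.mean(axis=0),
        fs=epochs.fs,
        times=epochs.times,
        n_trials_averaged=epochs.n_trials,
    )


def bandpass_erp(erp: ErpWaveform, lo: float = 0.0, hi: float = 30.0) -> ErpWaveform:
    """Zero-phase band-pass (forward-backward Butterworth, order 4).

    ``lo == 0`` degenerates to a pure low-pass at ``hi``.  Applied twice
    (filtfilt), the order-4 response gives ~48 dB attenuation one octave
    above the cutoff.
    """
    nyq = erp.fs / 2.0
    if not 0 <= lo < hi:
        raise ValueError("need 0 <= lo < hi")
    if hi >= nyq:
        raise ValueError(f"high cutoff {hi} Hz >= Nyquist {nyq} Hz")
    if lo == 0:
        sos = signal.butter(4, hi, btype="lowpass", fs=erp.fs, output="sos")
    else:
        sos = signal.butter(4, [lo, hi], btype="bandpass", fs=erp.fs, output="sos")
    filtered = signal.sosfiltfilt(sos, erp.data)
    return ErpWaveform(
        data=filtered,
        fs=erp.fs,
        times=erp.times,
        n_trials_averaged=erp.n_trials_averaged,
        filter_band=(lo, hi),
    )


def filter_single_trials(
    epochs: EpochSet,
    rts: np.ndarray,
    rt_min: float = 0.2,
    rt_max: float = 1.5,
    range_max_uv: float = 100.0,
) -> tuple[EpochSet, RejectionReport]:
    """Keep trials with plausible response time and bounded amplitude range.

    A trial survives iff its response time lies in ``[rt_min, rt_max]``
    seconds (inclusive) and its peak-to-peak range is at most
    ``range_max_uv``.  Kept trials are truncated to the interval from
    stimulus onset to the response: the returned EpochSet contains only
    post-onset samples, padded with zeros beyond each trial's response, with
    per-trial valid lengths in ``trial_lengths``.  Trial order is preserved.
    """
    rts = np.asarray(rts, dtype=float)
    if rts.shape != (epochs.n_trials,):
        raise ValueError(
            f"rts length {rts.shape} does not match n_trials {epochs.n_trials}"
        )
    rt_bad = (rts < rt_min) | (rts > rt_max)
    ptp = epochs.data.max(axis=1) - epochs.data.min(axis=1)
    range_bad = ptp > range_max_uv
    kept = np.flatnonzero(~(rt_bad | range_bad))
    report = RejectionReport(
        n_input=epochs.n_trials,
        n_rejected_amplitude=int(range_bad.sum()),
        n_rejected_rt=int(rt_bad.sum()),
        kept_indices=kept,
    )
    # rejected-for-both trials are counted in both tallies; kept + union(rejected)
    # partitions the input, which the report exposes via kept_indices.
    post = epochs.data[kept, epochs.onset_index :]
    lengths = np.minimum(
        np.round(rts[kept] * epochs.fs).astype(int) + 1, post.shape[1]
    )
    out = np.zeros_like(post)
    for row, ln in enumerate(lengths):
        out[row, :ln] = post[row, :ln]
    truncated = EpochSet(
        subject=epochs.subject,
        stimulus=epochs.stimulus,
        data=out,
        fs=epochs.fs,
        onset_index=0,
        t_pre=0.0,
        t_post=epochs.t_post,
        trial_lengths=lengths,
    )
    return truncated, report
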