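import numpy as np
import pytest

from erpscore.cohort import CohortSpec, generate_cohort
from erpscore.preprocess import EpochSet, ErpWaveform


def make_erp(data: np.ndarray, fs: float = 1000.0, t_pre: float = 100.0) -> ErpWaveform:
    """Wrap a raw sample vector as an ERP with onset at t_pre ms."""
    onset = int(round(t_pre * fs / 1000.0))
    times = (np.arange(len(data)) - onset) * 1000.0 / fs
    return ErpWaveform(data=np.asarray(data, float), fs=fs, times=times,
                       n_trials_averaged=1)


def gaussian_erp(amp: float, lat_ms: float, width_ms: float = 10.0,
                 fs: float = 1000.0, t_pre: float = 100.0,
                 t_post: float = 600.0) -> ErpWaveform:
    """Single-Gaussian ERP template used as a fixture."""
    n = int(round((t_pre + t_post) * fs / 1000.0)) + 1
    onset = int(round(t_pre * fs / 1000.0))
    t = (np.arange(n) - onset) * 1000.0 / fs
    data = amp * np.exp(-0.5 * ((t - lat_ms) / width_ms) ** 2)
    return ErpWaveform(data=data, fs=fs, times=t, n_trials_averaged=1)


def make_epochs(data: np.ndarray, fs: float = 1000.0, t_pre: float = 100.0,
                t_post: float | None = None) -> EpochSet:
    data = np.atleast_2d(np.asarray(data, float))
    onset = int(round(t_pre * fs / 1000.0))
    if t_post is None:
        t_post = (data.shape[1] - 1 - onset) * 1000.0 / fs
    return EpochSet(subject="S", stimulus="vw1", data=data, fs=fs,
                    onset_index=onset, t_pre=t_pre, t_post=t_post)


@pytest.fixture(scope="session")
def small_cohort():
    """Tiny noisy cohort reused by pipeline-level tests."""
    spec = CohortSpec(n_normal=4, n_mci=3, n_stimuli=2, n_trials=20,
                      noise_sd=8.0, seed=11)
    return generate_cohort(spec)


@pytest.fixture(scope="session")
def noiseless_cohort():
    spec = CohortSpec(n_normal=3, n_mci=2, n_stimuli=1, n_trials=4,
                      noise_sd=0.0, pink_noise_fraction=0.0,
                      artifact_rate=0.0, rt_outlier_rate=0.0, seed=7)
    return generate_cohort(spec)
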