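"""ERP preprocessing: baseline, rejection, averaging, filtering."""

import numpy as np
import pytest

from erpscore.preprocess import (
    bandpass_erp,
    baseline_correct,
    filter_single_trials,
    grand_average,
    reject_amplitude,
)
from tests.conftest import make_epochs, make_erp


class TestBaselineCorrect:
    def test_constant_trial_becomes_zero(self):
        es = make_epochs(np.full((1, 701), 7.0))
        out = baseline_correct(es)
        np.testing.assert_allclose(out.data, 0.0)

    def test_prestimulus_mean_is_zero(self):
        rng = np.random.default_rng(0)
        es = make_epochs(rng.standard_normal((10, 701)) * 20)
        out = baseline_correct(es)
        pre_means = out.data[:, :es.onset_index].mean(axis=1)
        assert np.all(np.abs(pre_means) <= 1e-9)

    def test_high_rate_prestimulus_window(self):
        # 100 ms pre-stimulus at 20 kHz = 2000 baseline samples
        rng = np.random.default_rng(1)
        es = make_epochs(rng.standard_normal((3, 14001)), fs=20000.0)
        assert es.onset_index == 2000
        out = baseline_correct(es)
        direct = es.data - es.data[:, :2000].mean(axis=1, keepdims=True)
        np.testing.assert_allclose(out.data, direct)

    def test_no_baseline_region_errors(self):
        es = make_epochs(np.zeros((2, 100)), t_pre=0.0)
        with pytest.raises(ValueError):
            baseline_correct(es)

    def test_constant_offset_removed(self):
        """Features downstream are invariant to a DC offset pre-correction."""
        rng = np.random.default_rng(2)
        base = rng.standard_normal((5, 701))
        a = baseline_correct(make_epochs(base))
        b = baseline_correct(make_epochs(base + 42.0))
        np.testing.assert_allclose(a.data, b.data, atol=1e-12)


class TestRejectAmplitude:
    def test_boundary_of_rule(self):
        tr_ok = np.zeros(701); tr_ok[300] = 49.9
        tr_bad = np.zeros(701); tr_bad[300] = -50.1
        tr_edge = np.zeros(701); tr_edge[300] = 50.0  # exactly at threshold: kept
        es = make_epochs(np.vstack([tr_ok, tr_bad, tr_edge]))
        kept, rep = reject_amplitude(es)
        assert rep.n_rejected_amplitude == 1
        assert list(rep.kept_indices) == [0, 2]

    def test_constructed_exceedances(self):
        rng = np.random.default_rng(3)
        data = rng.uniform(-40, 40, size=(200, 701))
        bad = rng.choice(200, size=12, replace=False)
        data[bad, 100] = 80.0 * np.sign(rng.standard_normal(12) + 0.1)
        es = make_epochs(data)
        kept, rep = reject_amplitude(es)
        assert kept.n_trials == 188
        assert rep.n_rejected_amplitude == 12
        # independent oracle: direct scan
        oracle = sum(1 for row in data if np.any(np.abs(row) > 50))
        assert rep.n_rejected_amplitude == oracle

    def test_idempotent(self):
        rng = np.random.default_rng(4)
        es = make_epochs(rng.uniform(-80, 80, size=(50, 101)))
        once, _ = reject_amplitude(es)
        twice, rep2 = reject_amplitude(once)
        np.testing.assert_array_equal(once.data, twice.data)
        assert rep2.n_rejected_amplitude == 0

    def test_empty_output_flagged_not_raised(self):
        es = make_epochs(np.full((3, 101), 60.0))
        kept, rep = reject_amplitude(es)
        assert kept.n_trials == 0
        assert rep.all_rejected


class TestGrandAverage:
    def test_identical_trials(self):
        row = np.sin(np.linspace(0, 10, 701))
        es = make_epochs(np.tile(row, (5, 1)))
        erp = grand_average(es)
        np.testing.assert_allclose(erp.data, row)
        assert erp.n_trials_averaged == 5

    def test_matches_naive_loop(self):
        rng = np.random.default_rng(5)
        data = rng.standard_normal((3, 50))
        es = make_epochs(data, t_pre=10.0)
        erp = grand_average(es)
        loop = np.array([data[:, j].sum() / 3 for j in range(50)])
        np.testing.assert_allclose(erp.data, loop)

    def test_snr_gain_sqrt_n(self):
        """Averaging 200 noisy trials shrinks residual SD by ~sqrt(200)."""
        rng = np.random.default_rng(6)
        noise_sd = 10.0
        template = np.zeros(701)
        data = template + rng.normal(0, noise_sd, size=(200, 701))
        erp = grand_average(make_epochs(data))
        resid_sd = erp.data.std()
        assert resid_sd == pytest.approx(noise_sd / np.sqrt(200), rel=0.15)

    def test_zero_trials_errors(self):
        es = make_epochs(np.zeros((1, 101)))
        es.data = es.data[:0]
        with pytest.raises(ValueError):
            grand_average(es)

    def test_commutes_with_baseline(self):
        rng = np.random.default_rng(7)
        es = make_epochs(rng.standard_normal((20, 701)) * 5)
        a = grand_average(baseline_correct(es)).data
        b = baseline_correct(
            make_epochs(grand_average(es).data[None, :])
        ).data[0]
        np.testing.assert_allclose(a, b, atol=1e-10)


class TestBandpass:
    def _sine_erp(self, freq, fs=1000.0, dur_s=2.0):
        t = np.arange(int(fs * dur_s)) / fs
        return make_erp(np.sin(2 * np.pi * freq * t), fs=fs, t_pre=0.1)

    def _amp_at(self, erp, freq):
        spec = np.abs(np.fft.rfft(erp.data))
        f = np.fft.rfftfreq(len(erp.data), 1 / erp.fs)
        return spec[np.argmin(np.abs(f - freq))]

    def test_passband_preserved(self):
        erp = self._sine_erp(10.0)
        out = bandpass_erp(erp)
        assert self._amp_at(out, 10) == pytest.approx(self._amp_at(erp, 10), rel=0.05)

    def test_stopband_attenuation_40db(self):
        erp = self._sine_erp(60.0)
        out = bandpass_erp(erp)
        ratio = self._amp_at(out, 60) / self._amp_at(erp, 60)
        assert 20 * np.log10(ratio) <= -40.0

    def test_above_nyquist_errors(self):
        erp = self._sine_erp(10.0, fs=100.0)
        with pytest.raises(ValueError):
            bandpass_erp(erp, 0.0, 60.0)

    def test_band_recorded(self):
        out = bandpass_erp(self._sine_erp(5.0))
        assert out.filter_band == (0.0, 30.0)


class TestFilterSingleTrials:
    def test_stated_bounds(self):
        data = np.zeros((2, 701))
        data[1, 200] = 99.0  # range 99 uV: kept
        es = make_epochs(data)
        kept, rep = filter_single_trials(es, np.array([0.19, 1.49]))
        assert rep.n_rejected_rt == 1
        assert list(rep.kept_indices) == [1]

    def test_union_count(self):
        rng = np.random.default_rng(8)
        n = 50
        data = rng.uniform(-30, 30, size=(n, 701))
        rts = rng.uniform(0.3, 1.2, size=n)
        rt_out = [0, 5, 9, 14, 20, 33, 41]
        for i in rt_out:
            rts[i] = 1.9
        range_out = [3, 14, 22, 30]  # 14 overlaps an RT outlier
        for i in range_out:
            data[i, 400] = 200.0
        es = make_epochs(data)
        kept, rep = filter_single_trials(es, rts)
        assert kept.n_trials == n - 10
        # oracle: explicit set union
        assert kept.n_trials == n - len(set(rt_out) | set(range_out))

    def test_truncation_to_response(self):
        fs = 1000.0
        data = np.ones((1, 701))
        es = make_epochs(data, fs=fs)
        kept, _ = filter_single_trials(es, np.array([0.3]))
        assert kept.trial_lengths[0] == int(round(0.3 * fs)) + 1
        # pre-stimulus samples are gone; padding beyond the response is zero
        assert kept.data.shape[1] == 701 - es.onset_index
        assert np.all(kept.data[0, :301] == 1.0)
        assert np.all(kept.data[0, 301:] == 0.0)

    def test_mismatched_rts_error(self):
        es = make_epochs(np.zeros((3, 701)))
        with pytest.raises(ValueError):
            filter_single_trials(es, np.array([0.5, 0.5]))

    def test_order_preserved(self):
        rng = np.random.default_rng(9)
        data = np.arange(10)[:, None] * np.ones((10, 701))
        es = make_epochs(data)
        rts = np.full(10, 0.5)
        rts[[2, 7]] = 0.05
        kept, rep = filter_single_trials(es, rts)
        ids = kept.data[:, 0]
        assert list(ids) == sorted(ids)
        assert list(rep.kept_indices) == [0, 1, 3, 4, 5, 6, 8, 9]
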