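"""Feature bank: prominent points, band powers, windows, dynamics, screening."""

import numpy as np
import pandas as pd
import pytest

from erpscore.features import (
    DEFAULT_WINDOWS,
    build_feature_table,
    detect_prominent_points,
    per_stimulus_prominent_block,
    relative_band_powers,
    screen_td_features,
    sliding_windows,
    slope_cv_dynamics,
)
from tests.conftest import gaussian_erp, make_erp


class TestProminentPoints:
    def test_negative_gaussian_found_as_n1(self):
        erp = gaussian_erp(-4.0, 100.0)
        pts = detect_prominent_points(erp)
        assert pts["N1"].peak_amplitude == pytest.approx(-4.0, abs=1e-6)
        assert pts["N1"].peak_latency == pytest.approx(100.0, abs=1.0)

    def test_all_zero_erp_tie_rule(self):
        erp = make_erp(np.zeros(701))
        pts = detect_prominent_points(erp)
        for label, p in pts.items():
            assert p.peak_amplitude == 0.0
            assert p.peak_latency == DEFAULT_WINDOWS[label][0]

    def test_default_windows(self):
        assert DEFAULT_WINDOWS == {
            "Pa": (25.0, 35.0),
            "P1": (60.0, 80.0),
            "N1": (90.0, 110.0),
            "P2": (150.0, 250.0),
        }

    def test_interval_mean_is_window_mean(self):
        erp = gaussian_erp(3.0, 180.0, 22.0)
        pts = detect_prominent_points(erp)
        mask = (erp.times >= 150) & (erp.times <= 250)
        assert pts["P2"].interval_mean == pytest.approx(erp.data[mask].mean())

    def test_short_erp_errors(self):
        erp = make_erp(np.zeros(200), t_pre=100.0)  # ends at 99 ms
        with pytest.raises(ValueError):
            detect_prominent_points(erp)


class TestBandPowers:
    def test_sum_to_one(self):
        erp = gaussian_erp(-4.0, 100.0)
        powers = relative_band_powers(erp)
        assert sum(powers.values()) == pytest.approx(1.0, abs=1e-9)

    def test_pure_theta_tone(self):
        t = np.arange(2000) / 1000.0
        erp = make_erp(np.sin(2 * np.pi * 6.0 * t))
        powers = relative_band_powers(erp)
        assert powers["theta"] >= 0.95

    def test_white_noise_proportional_to_bandwidth(self):
        rng = np.random.default_rng(0)
        acc = {"delta": 0.0, "theta": 0.0, "alpha": 0.0, "beta": 0.0}
        n_rep = 40
        for _ in range(n_rep):
            erp = make_erp(rng.standard_normal(4000))
            for k, v in relative_band_powers(erp).items():
                acc[k] += v / n_rep
        widths = {"delta": 3.5, "theta": 4.0, "alpha": 5.0, "beta": 17.0}
        total_w = sum(widths.values())
        for k in acc:
            assert acc[k] == pytest.approx(widths[k] / total_w, abs=0.03)

    def test_zero_power_errors(self):
        erp = make_erp(np.zeros(701))
        with pytest.raises(ValueError):
            relative_band_powers(erp)


class TestProminentBlock:
    def test_sixteen_features_per_stimulus(self):
        erp = gaussian_erp(-4.0, 100.0)
        feats = per_stimulus_prominent_block(erp, "vw1")
        assert len(feats) == 16

    def test_eighty_features_over_five_stimuli(self):
        erp = gaussian_erp(-4.0, 100.0)
        erps = {("S01", f"vw{i+1}"): erp for i in range(5)}
        table = build_feature_table(erps, include_td=False)
        assert table.shape == (1, 80)

    def test_names_parse_back(self):
        erp = gaussian_erp(2.0, 70.0)
        for name in per_stimulus_prominent_block(erp, "vw3"):
            parts = name.split("|")
            assert parts[0] == "vw3"
            assert parts[1] in ("prominent", "band_power")


class TestSlidingWindows:
    def test_paper_setting_yields_55_windows(self):
        # 700 ms epoch at 1 kHz: floor((700-25)/12.5)+1 = 55
        wins = sliding_windows(701, 1000.0, win_ms=25.0, overlap=0.5)
        assert len(wins) == 55

    def test_disjoint_windows(self):
        wins = sliding_windows(100, 1000.0, win_ms=25.0, overlap=0.0)
        assert len(wins) == 4
        assert wins == [(0, 25), (25, 50), (50, 75), (75, 100)]

    def test_nonpositive_step_errors(self):
        with pytest.raises(ValueError):
            sliding_windows(100, 1000.0, win_ms=25.0, overlap=1.0)

    def test_window_longer_than_signal_errors(self):
        with pytest.raises(ValueError):
            sliding_windows(20, 1000.0, win_ms=25.0)


class TestSlopeCv:
    def test_equal_pair(self):
        slopes, cvs = slope_cv_dynamics(np.array([3.0, 3.0]), step_ms=12.5)
        assert slopes[0] == 0.0
        assert cvs[0] == 0.0

    def test_arithmetic_oracle(self):
        slopes, cvs = slope_cv_dynamics(np.array([1.0, 3.0]), step_ms=12.5)
        assert slopes[0] == pytest.approx((3 - 1) / 12.5)
        assert cvs[0] == pytest.approx(np.std([1.0, 3.0], ddof=1) / 2.0)

    def test_counts(self):
        slopes, cvs = slope_cv_dynamics(np.arange(7, dtype=float), 12.5)
        assert len(slopes) == 6 and len(cvs) == 6

    def test_zero_mean_unequal_pair_flagged_missing(self):
        _, cvs = slope_cv_dynamics(np.array([-1.0, 1.0]), 12.5)
        assert np.isnan(cvs[0])

    def test_single_window_errors(self):
        with pytest.raises(ValueError):
            slope_cv_dynamics(np.array([1.0]), 12.5)


class TestScreening:
    def _table(self, values: dict) -> tuple[pd.DataFrame, pd.Series]:
        table = pd.DataFrame(values, index=[f"S{i}" for i in range(6)])
        groups = pd.Series(["normal"] * 3 + ["mci"] * 3, index=table.index)
        return table, groups

    def test_constant_feature_never_retained(self):
        table, groups = self._table({
            "vw1|td|mean|w00|slope": [1.0] * 6,
            "vw1|td|std|w00|slope": [3.1, 2.9, 3.0, -3.0, -2.9, -3.1],
        })
        res = screen_td_features(table, groups, cutoff=0.5)
        assert "vw1|td|mean|w00|slope" not in res.retained
        assert "vw1|td|std|w00|slope" in res.retained

    def test_strong_separation_retained(self):
        rng = np.random.default_rng(0)
        table, groups = self._table({
            "vw1|td|mean|w01|cv": np.concatenate([
                3 + 0.1 * rng.standard_normal(3),
                -3 + 0.1 * rng.standard_normal(3),
            ]),
        })
        res = screen_td_features(table, groups, cutoff=5.0)
        assert res.retained == ["vw1|td|mean|w01|cv"]

    def test_ranking_matches_brute_force(self):
        rng = np.random.default_rng(1)
        cols = {f"vw1|td|c{j}|w00|slope": rng.standard_normal(6) for j in range(8)}
        table, groups = self._table(cols)
        res = screen_td_features(table, groups, n_keep=8)
        # brute-force oracle
        def sep(col):
            a, b = col[:3], col[3:]
            pooled = np.sqrt((2 * a.var(ddof=1) + 2 * b.var(ddof=1)) / 4)
            return abs(a.mean() - b.mean()) / pooled
        oracle = sorted(cols, key=lambda c: -sep(np.asarray(cols[c])))
        assert res.retained == oracle

    def test_prominent_features_always_kept(self):
        table, groups = self._table({
            "vw1|prominent|N1|amplitude": [0.0] * 6,
            "vw1|td|mean|w00|slope": [1.0, 2, 3, 4, 5, 6],
        })
        res = screen_td_features(table, groups, cutoff=100.0)
        assert "vw1|prominent|N1|amplitude" in res.retained

    def test_degenerate_groups_error(self):
        table = pd.DataFrame({"vw1|td|a|w00|slope": [1.0, 2.0]}, index=["S0", "S1"])
        groups = pd.Series(["normal", "mci"], index=table.index)
        with pytest.raises(ValueError):
            screen_td_features(table, groups)


def test_feature_extraction_deterministic():
    erp = gaussian_erp(-4.0, 100.0)
    erps = {("S01", "vw1"): erp}
    a = build_feature_table(erps, include_td=True)
    b = build_feature_table(erps, include_td=True)
    pd.testing.assert_frame_equal(a, b)


def test_td_candidate_count_formula():
    """2 x 107 x (windows-1) x stimuli candidates before screening."""
    erp = gaussian_erp(-4.0, 100.0)
    erps = {("S01", "vw1"): erp, ("S01", "vw2"): erp}
    table = build_feature_table(erps, include_td=True)
    n_windows = len(sliding_windows(701, 1000.0, 25.0, 0.5))
    expected_td = 2 * 107 * (n_windows - 1) * 2
    n_td = sum(1 for c in table.columns if "|td|" in c)
    assert n_td == expected_td
    assert table.shape[1] == expected_td + 32
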