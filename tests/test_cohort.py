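"""Synthetic cohort generator: determinism, planted effects, artifacts."""

import numpy as np
import pandas as pd
import pytest

from erpscore.cohort import (
    CohortSpec,
    CohortSpecError,
    ComponentParams,
    default_components,
    erp_template,
    generate_cohort,
    load_cohort,
    save_cohort,
)
from erpscore.features import detect_prominent_points
from tests.conftest import make_erp


def test_same_seed_is_bit_identical():
    spec = CohortSpec(n_normal=3, n_mci=2, n_stimuli=2, n_trials=10, seed=42)
    a = generate_cohort(spec)
    b = generate_cohort(CohortSpec(n_normal=3, n_mci=2, n_stimuli=2, n_trials=10, seed=42))
    assert a.subjects.equals(b.subjects)
    for key in a.epochs:
        np.testing.assert_array_equal(a.epochs[key].data, b.epochs[key].data)
        np.testing.assert_array_equal(a.rts[key], b.rts[key])


def test_different_seed_differs():
    mk = lambda s: generate_cohort(CohortSpec(n_normal=2, n_mci=1, n_trials=5, seed=s))
    a, b = mk(1), mk(2)
    key = next(iter(a.epochs))
    assert not np.array_equal(a.epochs[key].data, b.epochs[key].data)


def test_zero_noise_trials_equal_ground_truth():
    spec = CohortSpec(n_normal=2, n_mci=1, n_stimuli=1, n_trials=3,
                      noise_sd=0.0, pink_noise_fraction=0.0, artifact_rate=0.0,
                      seed=3)
    c = generate_cohort(spec)
    for key, es in c.epochs.items():
        np.testing.assert_allclose(es.data, np.tile(c.ground_truth[key], (3, 1)))


def test_moca_group_means_match_population():
    """Sample mean of the normal group stays within 3 SE of 27.6 over seeds."""
    means = []
    for seed in range(30):
        c = generate_cohort(CohortSpec(n_normal=15, n_mci=1, n_stimuli=1,
                                       n_trials=1, noise_sd=0.0, seed=seed))
        means.append(c.subjects.query("group == 'normal'")["moca"].mean())
    pooled_mean = np.mean(means)
    se = 1.18 / np.sqrt(30 * 15)
    # integer rounding and clipping to 30 bias the mean by well under 0.1
    assert abs(pooled_mean - 27.6) < 3 * se + 0.1


def test_moca_bounded():
    spec = CohortSpec(n_normal=20, n_mci=20, moca_mci_mean=2.0, moca_mci_sd=8.0,
                      n_stimuli=1, n_trials=1, noise_sd=0.0, seed=0)
    c = generate_cohort(spec)
    assert c.subjects["moca"].between(0, 30).all()


def test_planted_n1_amplitude_slope_recovered_by_regression():
    """Least squares of measured N1 peak on MoCA recovers the planted slope."""
    comps = default_components()
    comps["N1"] = ComponentParams(-4.0, 100.0, 10.0, amp_slope=-0.3)
    mocas, n1_amps = [], []
    for moca in range(18, 31):  # a spread of noiseless subjects
        spec = CohortSpec(component_params=comps, noise_sd=0.0)
        template = erp_template(spec, moca)
        erp = make_erp(template)
        pts = detect_prominent_points(erp)
        mocas.append(moca)
        n1_amps.append(pts["N1"].peak_amplitude)
    slope = np.polyfit(mocas, n1_amps, 1)[0]
    assert slope == pytest.approx(-0.3, abs=0.01)


def test_group_n1_separation_matches_slope():
    """Noiseless group N1 difference = slope x group MoCA difference."""
    spec = CohortSpec(n_normal=5, n_mci=5, n_stimuli=1, n_trials=1,
                      noise_sd=0.0, pink_noise_fraction=0.0, artifact_rate=0.0,
                      seed=9)
    c = generate_cohort(spec)
    slope = spec.component_params["N1"].amp_slope
    amp = {}
    for _, row in c.subjects.iterrows():
        es = c.epochs[(row["id"], "vw1")]
        erp = make_erp(es.data[0], fs=spec.fs, t_pre=spec.epoch_pre)
        amp[row["id"]] = detect_prominent_points(erp)["N1"].peak_amplitude
    c.subjects["n1"] = c.subjects["id"].map(amp)
    by_group = c.subjects.groupby("group")[["moca", "n1"]].mean()
    d_moca = by_group.loc["normal", "moca"] - by_group.loc["mci", "moca"]
    d_n1 = by_group.loc["normal", "n1"] - by_group.loc["mci", "n1"]
    # latency also shifts with MoCA; the peak is still on the Gaussian crest
    assert d_n1 == pytest.approx(slope * d_moca, abs=0.05)


def test_artifact_fraction_matches_rate():
    """Trials exceeding +/-50 uV converge to artifact_rate (binomial CI)."""
    rate = 0.1
    spec = CohortSpec(n_normal=2, n_mci=1, n_stimuli=2, n_trials=200,
                      noise_sd=1.0, pink_noise_fraction=0.0,
                      artifact_rate=rate, artifact_amplitude=120.0, seed=21)
    c = generate_cohort(spec)
    n_tot = n_exc = 0
    for es in c.epochs.values():
        exceed = np.any(np.abs(es.data) > 50.0, axis=1)
        n_exc += exceed.sum()
        n_tot += es.n_trials
    phat = n_exc / n_tot
    ci = 3 * np.sqrt(rate * (1 - rate) / n_tot)
    assert abs(phat - rate) < ci


def test_rt_outliers_out_of_range():
    spec = CohortSpec(n_normal=2, n_mci=1, n_stimuli=1, n_trials=500,
                      rt_outlier_rate=0.2, seed=5)
    c = generate_cohort(spec)
    rts = np.concatenate(list(c.rts.values()))
    frac_out = np.mean((rts < 0.2) | (rts > 1.5))
    assert 0.1 < frac_out < 0.35  # ~rate plus lognormal tail


@pytest.mark.parametrize("field,value", [
    ("n_normal", 0),
    ("n_trials", -1),
    ("artifact_rate", 1.5),
    ("pink_noise_fraction", -0.1),
    ("noise_sd", -1.0),
])
def test_invalid_spec_names_field(field, value):
    spec = CohortSpec(**{field: value})
    with pytest.raises(CohortSpecError, match=field):
        generate_cohort(spec)


def test_epoch_dimensions_follow_fs():
    spec = CohortSpec(n_normal=1, n_mci=1, n_stimuli=1, n_trials=2,
                      fs=2000.0, seed=0)
    c = generate_cohort(spec)
    es = next(iter(c.epochs.values()))
    assert es.n_samples == int(round(700 * 2000 / 1000)) + 1
    assert es.onset_index == 200
    assert es.times[0] == pytest.approx(-100.0)
    assert es.times[-1] == pytest.approx(600.0)


def test_container_round_trip(tmp_path, noiseless_cohort):
    save_cohort(noiseless_cohort, tmp_path / "cohort")
    back = load_cohort(tmp_path / "cohort")
    assert back.subjects[["id", "group", "moca"]].equals(
        noiseless_cohort.subjects[["id", "group", "moca"]]
    )
    for key in noiseless_cohort.epochs:
        np.testing.assert_array_equal(
            back.epochs[key].data, noiseless_cohort.epochs[key].data
        )
        np.testing.assert_allclose(back.rts[key], noiseless_cohort.rts[key])
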