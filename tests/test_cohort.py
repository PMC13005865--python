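from dataclasses import replace

import numpy as np
import pytest

import hepaflux as hf
from hepaflux.cohort import _apply_noise, _liver_exchange
from hepaflux.errors import DataValidationError


def test_same_seed_reproduces_identical_dataset():
    a, _ = hf.generate_subject(hf.t1d_sub1_profile(), seed=5)
    b, _ = hf.generate_subject(hf.t1d_sub1_profile(), seed=5)
    assert a == b


def test_different_seeds_differ_with_noise():
    a, _ = hf.generate_subject(hf.healthy_profile(), seed=1, noise=True)
    b, _ = hf.generate_subject(hf.healthy_profile(), seed=2, noise=True)
    assert a.plasma_total_glucose.values != b.plasma_total_glucose.values


def test_noise_off_samples_ground_truth_exactly(healthy_noisefree):
    ds, truth = healthy_noisefree
    assert ds.plasma_total_glucose == truth.channels["glucose_total"]
    assert ds.plasma_ratio == truth.channels["ratio"]


def test_null_tracer_dose():
    """Zero dose: no enrichment above background, no hepatic signal, total
    glucose is purely endogenous."""
    prof = replace(hf.healthy_profile(), dose_grams=0.0)
    ds, truth = hf.generate_subject(prof, seed=0, noise=False)
    np.testing.assert_allclose(ds.plasma_ratio.v, prof.baseline_ratio)
    for voxel in ds.hepatic_dglc_amplitudes:
        np.testing.assert_array_equal(voxel.v, 0.0)
    np.testing.assert_allclose(ds.plasma_total_glucose.v,
                               truth.channels["endogenous_truth"].v, rtol=1e-12)


def test_generated_channels_reproduced_by_forward_model(healthy_noisefree, config):
    """Generator and estimator share one forward core: re-simulating with the
    ground-truth parameters reproduces the noise-free channels exactly."""
    ds, truth = healthy_noisefree
    fx = hf.simulate_omm(truth.params.omm, truth.insulin_input, ds.body_weight,
                         times=ds.plasma_total_glucose.t,
                         rtol=config.solver_rtol, atol=config.solver_atol)
    np.testing.assert_allclose(
        fx.G_exo.v, truth.channels["exogenous_truth"].v, rtol=1e-9, atol=1e-12)
    np.testing.assert_allclose(
        fx.G_endo.v, truth.channels["endogenous_truth"].v, rtol=1e-9)


def test_t1d_insulin_channel_from_sc_model(sub1_noisefree):
    ds, truth = sub1_noisefree
    prof = truth.params
    dense = np.arange(-60.0, 180.25, 0.5)
    fast = hf.simulate_sc_fast(prof.sc, prof.bolus_events, prof.body_weight, dense)
    np.testing.assert_allclose(
        ds.plasma_insulin_fast.v,
        np.interp(ds.plasma_insulin_fast.t, dense, fast.v), rtol=1e-9)


def test_liver_exchange_scale_preserving_limit():
    """Equal uptake and washout with constant plasma tracer converges to the
    plasma level."""
    plasma = hf.TimeSeries((-60.0, 600.0), (4.0, 4.0), "mmol/l")
    t = np.arange(-60.0, 601.0, 1.0)
    liver = _liver_exchange(0.03, 0.03, plasma, t)
    assert liver[-1] == pytest.approx(4.0, rel=1e-3)


def test_noise_is_unbiased_over_replicates():
    """Multiplicative noise with CV c leaves the channel mean unbiased:
    relative deviation over 200 replicates < 3c/sqrt(200)."""
    rng = np.random.default_rng(0)
    truth = np.array([5.2, 5.2, 6.0, 7.0, 7.5, 7.4, 6.6, 6.1, 6.2, 6.4])
    c = 0.02
    draws = np.array([_apply_noise(truth, c, rng) for _ in range(200)])
    rel_dev = np.abs(draws.mean(axis=0) - truth) / truth
    assert np.all(rel_dev < 3 * c / np.sqrt(200))


def test_default_study_emulation_counts():
    cohort = hf.generate_cohort(hf.study_mixture(), seed=0)
    assert len(cohort) == 20
    assert sum(ds.group == "t1d" for ds, _ in cohort) == 10
    assert sum(ds.subgroup_hint == "1" for ds, _ in cohort) == 6
    assert sum(ds.subgroup_hint == "2" for ds, _ in cohort) == 4


def test_zero_between_subject_cv_gives_identical_subjects():
    prof = replace(hf.healthy_profile(),
                   between_subject_cv={k: 0.0 for k in
                                       hf.healthy_profile().between_subject_cv})
    cohort = hf.generate_cohort([(prof, 3)], seed=0, noise=False)
    first = cohort[0][0]
    for ds, _ in cohort[1:]:
        assert ds.plasma_total_glucose.values == first.plasma_total_glucose.values


def test_healthy_cohort_basal_glucose_calibration():
    """Cohort mean fasting glucose stays within 3 SEM of the 5.2 mmol/l the
    healthy profile is calibrated to."""
    cohort = hf.generate_cohort([(hf.healthy_profile(), 10)], seed=1)
    basal = np.array([ds.plasma_total_glucose.v[0] for ds, _ in cohort])
    sem = basal.std(ddof=1) / np.sqrt(len(basal))
    assert abs(basal.mean() - 5.2) < 3 * sem


def test_empty_mixture_rejected():
    with pytest.raises(DataValidationError):
        hf.generate_cohort([], seed=0)
    with pytest.raises(DataValidationError):
        hf.generate_cohort([(hf.healthy_profile(), 0)], seed=0)


def test_negative_rate_profile_rejected():
    prof = hf.healthy_profile()
    with pytest.raises(DataValidationError):
        replace(prof.omm.gi, k_abs=-0.1)
    from hepaflux.errors import ConfigError
    with pytest.raises(ConfigError):
        replace(prof, hepatic_k_in=-1.0)


def test_jitter_preserves_emptying_shape_ratio():
    prof = hf.t1d_sub2_profile()
    rng = np.random.default_rng(9)
    jittered = hf.jitter_profile(prof, rng)
    assert jittered.omm.gi.k_min / jittered.omm.gi.k_max == pytest.approx(
        prof.omm.gi.k_min / prof.omm.gi.k_max)
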