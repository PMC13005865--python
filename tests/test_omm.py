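from dataclasses import replace

import numpy as np
import pytest

import hepaflux as hf
from hepaflux.errors import DataValidationError, IdentifiabilityError
from hepaflux.omm import egp_suppression, rd_fractional_increase, report_ge_disposal

BW = 80.0


def flat_insulin(value, t0=-60.0, t1=600.0):
    return hf.TimeSeries((t0, t1), (value, value), "pmol/l", "insulin")


def omm_params(**kw):
    base = dict(V=0.145, GEZI_D=0.015, SI_D=5e-5, p2=0.02, SI_P=2e-3,
                p2P=0.04, GE_P=0.005, G_b=5.2, I_b=40.0,
                gi=hf.GIParams(k_max=0.02, k_min=0.004, k_abs=0.06,
                               f_bio=0.9, D=333.04))
    base.update(kw)
    return hf.OMMParams(**base)


def dimensionless(times, values):
    return hf.TimeSeries(tuple(times), tuple(values), "dimensionless")


class TestSimulate:
    def test_basal_steady_state_without_meal_or_insulin_excursion(self):
        p = omm_params(gi=replace(omm_params().gi, D=0.0))
        fx = hf.simulate_omm(p, flat_insulin(40.0), BW)
        np.testing.assert_allclose(fx.total_glucose.v, 5.2, rtol=1e-7)
        np.testing.assert_allclose(fx.EGP_over_basal.v, 1.0, rtol=1e-7)
        np.testing.assert_allclose(fx.Rd_over_basal.v, 1.0, rtol=1e-7)

    def test_tracer_only_enters_through_meal(self):
        p = omm_params(gi=replace(omm_params().gi, D=0.0))
        step = hf.TimeSeries((-60.0, -0.001, 0.0, 600.0),
                             (40.0, 40.0, 300.0, 300.0), "pmol/l")
        fx = hf.simulate_omm(p, step, BW)
        np.testing.assert_array_equal(fx.G_exo.v, 0.0)

    def test_closed_form_decay_with_zero_glucose_effectiveness(self):
        """With GEZI = 0 (hence no basal production) and a constant insulin
        step, the endogenous pool decays as the closed form
        G_b * exp(-SI_D*dI*(t - (1-exp(-p2 t))/p2))."""
        dI = 200.0
        p = omm_params(GEZI_D=0.0, SI_P=0.0, GE_P=0.0,
                       gi=replace(omm_params().gi, D=0.0))
        fx = hf.simulate_omm(p, flat_insulin(p.I_b + dI), BW,
                             t_start=0.0, t_end=180.0)
        t = fx.G_endo.t
        expected = p.G_b * np.exp(-p.SI_D * dI * (t - (1 - np.exp(-p.p2 * t)) / p.p2))
        np.testing.assert_allclose(fx.G_endo.v, expected, atol=1e-6)

    def test_production_floor_never_negative(self):
        p = omm_params(SI_P=0.05)  # wildly strong suppression
        step = hf.TimeSeries((-60.0, -0.001, 0.0, 600.0),
                             (40.0, 40.0, 500.0, 500.0), "pmol/l")
        fx = hf.simulate_omm(p, step, BW)
        assert np.min(fx.EGP.v) == 0.0
        assert fx.scalars["egp_floor_hit"]

    def test_insulin_must_cover_window(self):
        with pytest.raises(DataValidationError, match="cover"):
            hf.simulate_omm(omm_params(), flat_insulin(40.0, t0=0.0), BW)

    def test_meal_mass_balance_at_long_horizon(self):
        p = omm_params()
        fx = hf.simulate_omm(p, flat_insulin(40.0), BW, t_end=600.0)
        appeared = np.trapezoid(fx.absorption.Ra.v, fx.absorption.Ra.t) * BW
        assert appeared == pytest.approx(p.gi.f_bio * p.gi.D, rel=0.01)


class TestSuppressionMetrics:
    def test_no_suppression_when_production_basal(self):
        s = dimensionless([0, 60, 120, 180], [1, 1, 1, 1])
        assert egp_suppression(s, (0, 180)) == 0.0

    def test_full_suppression_when_production_zero(self):
        s = dimensionless([0, 60, 120, 180], [0, 0, 0, 0])
        assert egp_suppression(s, (0, 180)) == 1.0

    def test_disposal_increase_trivial_cases(self):
        assert rd_fractional_increase(dimensionless([0, 180], [1, 1]), (0, 180)) == 0.0
        assert rd_fractional_increase(dimensionless([0, 180], [2, 2]), (0, 180)) == 1.0

    def test_disposal_increase_linear_ramp(self):
        # ramp 1 -> 3: time average 2, fractional increase 1
        assert rd_fractional_increase(dimensionless([0, 180], [1, 3]),
                                      (0, 180)) == pytest.approx(1.0)

    def test_empty_window_rejected(self):
        with pytest.raises(DataValidationError):
            egp_suppression(dimensionless([0, 180], [1, 1]), (60, 60))

    def test_sub1_first_hour_suppression_at_generator_defaults(self, sub1_noisefree):
        _, truth = sub1_noisefree
        assert truth.fluxes.scalars["egp_suppression_0_60"] == pytest.approx(
            0.26, abs=0.002)


class TestGEDisposal:
    def test_reduces_to_gezi_without_insulin_sensitivity(self):
        assert report_ge_disposal(omm_params(SI_D=0.0)) == 0.015

    def test_basal_insulin_contribution(self):
        p = omm_params(GEZI_D=0.01, SI_D=5e-5, I_b=60.0)
        assert report_ge_disposal(p) == pytest.approx(0.013)

    def test_t1d_scaling_flows_through_config(self):
        cfg = hf.AnalysisConfig()
        scaled = cfg.gezi_disposal_healthy * cfg.gezi_t1d_scale
        p = omm_params(GEZI_D=scaled, SI_D=0.0)
        assert report_ge_disposal(p) == pytest.approx(0.0075)


class TestFit:
    def _measured(self, truth, insulin):
        blood = np.asarray((-60, 0, 10, 20, 30, 60, 90, 120, 150, 180), float)
        fx = hf.simulate_omm(truth, insulin, BW, times=blood)
        return fx.G_exo, fx.G_endo

    def test_too_few_samples_rejected(self):
        p = omm_params()
        short = np.asarray((0.0, 30.0, 60.0, 120.0), float)
        ins = flat_insulin(40.0)
        fx = hf.simulate_omm(p, ins, BW, times=short)
        with pytest.raises(IdentifiabilityError):
            hf.fit_omm(fx.G_exo, fx.G_endo, ins, p, BW)

    def test_missing_insulin_rejected(self):
        p = omm_params()
        exo, endo = self._measured(p, flat_insulin(40.0))
        with pytest.raises(DataValidationError):
            hf.fit_omm(exo, endo, None, p, BW)

    @pytest.mark.parametrize("draw", range(3))
    def test_self_consistency_recovery_from_perturbed_start(self, draw):
        """Fitting noise-free simulated channels recovers the generating
        parameters to well under 0.5% relative."""
        rng = np.random.default_rng(10 + draw)
        truth = omm_params(
            SI_D=5e-5 * np.exp(rng.normal(0, 0.2)),
            SI_P=2e-3 * np.exp(rng.normal(0, 0.2)),
            GE_P=0.005 * np.exp(rng.normal(0, 0.2)),
        )
        ins = hf.TimeSeries((-60.0, 0.0, 60.0, 120.0, 180.0),
                            (40.0, 40.0, 320.0, 250.0, 150.0), "pmol/l")
        exo, endo = self._measured(truth, ins)
        init = replace(
            truth,
            SI_D=truth.SI_D * 1.15, p2=truth.p2 * 0.85,
            SI_P=truth.SI_P * 1.2, p2P=truth.p2P * 0.9, GE_P=truth.GE_P * 1.3,
            gi=replace(truth.gi, k_max=truth.gi.k_max * 1.2,
                       k_min=truth.gi.k_min * 0.8, k_abs=truth.gi.k_abs * 1.1),
        )
        fit = hf.fit_omm(exo, endo, ins, init, BW, staged=False,
                         rtol=1e-10, atol=1e-10)
        for name in ("SI_D", "p2", "SI_P", "p2P", "GE_P"):
            assert getattr(fit.params, name) == pytest.approx(
                getattr(truth, name), rel=5e-3), name
        for name in ("k_max", "k_min", "k_abs"):
            assert getattr(fit.params.gi, name) == pytest.approx(
                getattr(truth.gi, name), rel=5e-3), name

    def test_production_effectiveness_unidentifiable_in_t1d_flags_boundary(
            self, sub1_noisefree, config):
        """Freeing the production glucose-effectiveness term on diabetes-arm
        data (where its generating value is zero) drives it to its bound and
        the fit says so."""
        ds, truth = sub1_noisefree
        part = hf.partition_glucose(ds.plasma_total_glucose, ds.plasma_ratio,
                                    hf.baseline_ratio_of(ds))
        init = replace(truth.params.omm, fixed=("GEZI_D",))  # GE_P left free
        fit = hf.fit_omm(part.exogenous, part.endogenous, truth.insulin_input,
                         init, ds.body_weight, staged=False)
        assert any("GE_P" in w and "bound" in w for w in fit.warnings)

    def test_reported_cvs_only_for_free_parameters(self, healthy_analysis):
        fit = healthy_analysis.fit
        assert fit.converged
        assert "GEZI_D" not in fit.parameter_cv
        assert {"SI_D", "SI_P"} <= set(fit.parameter_cv)
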