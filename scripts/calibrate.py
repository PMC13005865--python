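"""One-time calibration of the synthetic-profile defaults.

Solves a small set of profile parameters so that the noise-free forward
simulation, pushed through the package's own summary operations, attains
the documented target phenotypes of each profile (see profiles.py):

* healthy — exogenous-glucose peak 5.2 mmol/l, total-glucose peak
  7.5 mmol/l, endogenous nadir 1.2 mmol/l and 0–180 min EGP suppression
  0.63, solved over (SI_D, gastric-emptying scale, k_abs, insulin-curve
  width) with SI_P solved in an inner loop; hepatic-exchange uptake for a
  liver tracer peak of 3.0 mmol/l; glycogen amplitude for an incremental
  AUC of +2.4 mol/l x min.
* t1d subgroups — insulin distribution volume for composite active-insulin
  peaks of 370 / 255 pmol/l; emptying scale for half-emptying times of
  65.3 / 110.7 min; SI_P for first-hour EGP suppression 0.26 / 0.11;
  SI_D tied to the healthy value (insulin-dependent disposal is similar
  across arms); liver peaks 6.1 / 2.7 mmol/l; glycogen incremental AUCs
  +2.5 / −3.0 mol/l x min.

The solved constants are frozen into ``hepaflux.profiles._CAL``; re-run
this script only if the model structure changes.

Usage:  python scripts/calibrate.py
"""

from __future__ import annotations

import json
from dataclasses import replace

import numpy as np
from scipy.optimize import brentq, least_squares

import hepaflux as hf
from hepaflux.datamodel import MR_GRID
from hepaflux.profiles import _CAL

TARGETS = {
    "healthy": {"exo_peak": 5.2, "total_peak": 7.5, "endo_nadir": 1.2,
                "supp_0_180": 0.63, "hepatic_peak": 3.0, "glycogen_iauc": 2400.0},
    "t1d_sub1": {"t50": 65.3, "supp_0_60": 0.26, "hepatic_peak": 6.1,
                 "glycogen_iauc": 2500.0, "composite_insulin_peak": 370.0},
    "t1d_sub2": {"t50": 110.7, "supp_0_60": 0.11, "hepatic_peak": 2.7,
                 "glycogen_iauc": -3000.0, "composite_insulin_peak": 255.0},
}

# fixed emptying shape: 5:1 fast/slow ratio, slow phase between 90% and 50%
# of the dose remaining (a glucose drink empties fast at first, then settles)
BASE_KMAX, BASE_KMIN = 0.05, 0.01


def with_cal(profile_fn, **cal_updates):
    """Rebuild a profile with updated calibration entries."""
    prof = profile_fn()
    omm = prof.omm
    gi_updates = {}
    for key, value in cal_updates.items():
        if key in ("SI_D", "SI_P"):
            omm = replace(omm, **{key: value})
        elif key in ("k_max", "k_min", "k_abs"):
            gi_updates[key] = value
        elif key == "k_in":
            prof = replace(prof, hepatic_k_in=value)
        elif key == "glycogen_amplitude":
            prof = replace(prof, glycogen=replace(prof.glycogen, amplitude=value))
        elif key == "V_I":
            prof = replace(prof, sc=replace(prof.sc, V_I=value))
        elif key == "sigma":
            prof = replace(prof, insulin_curve=replace(prof.insulin_curve, sigma=value))
        else:
            raise KeyError(key)
    omm = replace(omm, gi=replace(omm.gi, **gi_updates))
    return replace(prof, omm=omm)


def subject_metrics(prof):
    ds, truth = hf.generate_subject(prof, seed=0, noise=False)
    part = hf.partition_glucose(ds.plasma_total_glucose, ds.plasma_ratio,
                                hf.baseline_ratio_of(ds))
    sc = truth.fluxes.scalars
    return {"exo_peak": hf.peak_nadir(part.exogenous)[0],
            "total_peak": hf.peak_nadir(ds.plasma_total_glucose)[0],
            "endo_nadir": hf.peak_nadir(part.endogenous)[2],
            "supp_0_180": sc["egp_suppression_0_180"],
            "supp_0_60": sc["egp_suppression_0_60"],
            "t50": sc["t50_gr"]}


def calibrate_healthy(cal):
    tg = TARGETS["healthy"]

    def build(si_d, s, k_abs, sigma, si_p):
        return with_cal(hf.healthy_profile, SI_D=si_d, SI_P=si_p,
                        k_max=BASE_KMAX * s, k_min=BASE_KMIN * s,
                        k_abs=k_abs, sigma=sigma)

    def solve_si_p(si_d, s, k_abs, sigma):
        f = lambda lsp: subject_metrics(
            build(si_d, s, k_abs, sigma, np.exp(lsp)))["supp_0_180"] - tg["supp_0_180"]
        return np.exp(brentq(f, np.log(1e-4), np.log(3e-2), xtol=1e-11))

    def resid(x):
        si_d, s, k_abs, sigma = np.exp(x)
        si_p = solve_si_p(si_d, s, k_abs, sigma)
        m = subject_metrics(build(si_d, s, k_abs, sigma, si_p))
        return [m["exo_peak"] / tg["exo_peak"] - 1.0,
                m["total_peak"] / tg["total_peak"] - 1.0,
                m["endo_nadir"] / tg["endo_nadir"] - 1.0]

    sol = least_squares(resid, np.log([4e-5, 0.4, 0.06, 1.0]),
                        xtol=1e-13, ftol=1e-13, diff_step=1e-4)
    si_d, s, k_abs, sigma = np.exp(sol.x)
    cal["healthy"].update(SI_D=si_d, k_max=BASE_KMAX * s, k_min=BASE_KMIN * s,
                          k_abs=k_abs, sigma=sigma,
                          SI_P=solve_si_p(si_d, s, k_abs, sigma))
    print("healthy glucose residuals:", np.round(sol.fun, 8))


def calibrate_t1d(which, cal):
    tg = TARGETS[which]
    profile_fn = hf.PROFILES[which]
    # disposal sensitivity and intestinal absorption follow the healthy values
    cal[which]["SI_D"] = cal["healthy"]["SI_D"]
    cal[which]["k_abs"] = cal["healthy"]["k_abs"]

    # insulin volume -> composite active insulin peak on the blood grid
    def insulin_peak_err(v_i):
        prof = with_cal(profile_fn, V_I=v_i)
        ds, _ = hf.generate_subject(prof, seed=0, noise=False)
        composite = hf.composite_active_insulin(
            ds.plasma_insulin_fast, ds.basal_analogue_conc, ds.basal_analogue,
            hf.AnalysisConfig().active_fractions)
        return hf.peak_nadir(composite, exclude_before=-60)[0] \
            - tg["composite_insulin_peak"]

    cal[which]["V_I"] = brentq(insulin_peak_err, 0.02, 1.0, xtol=1e-10)

    # gastric-emptying scale -> half-emptying time of the dense retention curve
    prof0 = with_cal(profile_fn, **cal[which])
    dense = np.arange(0.0, 180.5, 0.5)

    def t50_err(log_s):
        s = np.exp(log_s)
        gi = replace(prof0.omm.gi, k_max=BASE_KMAX * s, k_min=BASE_KMIN * s)
        return (hf.simulate_gastro(gi, prof0.body_weight, dense).t50 or 1e9) - tg["t50"]

    s = np.exp(brentq(t50_err, np.log(0.05), np.log(20.0), xtol=1e-12))
    cal[which].update(k_max=BASE_KMAX * s, k_min=BASE_KMIN * s)

    # production sensitivity -> first-hour EGP suppression (independent of
    # SI_D and emptying: GE_P = 0 in the diabetes profiles)
    def supp_err(log_si_p):
        prof = with_cal(profile_fn, **{**cal[which], "SI_P": np.exp(log_si_p)})
        return subject_metrics(prof)["supp_0_60"] - tg["supp_0_60"]

    cal[which]["SI_P"] = np.exp(brentq(supp_err, np.log(1e-5), np.log(0.05),
                                       xtol=1e-12))


def calibrate_liver_and_glycogen(which, cal):
    tg = TARGETS[which]
    profile_fn = hf.PROFILES[which]

    def hepatic_err(log_k_in):
        prof = with_cal(profile_fn, **{**cal[which], "k_in": np.exp(log_k_in)})
        _, truth = hf.generate_subject(prof, seed=0, noise=False)
        return max(truth.hepatic_dglc.v) - tg["hepatic_peak"]

    cal[which]["k_in"] = np.exp(brentq(hepatic_err, np.log(1e-3), np.log(0.5),
                                       xtol=1e-12))

    # glycogen amplitude: the ramp's grid-trapezoid incremental AUC is A * S
    mr = np.asarray(MR_GRID)
    shape = hf.GlycogenShape(baseline=1.0, amplitude=1.0)
    S = np.trapezoid(shape(mr) - 1.0, mr)
    cal[which]["glycogen_amplitude"] = tg["glycogen_iauc"] / S


def verify(cal):
    print("\n== verification on solved values ==")
    for which in ("healthy", "t1d_sub1", "t1d_sub2"):
        prof = with_cal(hf.PROFILES[which], **cal[which])
        m = subject_metrics(prof)
        _, truth = hf.generate_subject(prof, seed=0, noise=False)
        gly = hf.iauc(truth.glycogen, (0, 180), 0.0).value
        print(which, {k: round(v, 4) for k, v in m.items()},
              "| hepatic_peak", round(max(truth.hepatic_dglc.v), 4),
              "| glycogen_iauc", round(gly, 2))


def main():
    cal = {k: dict(v) for k, v in _CAL.items()}
    calibrate_healthy(cal)
    for which in ("t1d_sub1", "t1d_sub2"):
        calibrate_t1d(which, cal)
    for which in ("healthy", "t1d_sub1", "t1d_sub2"):
        calibrate_liver_and_glycogen(which, cal)
    verify(cal)
    print("\n_CAL = " + json.dumps(
        {k: {kk: float(f"{vv:.10e}") for kk, vv in v.items()}
         for k, v in cal.items()}, indent=1))


if __name__ == "__main__":
    main()
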