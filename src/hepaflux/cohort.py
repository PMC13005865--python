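"""Forward simulation of virtual subjects and cohorts.

The generator and the estimator share one forward core: the glucose
channels come from ``omm.simulate_omm`` run on the profile's parameters,
the fast-acting insulin channel from ``insulin.simulate_sc_fast``, so a
noise-free generated subject is, by construction, an exact realisation of
the model the pipeline fits. Measurement noise is multiplicative Gaussian
per channel (truncated at zero); between-subject variability is lognormal
with unit mean, applied to a documented set of profile parameters.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, replace

import numpy as np
from scipy.integrate import solve_ivp

from .datamodel import (
    BLOOD_GRID,
    GLUCAGON_GRID,
    MR_GRID,
    AnalysisConfig,
    SubjectDataset,
    TimeSeries,
)
from .errors import DataValidationError
from .insulin import composite_active_insulin, simulate_sc_fast
from .omm import FluxTrajectories, simulate_omm
from .profiles import ProfileSpec


@dataclass(frozen=True)
class GroundTruth:
    """The noise-free truth behind one generated subject."""

    profile_name: str
    params: ProfileSpec  # the (possibly jittered) profile actually simulated
    fluxes: FluxTrajectories  # dense noise-free model trajectories
    insulin_input: TimeSeries  # dense composite active insulin, pmol/l
    hepatic_dglc: TimeSeries  # liver tracer glucose on the MR grid, mmol/l
    glycogen: TimeSeries  # glycogen concentration on the MR grid, mmol/l
    channels: dict[str, TimeSeries]  # noise-free sampled measurement channels


def _liver_exchange(k_in: float, k_out: float, plasma: TimeSeries,
                    times: np.ndarray) -> np.ndarray:
    """First-order exchange dL/dt = k_in * G_exo(t) - k_out * L, L(start) = 0."""
    tp, vp = plasma.t, plasma.v

    def rhs(t, y):
        return [k_in * np.interp(t, tp, vp) - k_out * y[0]]

    sol = solve_ivp(rhs, (times[0], times[-1]), [0.0], method="LSODA",
                    rtol=1e-10, atol=1e-12, dense_output=True)
    return np.clip(sol.sol(times)[0], 0.0, None)


def _apply_noise(values: np.ndarray, cv: float, rng: np.random.Generator) -> np.ndarray:
    if cv == 0:
        return values
    return np.clip(values * (1.0 + cv * rng.standard_normal(values.shape)), 0.0, None)


def generate_subject(
    profile: ProfileSpec,
    seed: int,
    noise: bool = True,
    config: AnalysisConfig | None = None,
    subject_id: str | None = None,
) -> tuple[SubjectDataset, GroundTruth]:
    """Simulate one virtual participant of the given profile.

    With ``noise=False`` the returned dataset samples the ground-truth
    trajectories exactly; identical seeds give byte-identical output.
    """
    config = config or AnalysisConfig()
    rng = np.random.default_rng(seed)
    blood = np.asarray(BLOOD_GRID)
    mr = np.asarray(MR_GRID)
    dose_on = profile.dose_grams > 0

    # --- insulin: the known input -------------------------------------
    dense_t = np.arange(-60.0, 180.0 + 0.25, 0.5)
    if profile.group == "healthy":
        curve = profile.insulin_curve
        fast_samples = TimeSeries(tuple(blood), tuple(curve(blood)), "pmol/l",
                                  "insulin (measured)")
        long_samples = TimeSeries(tuple(blood), tuple(np.zeros_like(blood)),
                                  "pmol/l", "long-acting insulin")
        # the model input is the measured series linearly interpolated,
        # exactly what the estimation stage will use
        insulin_input = TimeSeries(
            tuple(dense_t), tuple(np.interp(dense_t, blood, fast_samples.v)),
            "pmol/l", "active insulin input")
    else:
        fast_dense = simulate_sc_fast(profile.sc, profile.bolus_events,
                                      profile.body_weight, dense_t)
        fast_samples = TimeSeries(tuple(blood),
                                  tuple(np.interp(blood, dense_t, fast_dense.v)),
                                  "pmol/l", "fast-acting insulin (measured)")
        long_samples = TimeSeries(
            tuple(blood), tuple(np.full_like(blood, profile.basal_analogue_conc)),
            "pmol/l", "long-acting insulin (measured)")
        insulin_input = composite_active_insulin(
            fast_dense, profile.basal_analogue_conc, profile.basal_analogue,
            config.active_fractions)

    # --- glucose fluxes (shared forward core) -------------------------
    omm_params = profile.omm
    if omm_params.gi.D != profile.dose_mmol:
        omm_params = omm_params.replace_gi(D=profile.dose_mmol)
    if dose_on:
        fluxes = simulate_omm(omm_params, insulin_input, profile.body_weight,
                              rtol=config.solver_rtol, atol=config.solver_atol,
                              dense_step=config.dense_step_min)
        exo_d, endo_d = fluxes.G_exo, fluxes.G_endo
    else:  # null-tracer dataset: no meal, insulin may still act
        fluxes = simulate_omm(replace(omm_params, gi=replace(omm_params.gi, D=0.0)),
                              insulin_input, profile.body_weight,
                              rtol=config.solver_rtol, atol=config.solver_atol,
                              dense_step=config.dense_step_min)
        exo_d, endo_d = fluxes.G_exo, fluxes.G_endo

    exo_b = np.interp(blood, exo_d.t, exo_d.v)
    endo_b = np.interp(blood, endo_d.t, endo_d.v)
    total_b = exo_b + endo_b
    # measured enrichment: natural-abundance background plus the
    # purity-attenuated tracer/tracee ratio (the partition inverts this)
    ratio_b = profile.baseline_ratio + config.tracer_purity * np.where(
        endo_b > 0, exo_b / np.where(endo_b > 0, endo_b, 1.0), 0.0)

    # --- hepatic channels ---------------------------------------------
    liver = _liver_exchange(profile.hepatic_k_in, profile.hepatic_k_out,
                            exo_d, mr) if dose_on else np.zeros_like(mr)
    hepatic_truth = TimeSeries(tuple(mr), tuple(liver), "mmol/l",
                               "hepatic tracer glucose (truth)")
    amp_per_voxel = (liver / config.water_reference_conc
                     * config.deuterons_per_glucose / config.deuterons_per_water
                     * profile.water_reference_amplitude)
    glycogen_conc = profile.glycogen(mr)
    cal = profile.glycogen_calibration
    glycogen_amp = glycogen_conc * cal.phantom_amplitude / (
        cal.phantom_concentration * cal.factor_product)
    glucagon_vals = profile.glucagon(np.asarray(GLUCAGON_GRID))

    channels_truth = {
        "glucose_total": TimeSeries(tuple(blood), tuple(total_b), "mmol/l", "glucose_total"),
        "ratio": TimeSeries(tuple(blood), tuple(ratio_b), "ratio", "ratio"),
        "insulin_fast": fast_samples,
        "insulin_long": long_samples,
        "glucagon": TimeSeries(tuple(GLUCAGON_GRID), tuple(glucagon_vals),
                               "pmol/l", "glucagon"),
        "c13_glycogen": TimeSeries(tuple(mr), tuple(glycogen_amp), "a.u.", "c13_glycogen"),
        "exogenous_truth": TimeSeries(tuple(blood), tuple(exo_b), "mmol/l", "exogenous"),
        "endogenous_truth": TimeSeries(tuple(blood), tuple(endo_b), "mmol/l", "endogenous"),
    }

    cv = profile.noise_cv if noise else {}

    def noisy(series: TimeSeries, channel: str) -> TimeSeries:
        return series.with_values(_apply_noise(series.v, cv.get(channel, 0.0), rng)) \
            if noise else series

    voxels = []
    for i in range(6):
        values = _apply_noise(amp_per_voxel, cv.get("dmi_glc", 0.0), rng) \
            if noise else amp_per_voxel
        voxels.append(TimeSeries(tuple(mr), tuple(values), "a.u.", f"dmi_glc[{i}]"))

    dataset = SubjectDataset(
        subject_id=subject_id or f"{profile.name}-{seed}",
        group=profile.group,
        subgroup_hint=profile.subgroup_hint,
        body_weight=profile.body_weight,
        height=profile.height,
        dose_grams=profile.dose_grams,
        bolus_events=profile.bolus_events,
        basal_analogue=profile.basal_analogue,
        basal_analogue_conc=profile.basal_analogue_conc,
        plasma_total_glucose=noisy(channels_truth["glucose_total"], "glucose_total"),
        plasma_ratio=noisy(channels_truth["ratio"], "ratio"),
        plasma_insulin_fast=noisy(channels_truth["insulin_fast"], "insulin_fast"),
        plasma_insulin_long=noisy(channels_truth["insulin_long"], "insulin_long"),
        plasma_glucagon=noisy(channels_truth["glucagon"], "glucagon"),
        hepatic_dglc_amplitudes=tuple(voxels),
        water_reference_amplitude=profile.water_reference_amplitude,
        glycogen_amplitudes=noisy(channels_truth["c13_glycogen"], "c13_glycogen"),
        glycogen_calibration=cal,
    )
    truth = GroundTruth(
        profile_name=profile.name,
        params=profile,
        fluxes=fluxes,
        insulin_input=insulin_input,
        hepatic_dglc=hepatic_truth,
        glycogen=TimeSeries(tuple(mr), tuple(glycogen_conc), "mmol/l", "glycogen (truth)"),
        channels=channels_truth,
    )
    return dataset, truth


# parameters the between-subject lognormal jitter may touch, and where they live
_JITTER_TARGETS = {
    "G_b": ("omm", "G_b"),
    "SI_D": ("omm", "SI_D"),
    "SI_P": ("omm", "SI_P"),
    "k_abs": ("gi", "k_abs"),
    "k_in": ("self", "hepatic_k_in"),
    "V_I": ("sc", "V_I"),
}


def _lognormal_factor(cv: float, rng: np.random.Generator) -> float:
    """Unit-mean lognormal multiplier with coefficient of variation cv."""
    if cv <= 0:
        return 1.0
    sigma = float(np.sqrt(np.log1p(cv * cv)))
    return float(np.exp(rng.normal(-0.5 * sigma * sigma, sigma)))


def jitter_profile(profile: ProfileSpec, rng: np.random.Generator) -> ProfileSpec:
    """Draw one subject's parameters around the profile defaults."""
    cvs = profile.between_subject_cv
    omm = profile.omm
    gi = omm.gi
    changes: dict = {}
    for key, (where, attr) in _JITTER_TARGETS.items():
        f = _lognormal_factor(cvs.get(key, 0.0), rng)
        if f == 1.0:
            continue
        if where == "omm":
            omm = replace(omm, **{attr: getattr(omm, attr) * f})
        elif where == "gi":
            gi = replace(gi, **{attr: getattr(gi, attr) * f})
        elif where == "sc" and profile.sc is not None:
            changes["sc"] = replace(changes.get("sc", profile.sc),
                                    **{attr: getattr(changes.get("sc", profile.sc), attr) * f})
        elif where == "self":
            changes[attr] = getattr(profile, attr) * f
    # gastric emptying speed scales k_max and k_min together (fixed ratio)
    f_empt = _lognormal_factor(cvs.get("k_empt", 0.0), rng)
    gi = replace(gi, k_max=gi.k_max * f_empt, k_min=gi.k_min * f_empt)
    omm = replace(omm, gi=gi)
    changes["omm"] = omm
    gly = profile.glycogen
    f_base = _lognormal_factor(cvs.get("glycogen_baseline", 0.0), rng)
    f_amp = _lognormal_factor(cvs.get("glycogen_amplitude", 0.0), rng)
    changes["glycogen"] = replace(gly, baseline=gly.baseline * f_base,
                                  amplitude=gly.amplitude * f_amp)
    if profile.insulin_curve is not None:
        curve = profile.insulin_curve
        f_exc = _lognormal_factor(cvs.get("insulin_excursion", 0.0), rng)
        changes["insulin_curve"] = replace(
            curve, peak=curve.I_b + (curve.peak - curve.I_b) * f_exc)
    if profile.bolus_events:
        f_dose = _lognormal_factor(cvs.get("bolus_dose", 0.0), rng)
        changes["bolus_events"] = tuple(
            replace(b, dose_units=b.dose_units * f_dose) for b in profile.bolus_events)
    f_bw = _lognormal_factor(cvs.get("body_weight", 0.0), rng)
    changes["body_weight"] = profile.body_weight * f_bw
    return replace(profile, **changes)


def generate_cohort(
    mixture: list[tuple[ProfileSpec, int]],
    seed: int,
    noise: bool = True,
    config: AnalysisConfig | None = None,
) -> list[tuple[SubjectDataset, GroundTruth]]:
    """Generate independent subjects for each (profile, n) in the mixture."""
    if not mixture:
        raise DataValidationError("empty profile mixture")
    for _, n in mixture:
        if n < 1:
            raise DataValidationError("each mixture entry needs n >= 1")
    seq = np.random.SeedSequence(seed)
    total = sum(n for _, n in mixture)
    children = seq.spawn(2 * total)
    out = []
    idx = 0
    for profile, n in mixture:
        for j in range(n):
            jitter_rng = np.random.default_rng(children[idx])
            subject_seed = children[idx + 1]
            idx += 2
            subject_profile = jitter_profile(profile, jitter_rng)
            # generate_subject seeds its rng with default_rng, which accepts
            # a SeedSequence as well as an int
            ds, truth = generate_subject(subject_profile, subject_seed,
                                         noise=noise, config=config,
                                         subject_id=f"{profile.name}-{j:02d}")
            out.append((ds, truth))
    return out
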