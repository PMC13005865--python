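"""Subcutaneous fast-acting insulin kinetics and the composite active profile.

Fast-acting analogue boluses are described by a two-compartment depot with
dual absorption routes feeding a single plasma pool:

    dq1/dt = -(k_a1 + k_d) q1 + bolus impulses
    dq2/dt =  k_d q1 - k_a2 q2
    dI/dt  = -k_e (I - I_b) + F (k_a1 q1 + k_a2 q2) / (V_I * BW)

with q in pmol and I in pmol/l. The system is linear with constant
coefficients, so trajectories are evaluated exactly as a superposition of
per-bolus matrix-exponential impulse responses — no ODE solver, no
integration error. Long-acting basal analogues enter only through their
measured (or emulated) concentration multiplied by a literature free-active
fraction, superimposed on the fast-acting profile to form the composite
active insulin used as the known input of the glucose model.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, replace

import lmfit
import numpy as np
from scipy.linalg import expm

from .datamodel import BolusEvent, TimeSeries
from .errors import ConfigError, DataValidationError, FitError, IdentifiabilityError


@dataclass(frozen=True)
class SCInsulinParams:
    """Subcutaneous absorption / plasma kinetics of a fast-acting analogue."""

    k_d: float  # depot -> second-compartment transfer, 1/min
    k_a1: float  # absorption from the first depot compartment, 1/min
    k_a2: float  # absorption from the second depot compartment, 1/min
    k_e: float  # plasma elimination rate, 1/min
    V_I: float  # insulin distribution volume, l/kg
    F: float = 1.0  # bioavailability fraction
    I_b: float = 0.0  # basal plasma insulin, pmol/l

    def __post_init__(self) -> None:
        for name in ("k_d", "k_a1", "k_a2", "k_e", "V_I"):
            value = getattr(self, name)
            if not (np.isfinite(value) and value > 0):
                raise DataValidationError(f"SCInsulinParams.{name} must be finite and > 0")
        if not 0 < self.F <= 1:
            raise DataValidationError("bioavailability F must be in (0, 1]")
        if self.I_b < 0:
            raise DataValidationError("basal insulin I_b must be >= 0")

    @property
    def elimination_half_life(self) -> float:
        return math.log(2.0) / self.k_e


@dataclass(frozen=True)
class InsulinExposure:
    """Fitted fast-acting kinetics plus the composite active profile."""

    fast_params: SCInsulinParams
    fast_fit: TimeSeries  # fitted fast-acting trajectory, pmol/l
    long_active: TimeSeries  # active fraction x long-acting concentration
    composite: TimeSeries  # fast + active long, pmol/l
    analogue: str
    rss: float
    parameter_cv: dict[str, float]
    converged: bool
    warnings: tuple[str, ...] = ()


def _system_matrix(p: SCInsulinParams, body_weight: float) -> np.ndarray:
    g = p.F / (p.V_I * body_weight)
    return np.array(
        [
            [-(p.k_a1 + p.k_d), 0.0, 0.0],
            [p.k_d, -p.k_a2, 0.0],
            [g * p.k_a1, g * p.k_a2, -p.k_e],
        ]
    )


def simulate_sc_fast(
    params: SCInsulinParams,
    boluses: list[BolusEvent] | tuple[BolusEvent, ...],
    body_weight: float,
    times: np.ndarray,
) -> TimeSeries:
    """Plasma fast-acting insulin (pmol/l) on ``times``.

    Exact by linearity: each bolus contributes e^{A (t - t_bolus)} applied to
    a pure-depot initial state; contributions and the basal level add.
    """
    times = np.asarray(times, dtype=float)
    if boluses and max(b.time_min for b in boluses) > times[-1]:
        warnings.warn("bolus after the last requested time contributes nothing")
    A = _system_matrix(params, body_weight)
    deviation = np.zeros_like(times)
    for bolus in boluses:
        tau = times - bolus.time_min
        active = tau > 0
        for i in np.nonzero(active)[0]:
            state = expm(A * tau[i]) @ np.array([bolus.dose_pmol, 0.0, 0.0])
            deviation[i] += state[2]
    values = params.I_b + deviation
    return TimeSeries(tuple(times), tuple(np.maximum(values, 0.0)), "pmol/l",
                      "fast-acting insulin")


def sc_auc_above_basal(params: SCInsulinParams, dose_units: float, body_weight: float) -> float:
    """Closed-form area above basal for one bolus: F*dose/(k_e*V_I*BW)."""
    dose_pmol = dose_units * 6000.0
    return params.F * dose_pmol / (params.k_e * params.V_I * body_weight)


#: parameters estimated by default; bioavailability F stays fixed (only the
#: ratio F/V_I is identifiable from concentrations, so V_I carries the scale)
_FIT_PARAM_NAMES = ("k_d", "k_a1", "k_a2", "k_e", "V_I")


def fit_sc_model(
    measured: TimeSeries,
    boluses: list[BolusEvent] | tuple[BolusEvent, ...],
    body_weight: float,
    init: SCInsulinParams,
    cv: float = 0.06,
    proportional_weights: bool = True,
    fixed: dict[str, float] | None = None,
    bounds: dict[str, tuple[float, float]] | None = None,
) -> tuple[SCInsulinParams, dict]:
    """Weighted least squares of the depot model against measured insulin.

    Returns the estimated parameters and a diagnostics dict with the weighted
    residual sum of squares, asymptotic parameter CVs, a convergence flag and
    any warnings. Setting a bound with lower == upper (or naming a rate in
    ``fixed``) holds that parameter at its value.
    """
    if not boluses or all(b.dose_units == 0 for b in boluses):
        raise IdentifiabilityError("no non-zero bolus: absorption parameters "
                                   "cannot be identified")
    t = measured.t
    first_bolus = min(b.time_min for b in boluses)
    n_post = int(np.sum(t > first_bolus))
    fixed = dict(fixed or {})
    free_names = [n for n in _FIT_PARAM_NAMES if n not in fixed]
    if bounds:
        for name, (lo, hi) in bounds.items():
            if lo == hi and name in free_names:
                free_names.remove(name)
                fixed[name] = lo
    if n_post < 5:
        raise IdentifiabilityError(f"only {n_post} post-bolus samples; need >= 5")
    if n_post < len(free_names):
        raise IdentifiabilityError("fewer post-bolus samples than free parameters")

    pars = lmfit.Parameters()
    for name in _FIT_PARAM_NAMES:
        value = fixed.get(name, getattr(init, name))
        default_bounds = (1e-3, 2.0) if name == "V_I" else (1e-5, 2.0)
        lo, hi = (bounds or {}).get(name, default_bounds)
        if name in fixed or lo == hi:
            # lmfit rejects min == max; a held parameter just doesn't vary
            lo, hi = default_bounds
        pars.add(name, value=value, min=min(lo, value), max=max(hi, value),
                 vary=name not in fixed)

    sigma = cv * np.maximum(np.abs(measured.v), 1.0) if proportional_weights \
        else np.full_like(measured.v, cv * max(np.mean(measured.v), 1.0))

    def residuals(p: lmfit.Parameters) -> np.ndarray:
        trial = replace(init, **{n: p[n].value for n in _FIT_PARAM_NAMES})
        model = simulate_sc_fast(trial, boluses, body_weight, t)
        return (model.v - measured.v) / sigma

    result = lmfit.minimize(residuals, pars, method="leastsq")
    est = replace(init, **{n: result.params[n].value for n in _FIT_PARAM_NAMES})
    notes: list[str] = []
    if not result.success:
        notes.append(f"fit did not converge: {result.message}")
    cvs: dict[str, float] = {}
    for name in free_names:
        par = result.params[name]
        if par.stderr is not None and par.value != 0:
            cvs[name] = abs(par.stderr / par.value)
        lo, hi = par.min, par.max
        if par.value - lo < 1e-3 * (hi - lo) or hi - par.value < 1e-3 * (hi - lo):
            notes.append(f"parameter {name} at its bound ({par.value:.4g})")
    diagnostics = {
        "rss": float(np.sum(np.asarray(result.residual) ** 2)),
        "parameter_cv": cvs,
        "converged": bool(result.success),
        "warnings": tuple(notes),
        "n_post_bolus": n_post,
        "free_parameters": tuple(free_names),
    }
    return est, diagnostics


def composite_active_insulin(
    fast: TimeSeries,
    long_conc: TimeSeries | float,
    analogue: str,
    fractions: dict[str, float],
) -> TimeSeries:
    """Fast-acting profile plus the free-active fraction of the basal analogue.

    composite(t) = fast(t) + phi_analogue * long(t); phi_none = 0. A constant
    ``long_conc`` models steady basal replacement (e.g. detemir covering a
    suspended pump).
    """
    if analogue == "none":
        phi = 0.0
    elif analogue in fractions:
        phi = fractions[analogue]
    else:
        raise ConfigError(
            f"unknown basal analogue {analogue!r}; known: "
            f"{['none', *sorted(fractions)]}"
        )
    if isinstance(long_conc, TimeSeries):
        if long_conc.times != fast.times:
            long_values = np.interp(fast.t, long_conc.t, long_conc.v)
        else:
            long_values = long_conc.v
    else:
        long_values = np.full(len(fast), float(long_conc))
    values = fast.v + phi * long_values
    if np.any(values < 0):
        raise FitError("composite active insulin went negative")
    return TimeSeries(fast.times, tuple(values), "pmol/l", "composite active insulin")
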