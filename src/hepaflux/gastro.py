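"""Gastrointestinal absorption of an oral glucose drink.

A single liquid stomach compartment empties into the gut with a
glucose-mass-dependent rate and the gut absorbs into plasma:

    dq_sto/dt = -k_empt(q_sto) * q_sto,        q_sto(0) = D
    dq_gut/dt =  k_empt(q_sto) * q_sto - k_abs * q_gut

    k_empt(q) = k_min + (k_max - k_min)/2 *
                [tanh(alpha*(q - b*D)) - tanh(beta*(q - c*D)) + 2]
    alpha = 5 / (2*D*(1-b)),   beta = 5 / (2*D*c)

so emptying starts near k_max, dips towards k_min once the fraction
remaining falls below b, and returns to k_max below fraction c. The meal
rate of appearance in plasma is Ra = f_bio * k_abs * q_gut / BW
(mmol kg^-1 min^-1) and gastric retention is GR(t) = q_sto(t)/D. A solid
grinding compartment is deliberately omitted: the meal is a glucose drink.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.integrate import solve_ivp

from .datamodel import TimeSeries
from .errors import DataValidationError, FitError


@dataclass(frozen=True)
class GIParams:
    """Parameters of the gastric emptying / intestinal absorption model."""

    k_max: float  # fastest gastric emptying rate, 1/min
    k_min: float  # slowest gastric emptying rate, 1/min
    k_abs: float  # intestinal absorption rate, 1/min
    b: float = 0.90  # fraction remaining at which emptying has slowed halfway
    c: float = 0.50  # fraction remaining at which emptying has recovered halfway
    f_bio: float = 0.90  # oral bioavailability
    D: float = 0.0  # ingested dose, mmol

    def __post_init__(self) -> None:
        if self.k_min > self.k_max:
            raise DataValidationError("k_min must be <= k_max")
        if min(self.k_max, self.k_min, self.k_abs) <= 0:
            raise DataValidationError("all GI rate constants must be > 0")
        if not 0 < self.f_bio <= 1:
            raise DataValidationError("f_bio must be in (0, 1]")
        if not 0 < self.c < self.b < 1:
            raise DataValidationError("need 0 < c < b < 1")

    def k_empt(self, q_sto: np.ndarray | float) -> np.ndarray | float:
        if self.D <= 0:
            raise DataValidationError("dose D must be > 0 for emptying dynamics")
        if self.k_max == self.k_min:
            return np.broadcast_to(self.k_min, np.shape(q_sto)).astype(float) \
                if np.ndim(q_sto) else self.k_min
        alpha = 5.0 / (2.0 * self.D * (1.0 - self.b))
        beta = 5.0 / (2.0 * self.D * self.c)
        return self.k_min + 0.5 * (self.k_max - self.k_min) * (
            np.tanh(alpha * (q_sto - self.b * self.D))
            - np.tanh(beta * (q_sto - self.c * self.D))
            + 2.0
        )


@dataclass(frozen=True)
class AbsorptionTrajectories:
    """Gastric retention, meal rate of appearance and their summaries."""

    GR: TimeSeries  # dimensionless, in [0, 1]
    Ra: TimeSeries  # mmol/kg/min
    t50: float | None  # min; None when retention never reaches 0.5 on the grid
    fraction_appeared_60: float
    fraction_appeared_180: float


def gastro_rhs(t: float, y: np.ndarray, params: GIParams) -> list[float]:
    q_sto, q_gut = y
    ke = params.k_empt(max(q_sto, 0.0))
    return [-ke * q_sto, ke * q_sto - params.k_abs * q_gut]


def simulate_gastro(
    params: GIParams,
    body_weight: float,
    times: np.ndarray,
    rtol: float = 1e-8,
    atol: float = 1e-8,
) -> AbsorptionTrajectories:
    """Integrate the stomach/gut system and summarise it on ``times``.

    ``times`` must start at >= 0 (the dose is ingested at t = 0); retention
    before ingestion is identically 1. t50 is located by linear
    interpolation on the supplied grid and reported as None if retention
    never crosses one half within it.
    """
    if params.D <= 0:
        raise DataValidationError("ingested dose must be > 0")
    times = np.asarray(times, dtype=float)
    t_end = float(times[-1])
    sol = solve_ivp(
        gastro_rhs, (0.0, t_end), [params.D, 0.0], args=(params,),
        method="LSODA", rtol=rtol, atol=atol * params.D, dense_output=True,
    )
    if not sol.success:
        raise FitError(f"gastric emptying solver failed: {sol.message}")
    post = np.clip(times, 0.0, None)
    states = sol.sol(post)
    q_sto = np.where(times < 0, params.D, np.clip(states[0], 0.0, None))
    q_gut = np.where(times < 0, 0.0, np.clip(states[1], 0.0, None))
    gr_values = q_sto / params.D
    ra_values = params.f_bio * params.k_abs * q_gut / body_weight
    GR = TimeSeries(tuple(times), tuple(gr_values), "dimensionless", "gastric retention")
    Ra = TimeSeries(tuple(times), tuple(ra_values), "mmol/kg/min", "meal Ra")
    t50 = compute_t50(GR)

    def appeared(by: float) -> float:
        mask = times <= by + 1e-9
        return float(
            np.trapezoid(ra_values[mask], times[mask]) * body_weight / params.D
        )

    return AbsorptionTrajectories(
        GR=GR, Ra=Ra, t50=t50,
        fraction_appeared_60=appeared(60.0) if t_end >= 60 else float("nan"),
        fraction_appeared_180=appeared(180.0) if t_end >= 180 else float("nan"),
    )


def compute_t50(GR: TimeSeries) -> float | None:
    """Time of first crossing of retention = 0.5, by linear interpolation.

    Returns None (undefined) when the series never reaches 0.5 — e.g. a grid
    that stops before half the dose has emptied.
    """
    t, v = GR.t, GR.v
    below = np.nonzero(v <= 0.5)[0]
    if below.size == 0:
        return None
    i = below[0]
    if v[i] == 0.5 or i == 0:
        return float(t[i])
    t0, t1, v0, v1 = t[i - 1], t[i], v[i - 1], v[i]
    return float(t0 + (v0 - 0.5) * (t1 - t0) / (v0 - v1))
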