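"""Virtual-subject profiles: the study conditions the generator emulates.

Three documented profiles span the study arms: a healthy control profile
and two type 1 diabetes subgroup profiles (subgroup 1: fast gastric
emptying, steep tracer appearance, net postprandial glycogen accumulation;
subgroup 2: slow emptying, blunted tracer appearance, net glycogen
depletion). Each profile's defaults are calibrated once — by
scripts/calibrate.py — so that the noise-free forward simulation, pushed
through the full analysis pipeline, reproduces the headline postprandial
phenotypes the profiles are designed to represent (basal glucose 5.2 vs
10.7 mmol/l; total-glucose peak 7.5 mmol/l and endogenous nadir
1.2 mmol/l in health; 63% EGP suppression over 3 h in health and a
roughly halved first-hour suppression of 0.26 vs 0.11 across the
subgroups; half-emptying times 65.3 vs 110.7 min; hepatic tracer peaks
3.0 / 6.1 / 2.7 mmol/l; glycogen 0–180 min iAUCs of +2.4, +2.5 and
−3.0 mol/l x min). The calibrated values are frozen here; they are inputs
to the analysis, not quantities it estimates.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .datamodel import BolusEvent, GLUCOSE_G_PER_MMOL, GlycogenCalibration
from .errors import ConfigError
from .gastro import GIParams
from .insulin import SCInsulinParams
from .omm import OMMParams, healthy_fixing, t1d_fixing

DOSE_GRAMS = 60.0
DOSE_MMOL = DOSE_GRAMS / GLUCOSE_G_PER_MMOL  # 333.04 mmol


@dataclass(frozen=True)
class InsulinCurve:
    """Parametric endogenous insulin excursion (healthy profile only).

    Basal level plus a log-normal-shaped postprandial excursion:
    I(t) = I_b + (peak - I_b) * exp(-ln(t/t_peak)^2 / (2 sigma^2)) for t > 0.
    No beta-cell secretion model is implied — insulin is a known input.
    """

    I_b: float  # pmol/l
    peak: float  # pmol/l
    t_peak: float  # min
    sigma: float  # log-width, dimensionless

    def __call__(self, t):
        import numpy as np

        t = np.asarray(t, dtype=float)
        out = np.full_like(t, self.I_b)
        pos = t > 0
        out[pos] = self.I_b + (self.peak - self.I_b) * np.exp(
            -np.log(t[pos] / self.t_peak) ** 2 / (2.0 * self.sigma**2)
        )
        return out


@dataclass(frozen=True)
class GlycogenShape:
    """Net hepatic glycogen trajectory: baseline + A * ramp((t - t_on)/w).

    The ramp is the C1 smoothstep 3x^2 - 2x^3 on (0, 1); A > 0 means net
    postprandial accumulation, A < 0 net depletion. The trajectory is a
    descriptive concentration curve — no glycogen flux model is implied.
    """

    baseline: float  # mmol/l
    amplitude: float  # mmol/l (signed)
    t_on: float = 30.0  # min
    width: float = 120.0  # min

    def __post_init__(self) -> None:
        if not self.baseline > 0:
            raise ConfigError("glycogen baseline must be > 0")

    def __call__(self, t):
        import numpy as np

        x = np.clip((np.asarray(t, dtype=float) - self.t_on) / self.width, 0.0, 1.0)
        return self.baseline + self.amplitude * (3.0 * x**2 - 2.0 * x**3)


@dataclass(frozen=True)
class GlucagonShape:
    """Descriptive postprandial glucagon: decline to a nadir, partial return.

    Purely phenomenological; the fitted model never consumes glucagon.
    """

    g0: float  # pmol/l at T0
    nadir: float  # pmol/l
    t_nadir: float  # min

    def __call__(self, t):
        import numpy as np

        t = np.asarray(t, dtype=float)
        shape = np.minimum(np.abs(t - self.t_nadir) / self.t_nadir, 1.0)
        out = self.nadir + (self.g0 - self.nadir) * shape
        out[t <= 0] = self.g0
        return out


@dataclass(frozen=True)
class ProfileSpec:
    """Everything needed to forward-simulate one virtual participant."""

    name: str
    group: str  # {"healthy", "t1d"}
    subgroup_hint: str
    body_weight: float  # kg
    height: float  # m
    dose_grams: float
    omm: OMMParams
    sc: SCInsulinParams | None  # t1d only
    bolus_events: tuple[BolusEvent, ...]
    basal_analogue: str
    basal_analogue_conc: float  # pmol/l, constant (pump-replacement emulation)
    insulin_curve: InsulinCurve | None  # healthy only
    glycogen: GlycogenShape
    hepatic_k_in: float  # liver tracer-glucose uptake from plasma, 1/min
    hepatic_k_out: float  # liver tracer-glucose washout, 1/min
    glucagon: GlucagonShape
    baseline_ratio: float = 0.004  # pre-dose natural-abundance enrichment
    water_reference_amplitude: float = 500.0  # a.u.
    glycogen_calibration: GlycogenCalibration = field(
        default_factory=lambda: GlycogenCalibration(
            phantom_concentration=500.0, phantom_amplitude=1000.0,
            f_distance=1.25, f_loading=0.95, f_T1=1.40, f_NOE=0.75,
        )
    )
    noise_cv: dict = field(
        default_factory=lambda: {
            "glucose_total": 0.02, "ratio": 0.02, "insulin_fast": 0.06,
            "insulin_long": 0.06, "glucagon": 0.10, "dmi_glc": 0.08,
            "c13_glycogen": 0.10,
        }
    )
    between_subject_cv: dict = field(
        default_factory=lambda: {
            "G_b": 0.08, "SI_D": 0.20, "SI_P": 0.20, "k_empt": 0.15,
            "k_abs": 0.15, "k_in": 0.15, "glycogen_baseline": 0.20,
            "glycogen_amplitude": 0.25, "insulin_excursion": 0.30,
            "V_I": 0.25, "bolus_dose": 0.25, "body_weight": 0.12,
        }
    )

    def __post_init__(self) -> None:
        if self.hepatic_k_in <= 0 or self.hepatic_k_out <= 0:
            raise ConfigError("hepatic exchange rates must be > 0")
        for cv in {**self.noise_cv, **self.between_subject_cv}.values():
            if cv < 0:
                raise ConfigError("coefficients of variation must be >= 0")

    @property
    def dose_mmol(self) -> float:
        return self.dose_grams / GLUCOSE_G_PER_MMOL


# ---------------------------------------------------------------------------
# Calibrated default profiles. The numeric constants below were solved by
# scripts/calibrate.py (root-finding of the forward model against the target
# phenotypes documented in the module docstring) and are frozen.

#: disposal glucose effectiveness at zero insulin: healthy population value
GEZI_HEALTHY = 0.015
#: proportional GEZI adjustment applied in type 1 diabetes
GEZI_T1D_SCALE = 0.5
GLUCOSE_VOLUME = 0.145  # l/kg

_CAL = {
    # solved by scripts/calibrate.py -- do not edit by hand
    "healthy": {
        "SI_D": 1.1523171517e-05, "SI_P": 2.7490125557e-03,
        "k_max": 1.4047780674e-02, "k_min": 2.8095561348e-03,
        "k_abs": 6.4878910725e-02, "sigma": 1.2247664304,
        "k_in": 1.9328662158e-02, "glycogen_amplitude": 2.6666666667e+01,
    },
    "t1d_sub1": {
        "SI_D": 1.1523171517e-05, "SI_P": 1.0856284804e-03,
        "k_max": 2.7876486492e-02, "k_min": 5.5752972983e-03,
        "k_abs": 6.4878910725e-02, "k_in": 1.5515818567e-02,
        "glycogen_amplitude": 2.7777777778e+01, "V_I": 1.4216868500e-01,
    },
    "t1d_sub2": {
        "SI_D": 1.1523171517e-05, "SI_P": 7.5274872699e-04,
        "k_max": 1.6443908004e-02, "k_min": 3.2887816008e-03,
        "k_abs": 6.4878910725e-02, "k_in": 9.9236655279e-03,
        "glycogen_amplitude": -3.3333333333e+01, "V_I": 1.8623657413e-01,
    },
}


def _gi(cal: dict, dose_mmol: float = DOSE_MMOL) -> GIParams:
    return GIParams(k_max=cal["k_max"], k_min=cal["k_min"], k_abs=cal["k_abs"],
                    b=0.90, c=0.50, f_bio=0.90, D=dose_mmol)


def healthy_profile() -> ProfileSpec:
    cal = _CAL["healthy"]
    omm = OMMParams(
        V=GLUCOSE_VOLUME, GEZI_D=GEZI_HEALTHY,
        SI_D=cal["SI_D"], p2=0.02,
        SI_P=cal["SI_P"], p2P=0.04, GE_P=0.005,
        G_b=5.2, I_b=43.4,
        gi=_gi(cal), fixed=healthy_fixing(),
    )
    return ProfileSpec(
        name="healthy", group="healthy", subgroup_hint="none",
        body_weight=81.8, height=1.76, dose_grams=DOSE_GRAMS,
        omm=omm, sc=None, bolus_events=(), basal_analogue="none",
        basal_analogue_conc=0.0,
        insulin_curve=InsulinCurve(I_b=43.4, peak=366.0, t_peak=81.0,
                                   sigma=cal["sigma"]),
        glycogen=GlycogenShape(baseline=230.0, amplitude=cal["glycogen_amplitude"]),
        hepatic_k_in=cal["k_in"], hepatic_k_out=0.03,
        glucagon=GlucagonShape(g0=4.41, nadir=1.05, t_nadir=63.0),
    )


def _t1d_profile(which: str, g_b: float, body_weight: float, height: float,
                 bolus_units: float, glycogen_baseline: float,
                 glucagon: GlucagonShape) -> ProfileSpec:
    cal = _CAL[which]
    omm = OMMParams(
        V=GLUCOSE_VOLUME, GEZI_D=GEZI_HEALTHY * GEZI_T1D_SCALE,
        SI_D=cal["SI_D"], p2=0.02,
        SI_P=cal["SI_P"], p2P=0.04, GE_P=0.0,
        G_b=g_b, I_b=75.0,  # composite basal: residual fast + active detemir
        gi=_gi(cal), fixed=t1d_fixing(),
    )
    # depot-route-dominant kinetics: plasma peaks ~50 min after the bolus,
    # as a rapid-acting analogue does
    sc = SCInsulinParams(k_d=0.030, k_a1=0.002, k_a2=0.018, k_e=0.10,
                         V_I=cal["V_I"], F=0.80, I_b=20.0)
    return ProfileSpec(
        name=which, group="t1d", subgroup_hint=which[-1],
        body_weight=body_weight, height=height, dose_grams=DOSE_GRAMS,
        omm=omm, sc=sc,
        bolus_events=(BolusEvent(time_min=-45.0, dose_units=bolus_units),),
        basal_analogue="detemir", basal_analogue_conc=220.0,
        insulin_curve=None,
        glycogen=GlycogenShape(baseline=glycogen_baseline,
                               amplitude=cal["glycogen_amplitude"]),
        hepatic_k_in=cal["k_in"], hepatic_k_out=0.03,
        glucagon=glucagon,
    )


def t1d_sub1_profile() -> ProfileSpec:
    """Subgroup 1: faster emptying, steeper tracer rise, glycogen accrual."""
    return _t1d_profile("t1d_sub1", g_b=10.8, body_weight=77.5, height=1.70,
                        bolus_units=8.2, glycogen_baseline=274.0,
                        glucagon=GlucagonShape(g0=2.01, nadir=1.15, t_nadir=52.0))


def t1d_sub2_profile() -> ProfileSpec:
    """Subgroup 2: slower emptying, blunted tracer rise, glycogen depletion."""
    return _t1d_profile("t1d_sub2", g_b=10.6, body_weight=87.5, height=1.76,
                        bolus_units=7.4, glycogen_baseline=312.0,
                        glucagon=GlucagonShape(g0=3.98, nadir=2.51, t_nadir=60.0))


PROFILES = {
    "healthy": healthy_profile,
    "t1d_sub1": t1d_sub1_profile,
    "t1d_sub2": t1d_sub2_profile,
}


def study_mixture() -> list[tuple[ProfileSpec, int]]:
    """The default study emulation: 10 healthy + 6 subgroup-1 + 4 subgroup-2."""
    return [(healthy_profile(), 10), (t1d_sub1_profile(), 6), (t1d_sub2_profile(), 4)]
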