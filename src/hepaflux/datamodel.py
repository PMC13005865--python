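"""Core domain types: time series, per-subject datasets, calibration and config.

Conventions
-----------
* Time is in minutes relative to T0, the start of tracer ingestion; negative
  times are pre-dose (the fasting blood draw at T−60, the prandial insulin
  bolus at roughly T−45).
* Concentrations are mmol/l (glucose, glycogen) or pmol/l (insulin, glucagon);
  spectral amplitudes are arbitrary units ("a.u."); tracer enrichment is a
  dimensionless molar ratio.
* Missing samples are absent rows, never sentinel values — glucagon is drawn
  on a sparser schedule by design.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .errors import AlignmentError, ConfigError, DataValidationError, UnitError

#: molar mass of glucose used for dose conversion, g/mmol (isotope mass
#: difference of the dideuterated tracer is <1.2% and is ignored)
GLUCOSE_G_PER_MMOL = 0.180156

#: pmol of insulin per international unit
PMOL_PER_UNIT = 6000.0

ALLOWED_UNITS = {
    "mmol/l",
    "pmol/l",
    "ratio",
    "a.u.",
    "mmol/l/min",
    "mmol/kg/min",
    "dimensionless",
}

#: blood sampling grid, minutes relative to dose ingestion
BLOOD_GRID = (-60.0, 0.0, 10.0, 20.0, 30.0, 60.0, 90.0, 120.0, 150.0, 180.0)
#: glucagon subset of the blood grid
GLUCAGON_GRID = (0.0, 10.0, 30.0, 60.0, 120.0, 180.0)
#: MR sampling grid for the imaging channels (10-min spacing; extends to
#: 180 min so 0–180 incremental AUCs of the imaging channels are computable)
MR_GRID = tuple(float(t) for t in range(0, 181, 10))

GROUPS = ("healthy", "t1d")
BASAL_ANALOGUES = ("none", "glargine", "detemir", "degludec")


@dataclass(frozen=True)
class TimeSeries:
    """An irregularly sampled scalar signal with a declared unit."""

    times: tuple[float, ...]
    values: tuple[float, ...]
    unit: str
    label: str = ""

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        v = np.asarray(self.values, dtype=float)
        if t.size < 1:
            raise DataValidationError(f"{self.label or 'series'}: length must be >= 1")
        if t.size != v.size:
            raise DataValidationError(
                f"{self.label or 'series'}: times and values differ in length"
            )
        if t.size > 1 and not np.all(np.diff(t) > 0):
            raise DataValidationError(
                f"{self.label or 'series'}: times must be strictly increasing"
            )
        if not np.all(np.isfinite(t)) or not np.all(np.isfinite(v)):
            raise DataValidationError(f"{self.label or 'series'}: non-finite entries")
        if self.unit not in ALLOWED_UNITS:
            raise UnitError(
                f"{self.label or 'series'}: unknown unit {self.unit!r}; "
                f"allowed: {sorted(ALLOWED_UNITS)}"
            )
        object.__setattr__(self, "times", tuple(float(x) for x in t))
        object.__setattr__(self, "values", tuple(float(x) for x in v))

    # -- convenience -------------------------------------------------------
    @property
    def t(self) -> np.ndarray:
        return np.asarray(self.times, dtype=float)

    @property
    def v(self) -> np.ndarray:
        return np.asarray(self.values, dtype=float)

    def __len__(self) -> int:
        return len(self.times)

    def at(self, time: float) -> float:
        """Linear interpolation inside the support; error outside."""
        t = self.t
        if time < t[0] - 1e-9 or time > t[-1] + 1e-9:
            raise AlignmentError(
                f"time {time} outside support [{t[0]}, {t[-1]}] of "
                f"{self.label or 'series'}")
        return float(np.interp(time, t, self.v))

    def window(self, t_start: float, t_end: float) -> "TimeSeries":
        mask = (self.t >= t_start) & (self.t <= t_end)
        return TimeSeries(tuple(self.t[mask]), tuple(self.v[mask]), self.unit, self.label)

    def with_values(self, values: Sequence[float]) -> "TimeSeries":
        return replace(self, values=tuple(float(x) for x in values))


@dataclass(frozen=True)
class GlycogenCalibration:
    """Phantom-replacement calibration chain for natural-abundance 13C MRS.

    The product of the four correction factors maps the in-vivo/phantom
    amplitude ratio onto a concentration: coil-to-liver distance, coil
    loading, T1 relaxation and nuclear Overhauser enhancement.
    """

    phantom_concentration: float  # mmol/l
    phantom_amplitude: float  # a.u.
    f_distance: float = 1.0
    f_loading: float = 1.0
    f_T1: float = 1.0
    f_NOE: float = 1.0

    def __post_init__(self) -> None:
        for name in ("phantom_concentration", "phantom_amplitude",
                     "f_distance", "f_loading", "f_T1", "f_NOE"):
            if not getattr(self, name) > 0:
                raise ConfigError(f"GlycogenCalibration.{name} must be > 0")

    @property
    def factor_product(self) -> float:
        return self.f_distance * self.f_loading * self.f_T1 * self.f_NOE


@dataclass(frozen=True)
class BolusEvent:
    """A subcutaneous fast-acting insulin bolus."""

    time_min: float
    dose_units: float
    analogue: str = "aspart"

    def __post_init__(self) -> None:
        if self.dose_units < 0:
            raise DataValidationError("bolus dose must be >= 0")

    @property
    def dose_pmol(self) -> float:
        return self.dose_units * PMOL_PER_UNIT


@dataclass(frozen=True)
class AnalysisConfig:
    """Tunable constants of the analysis, every default overridable on disk.

    tracer_purity
        Isotopic purity of the ingested dideuterated glucose (fraction).
    water_reference_conc
        Assumed hepatic natural-abundance mono-2H water concentration used as
        the internal reference for deuterium imaging, mmol/l.
    deuterons_per_glucose / deuterons_per_water
        Label multiplicities used for per-deuteron amplitude normalisation.
    gezi_disposal_healthy
        Population value of disposal glucose effectiveness at zero insulin
        (min⁻¹); fixed during fitting for identifiability.
    gezi_t1d_scale
        Proportional adjustment of GEZI_Disposal applied in type 1 diabetes.
    active_fractions
        Free-active fraction of each long-acting basal analogue that is
        superimposed on the fast-acting profile.
    """

    tracer_purity: float = 0.99
    water_reference_conc: float = 8.94
    deuterons_per_glucose: int = 2
    deuterons_per_water: int = 1
    gezi_disposal_healthy: float = 0.015
    gezi_t1d_scale: float = 0.5
    active_fractions: dict = field(
        default_factory=lambda: {"glargine": 1.00, "detemir": 0.25, "degludec": 0.0285}
    )
    glucose_volume: float = 0.145  # glucose distribution volume, l/kg
    f_bio: float = 0.90  # oral bioavailability of the glucose drink
    # measurement-error coefficients of variation per channel, used as WLS
    # weights and as the generator's noise model
    channel_cv: dict = field(
        default_factory=lambda: {
            "glucose_total": 0.02,
            "ratio": 0.02,
            "insulin_fast": 0.06,
            "insulin_long": 0.06,
            "glucagon": 0.10,
            "dmi_glc": 0.08,
            "c13_glycogen": 0.10,
        }
    )
    residual_floor_mmol: float = 0.2  # floor on proportional-error sigma
    solver_rtol: float = 1e-8
    solver_atol: float = 1e-8
    dense_step_min: float = 0.5
    mole_percent_excess: bool = False  # alternative enrichment convention
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.tracer_purity <= 1:
            raise ConfigError("tracer_purity must be in (0, 1]")
        for name, frac in self.active_fractions.items():
            if not 0 <= frac <= 1:
                raise ConfigError(f"active fraction for {name} outside [0, 1]")
        for name in ("water_reference_conc", "gezi_disposal_healthy",
                     "glucose_volume", "solver_rtol", "solver_atol",
                     "dense_step_min"):
            if not getattr(self, name) > 0:
                raise ConfigError(f"AnalysisConfig.{name} must be > 0")


@dataclass(frozen=True)
class SubjectDataset:
    """Everything measured on one participant during the visit."""

    subject_id: str
    group: str
    body_weight: float  # kg
    height: float  # m
    dose_grams: float  # grams of dideuterated glucose ingested
    subgroup_hint: str = "none"  # {"none", "1", "2"}: generating profile, if known
    bolus_events: tuple[BolusEvent, ...] = ()
    basal_analogue: str = "none"
    basal_analogue_conc: float = 0.0  # circulating long-acting analogue, pmol/l
    plasma_total_glucose: TimeSeries | None = None
    plasma_ratio: TimeSeries | None = None
    plasma_insulin_fast: TimeSeries | None = None
    plasma_insulin_long: TimeSeries | None = None
    plasma_glucagon: TimeSeries | None = None
    hepatic_dglc_amplitudes: tuple[TimeSeries, ...] = ()
    water_reference_amplitude: float = 0.0
    glycogen_amplitudes: TimeSeries | None = None
    glycogen_calibration: GlycogenCalibration | None = None

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise DataValidationError(f"unknown group {self.group!r}")
        if self.basal_analogue not in BASAL_ANALOGUES:
            raise DataValidationError(f"unknown basal analogue {self.basal_analogue!r}")
        if not self.body_weight > 0:
            raise DataValidationError("body_weight must be > 0")
        if self.dose_grams < 0:
            raise DataValidationError("dose_grams must be >= 0")

    @property
    def dose_mmol(self) -> float:
        """Ingested tracer dose in mmol (dose in g over 0.180156 g/mmol)."""
        return self.dose_grams / GLUCOSE_G_PER_MMOL


@dataclass(frozen=True)
class Finding:
    """One validation finding; `severity` is 'error' or 'warning'."""

    severity: str
    message: str


def validate_dataset(ds: SubjectDataset) -> list[Finding]:
    """Check the study-protocol invariants of a dataset.

    Returns a list of findings (empty means clean). Structural invariants
    violated at construction raise instead; this function covers the softer
    protocol conventions. It never mutates its input. A glucagon series
    present only on its sparser schedule is by design, not a finding.
    """
    findings: list[Finding] = []
    if ds.dose_grams == 0:
        findings.append(Finding("warning", "dose_grams is 0: null-tracer dataset"))
    if ds.group == "t1d":
        if not any(b.time_min < 0 for b in ds.bolus_events):
            findings.append(
                Finding("warning",
                        "no prandial bolus before T0 (protocol gives the "
                        "fast-acting bolus about 45 min pre-dose)")
            )
    if ds.hepatic_dglc_amplitudes and len(ds.hepatic_dglc_amplitudes) != 6:
        findings.append(
            Finding("warning",
                    f"{len(ds.hepatic_dglc_amplitudes)} deuterium voxels; the "
                    "quantification convention averages six central voxels")
        )
    if ds.hepatic_dglc_amplitudes and not ds.water_reference_amplitude > 0:
        findings.append(
            Finding("error", "deuterium voxels present but no positive "
                             "baseline water reference amplitude")
        )
    if ds.glycogen_amplitudes is not None and ds.glycogen_calibration is None:
        findings.append(
            Finding("error", "glycogen amplitudes present without calibration")
        )
    for name in ("plasma_total_glucose", "plasma_ratio"):
        series = getattr(ds, name)
        if series is not None and not math.isclose(series.times[0], -60.0):
            findings.append(
                Finding("warning", f"{name} does not start at the T−60 fasting draw")
            )
    return findings
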