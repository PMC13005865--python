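"""Concentration quantification for the two magnetic-resonance channels.

Deuterated glucose (deuterium imaging): each voxel's glucose-peak amplitude
is normalised per deuteron (two labelled positions per glucose, one per
mono-deuterated water), referenced to the pre-ingestion natural-abundance
water amplitude of the same voxels, and scaled by the assumed hepatic
mono-deuterated water concentration (8.94 mmol/l by default). Voxel
averaging happens after per-voxel quantification. The result is mmol of
tracer glucose per selected volume — hepatocytes plus sinusoids.

Glycogen (carbon-13 at natural abundance): in-vivo amplitudes are referenced
to a phantom of known concentration and corrected multiplicatively for
coil-to-liver distance, coil loading, T1 relaxation and nuclear Overhauser
enhancement.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .datamodel import AnalysisConfig, GlycogenCalibration, TimeSeries
from .errors import AlignmentError, ConfigError, DataValidationError


@dataclass(frozen=True)
class DMIQuantInput:
    voxel_amplitudes: tuple[TimeSeries, ...]  # per-voxel glucose-peak amplitudes, a.u.
    water_baseline_amplitude: float  # pre-ingestion water amplitude, a.u.

    def __post_init__(self) -> None:
        if len(self.voxel_amplitudes) < 1:
            raise DataValidationError("need at least one voxel")
        if not self.water_baseline_amplitude > 0:
            raise ConfigError("water baseline amplitude must be > 0")
        for series in self.voxel_amplitudes:
            if np.any(series.v < 0):
                raise DataValidationError(f"negative amplitude in {series.label}")


def dglc_concentration(inp: DMIQuantInput, config: AnalysisConfig) -> TimeSeries:
    """Voxel-averaged hepatic tracer-glucose concentration, mmol/l.

    C(t) = mean over voxels of
           (A_glc(t)/n_D,glc) / (A_water,0/n_D,water) * C_water,ref
    """
    grids = {series.times for series in inp.voxel_amplitudes}
    if len(grids) != 1:
        raise AlignmentError("voxel amplitude series are on different time grids")
    per_deuteron_water = inp.water_baseline_amplitude / config.deuterons_per_water
    stack = np.vstack([s.v for s in inp.voxel_amplitudes]) / config.deuterons_per_glucose
    conc = (stack / per_deuteron_water).mean(axis=0) * config.water_reference_conc
    times = inp.voxel_amplitudes[0].times
    return TimeSeries(times, tuple(conc), "mmol/l", "hepatic tracer glucose")


def glycogen_concentration(amplitudes: TimeSeries, cal: GlycogenCalibration) -> TimeSeries:
    """Phantom-referenced hepatic glycogen concentration, mmol/l.

    C(t) = A(t)/A_phantom * C_phantom * f_distance * f_loading * f_T1 * f_NOE
    """
    if np.any(amplitudes.v < 0):
        raise DataValidationError("negative glycogen amplitude sample")
    scale = cal.phantom_concentration / cal.phantom_amplitude * cal.factor_product
    return TimeSeries(amplitudes.times, tuple(amplitudes.v * scale),
                      "mmol/l", "hepatic glycogen")
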