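"""Partition of total plasma glucose into exogenous and endogenous pools.

The GC-MS readout is the molar ratio r of dideuterated tracer to
unlabelled (tracee) glucose. After subtracting the pre-dose natural
abundance background and correcting for tracer purity,

    r' = (r - r_baseline) / purity          (clipped at 0)
    exogenous  = total * r' / (1 + r')
    endogenous = total - exogenous

so the two pools reconstruct total glucose exactly by construction. An
alternative mole-percent-excess convention (r interpreted as the labelled
mole fraction, exogenous = total * r') is available behind the config
switch ``mole_percent_excess``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .datamodel import TimeSeries
from .errors import AlignmentError, ConfigError

logger = logging.getLogger("hepaflux")


@dataclass(frozen=True)
class PartitionResult:
    exogenous: TimeSeries  # mmol/l
    endogenous: TimeSeries  # mmol/l
    corrected_ratio: TimeSeries  # dimensionless


def partition_glucose(
    total: TimeSeries,
    ratio: TimeSeries,
    baseline_ratio: float,
    purity: float = 0.99,
    mole_percent_excess: bool = False,
) -> PartitionResult:
    """Split total glucose using the purity-corrected enrichment ratio.

    ``baseline_ratio`` is the measured pre-dose ratio (the natural-abundance
    background); negative corrected ratios (assay noise at early times) are
    clipped to zero with a warning, not an error.
    """
    if purity <= 0 or purity > 1:
        raise ConfigError("tracer purity must be in (0, 1]")
    if total.times != ratio.times:
        raise AlignmentError("total glucose and enrichment ratio are on "
                             "different time grids")
    corrected = (ratio.v - baseline_ratio) / purity
    if np.any(corrected < -1e-12):
        logger.warning("negative corrected enrichment at %d sample(s); clipped to 0",
                       int(np.sum(corrected < -1e-12)))
    corrected = np.clip(corrected, 0.0, None)
    if mole_percent_excess:
        frac = np.clip(corrected, 0.0, 1.0)
    else:
        frac = corrected / (1.0 + corrected)
    exo = total.v * frac
    endo = total.v - exo
    mk = lambda v, unit, label: TimeSeries(total.times, tuple(v), unit, label)
    return PartitionResult(
        exogenous=mk(exo, "mmol/l", "exogenous glucose"),
        endogenous=mk(endo, "mmol/l", "endogenous glucose"),
        corrected_ratio=mk(corrected, "dimensionless", "corrected enrichment"),
    )
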