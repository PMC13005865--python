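"""On-disk layout: one metadata JSON + one tidy long-format CSV per subject.

The CSV has columns ``time_min, channel, voxel, value, unit`` with
``channel`` one of glucose_total, ratio, insulin_fast, insulin_long,
glucagon, dmi_glc, c13_glycogen; ``voxel`` is empty except for dmi_glc.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import sys
from pathlib import Path

import pandas as pd
import yaml

from .datamodel import (
    AnalysisConfig,
    BolusEvent,
    GlycogenCalibration,
    SubjectDataset,
    TimeSeries,
    validate_dataset,
)
from .errors import SchemaError, UnitError

logger = logging.getLogger("hepaflux")

CHANNELS = {
    "glucose_total": ("plasma_total_glucose", "mmol/l"),
    "ratio": ("plasma_ratio", "ratio"),
    "insulin_fast": ("plasma_insulin_fast", "pmol/l"),
    "insulin_long": ("plasma_insulin_long", "pmol/l"),
    "glucagon": ("plasma_glucagon", "pmol/l"),
    "c13_glycogen": ("glycogen_amplitudes", "a.u."),
}

_CSV_COLUMNS = ["time_min", "channel", "voxel", "value", "unit"]


def configure_logging(level: int = logging.INFO, logfile: str | Path | None = None) -> None:
    """Timestamped logging to stderr and, optionally, a file."""
    handlers: list[logging.Handler] = [logging.StreamHandler(sys.stderr)]
    if logfile is not None:
        handlers.append(logging.FileHandler(logfile))
    fmt = logging.Formatter("%(asctime)s %(levelname)s %(name)s: %(message)s")
    logger.setLevel(level)
    logger.handlers.clear()
    for h in handlers:
        h.setFormatter(fmt)
        logger.addHandler(h)


def save_dataset(ds: SubjectDataset, directory: str | Path) -> Path:
    """Write a subject to ``directory`` (metadata.json + measurements.csv)."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    meta = {
        "subject_id": ds.subject_id,
        "group": ds.group,
        "subgroup_hint": ds.subgroup_hint,
        "body_weight": ds.body_weight,
        "height": ds.height,
        "dose_grams": ds.dose_grams,
        "basal_analogue": ds.basal_analogue,
        "basal_analogue_conc": ds.basal_analogue_conc,
        "bolus_events": [
            {"time_min": b.time_min, "dose_units": b.dose_units, "analogue": b.analogue}
            for b in ds.bolus_events
        ],
        "water_reference_amplitude": ds.water_reference_amplitude,
        "glycogen_calibration": (
            dataclasses.asdict(ds.glycogen_calibration)
            if ds.glycogen_calibration is not None
            else None
        ),
    }
    (directory / "metadata.json").write_text(json.dumps(meta, indent=1))

    rows: list[dict] = []

    def emit(series: TimeSeries | None, channel: str, voxel: str = "") -> None:
        if series is None:
            return
        for t, v in zip(series.times, series.values):
            rows.append({"time_min": t, "channel": channel, "voxel": voxel,
                         "value": v, "unit": series.unit})

    for channel, (attr, _) in CHANNELS.items():
        emit(getattr(ds, attr), channel)
    for i, voxel_series in enumerate(ds.hepatic_dglc_amplitudes):
        emit(voxel_series, "dmi_glc", voxel=str(i))
    pd.DataFrame(rows, columns=_CSV_COLUMNS).to_csv(
        directory / "measurements.csv", index=False, float_format="%.17g")
    logger.info("saved subject %s to %s (%d rows)", ds.subject_id, directory, len(rows))
    return directory


def load_dataset(path: str | Path, config: AnalysisConfig | None = None) -> SubjectDataset:
    """Load and validate one subject from its on-disk directory.

    Raises SchemaError for missing files/fields/columns, UnitError for a unit
    not matching the channel's declared unit (no silent conversion), and the
    TimeSeries constructor raises for non-increasing time grids.
    """
    path = Path(path)
    meta_file = path / "metadata.json"
    csv_file = path / "measurements.csv"
    if not meta_file.exists():
        raise SchemaError(f"missing metadata file {meta_file}")
    if not csv_file.exists():
        raise SchemaError(f"missing measurements file {csv_file}")
    meta = json.loads(meta_file.read_text())
    for key in ("subject_id", "group", "body_weight", "height", "dose_grams"):
        if key not in meta:
            raise SchemaError(f"metadata missing required field {key!r}")
    df = pd.read_csv(csv_file, dtype={"voxel": "string"},
                     float_precision="round_trip")
    missing = set(_CSV_COLUMNS) - set(df.columns)
    if missing:
        raise SchemaError(f"measurements.csv missing columns {sorted(missing)}")

    def series_for(channel: str, sub: pd.DataFrame, label: str) -> TimeSeries | None:
        if sub.empty:
            return None
        units = sub["unit"].unique()
        expected = CHANNELS.get(channel, (None, "a.u."))[1]
        if len(units) != 1 or units[0] != expected:
            raise UnitError(
                f"channel {channel!r} carries unit(s) {list(units)}; expected "
                f"{expected!r} (no implicit conversion)"
            )
        sub = sub.sort_values("time_min")
        return TimeSeries(tuple(sub["time_min"]), tuple(sub["value"]), expected, label)

    kwargs: dict = {}
    for channel, (attr, _) in CHANNELS.items():
        kwargs[attr] = series_for(channel, df[df["channel"] == channel], channel)
    dmi = df[df["channel"] == "dmi_glc"]
    voxels = []
    if not dmi.empty:
        for voxel_id in sorted(dmi["voxel"].dropna().unique(), key=lambda s: int(s)):
            voxels.append(series_for("dmi_glc", dmi[dmi["voxel"] == voxel_id],
                                     f"dmi_glc[{voxel_id}]"))
    cal = meta.get("glycogen_calibration")
    ds = SubjectDataset(
        subject_id=str(meta["subject_id"]),
        group=meta["group"],
        subgroup_hint=str(meta.get("subgroup_hint", "none")),
        body_weight=float(meta["body_weight"]),
        height=float(meta["height"]),
        dose_grams=float(meta["dose_grams"]),
        basal_analogue=meta.get("basal_analogue", "none"),
        basal_analogue_conc=float(meta.get("basal_analogue_conc", 0.0)),
        bolus_events=tuple(
            BolusEvent(b["time_min"], b["dose_units"], b.get("analogue", "aspart"))
            for b in meta.get("bolus_events", [])
        ),
        hepatic_dglc_amplitudes=tuple(voxels),
        water_reference_amplitude=float(meta.get("water_reference_amplitude", 0.0)),
        glycogen_calibration=GlycogenCalibration(**cal) if cal else None,
        **kwargs,
    )
    for finding in validate_dataset(ds):
        logger.log(logging.ERROR if finding.severity == "error" else logging.WARNING,
                   "%s: %s", ds.subject_id, finding.message)
    return ds


def load_config(path: str | Path) -> AnalysisConfig:
    """Read an AnalysisConfig from YAML or JSON; unknown keys are rejected."""
    path = Path(path)
    raw = yaml.safe_load(path.read_text()) or {}
    known = {f.name for f in dataclasses.fields(AnalysisConfig)}
    unknown = set(raw) - known
    if unknown:
        raise SchemaError(f"unknown config keys: {sorted(unknown)}")
    defaults = AnalysisConfig()
    merged = {}
    for f in dataclasses.fields(AnalysisConfig):
        if f.name in raw:
            value = raw[f.name]
            if isinstance(getattr(defaults, f.name), dict):
                value = {**getattr(defaults, f.name), **value}
            merged[f.name] = value
    return dataclasses.replace(defaults, **merged)


def save_config(config: AnalysisConfig, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(dataclasses.asdict(config), sort_keys=False))
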