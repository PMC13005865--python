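import dataclasses

import numpy as np
import pandas as pd
import pytest

import hepaflux as hf
from hepaflux.datamodel import GLUCOSE_G_PER_MMOL
from hepaflux.errors import DataValidationError, SchemaError, UnitError


class TestTimeSeries:
    def test_strictly_increasing_times_enforced(self):
        with pytest.raises(DataValidationError):
            hf.TimeSeries((0.0, 10.0, 10.0), (1.0, 2.0, 3.0), "mmol/l")

    def test_unknown_unit_rejected(self):
        with pytest.raises(UnitError):
            hf.TimeSeries((0.0,), (1.0,), "mg/dl")

    def test_non_finite_rejected(self):
        with pytest.raises(DataValidationError):
            hf.TimeSeries((0.0, 1.0), (1.0, float("nan")), "mmol/l")

    def test_length_mismatch_rejected(self):
        with pytest.raises(DataValidationError):
            hf.TimeSeries((0.0, 1.0), (1.0,), "mmol/l")


def test_dose_conversion_grams_to_mmol(healthy_noisefree):
    ds, _ = healthy_noisefree
    assert ds.dose_grams == 60.0
    assert ds.dose_mmol == pytest.approx(60.0 / GLUCOSE_G_PER_MMOL)
    assert ds.dose_mmol == pytest.approx(333.04, abs=0.005)


def test_round_trip_is_identity(tmp_path):
    ds, _ = hf.generate_subject(hf.t1d_sub1_profile(), seed=11, noise=True)
    hf.save_dataset(ds, tmp_path / "s1")
    ds2 = hf.load_dataset(tmp_path / "s1")
    for field in ("subject_id", "group", "subgroup_hint", "body_weight",
                  "height", "dose_grams", "basal_analogue",
                  "basal_analogue_conc", "bolus_events",
                  "water_reference_amplitude", "glycogen_calibration"):
        assert getattr(ds2, field) == getattr(ds, field), field
    for channel in ("plasma_total_glucose", "plasma_ratio",
                    "plasma_insulin_fast", "plasma_insulin_long",
                    "plasma_glucagon", "glycogen_amplitudes"):
        a, b = getattr(ds, channel), getattr(ds2, channel)
        assert a.times == b.times, channel
        np.testing.assert_allclose(a.v, b.v, rtol=1e-9)
    assert len(ds2.hepatic_dglc_amplitudes) == 6
    for va, vb in zip(ds.hepatic_dglc_amplitudes, ds2.hepatic_dglc_amplitudes):
        np.testing.assert_allclose(va.v, vb.v, rtol=1e-9)


def test_load_rejects_missing_column(tmp_path):
    ds, _ = hf.generate_subject(hf.healthy_profile(), seed=0, noise=False)
    hf.save_dataset(ds, tmp_path / "s")
    csv = tmp_path / "s" / "measurements.csv"
    df = pd.read_csv(csv).drop(columns=["unit"])
    df.to_csv(csv, index=False)
    with pytest.raises(SchemaError, match="unit"):
        hf.load_dataset(tmp_path / "s")


def test_load_rejects_wrong_unit_without_conversion(tmp_path):
    ds, _ = hf.generate_subject(hf.healthy_profile(), seed=0, noise=False)
    hf.save_dataset(ds, tmp_path / "s")
    csv = tmp_path / "s" / "measurements.csv"
    df = pd.read_csv(csv, dtype={"voxel": "string"})
    df.loc[df.channel == "glucose_total", "unit"] = "mg/dl"
    df.to_csv(csv, index=False)
    with pytest.raises(UnitError, match="glucose_total"):
        hf.load_dataset(tmp_path / "s")


def test_load_rejects_missing_metadata_field(tmp_path):
    ds, _ = hf.generate_subject(hf.healthy_profile(), seed=0, noise=False)
    hf.save_dataset(ds, tmp_path / "s")
    meta = tmp_path / "s" / "metadata.json"
    import json
    raw = json.loads(meta.read_text())
    del raw["dose_grams"]
    meta.write_text(json.dumps(raw))
    with pytest.raises(SchemaError, match="dose_grams"):
        hf.load_dataset(tmp_path / "s")


class TestValidation:
    def test_clean_default_dataset(self, healthy_noisefree):
        ds, _ = healthy_noisefree
        assert hf.validate_dataset(ds) == []

    def test_t1d_without_prandial_bolus_warns(self, sub1_noisefree):
        ds, _ = sub1_noisefree
        ds2 = dataclasses.replace(ds, bolus_events=())
        findings = hf.validate_dataset(ds2)
        assert any("prandial bolus" in f.message and f.severity == "warning"
                   for f in findings)

    def test_five_voxels_warns_about_six_voxel_convention(self, healthy_noisefree):
        ds, _ = healthy_noisefree
        ds2 = dataclasses.replace(ds, hepatic_dglc_amplitudes=ds.hepatic_dglc_amplitudes[:5])
        findings = hf.validate_dataset(ds2)
        assert any("six" in f.message for f in findings)

    def test_sparse_glucagon_grid_is_not_a_finding(self, healthy_noisefree):
        ds, _ = healthy_noisefree
        assert len(ds.plasma_glucagon) < len(ds.plasma_total_glucose)
        assert hf.validate_dataset(ds) == []

    def test_validation_is_pure(self, healthy_noisefree):
        ds, _ = healthy_noisefree
        before = dataclasses.replace(ds)
        hf.validate_dataset(ds)
        assert ds == before


def test_config_round_trip_and_unknown_key(tmp_path):
    cfg = hf.AnalysisConfig(tracer_purity=0.97)
    hf.save_config(cfg, tmp_path / "cfg.yaml")
    cfg2 = hf.load_config(tmp_path / "cfg.yaml")
    assert cfg2 == cfg
    (tmp_path / "bad.yaml").write_text("not_a_setting: 1\n")
    with pytest.raises(SchemaError, match="not_a_setting"):
        hf.load_config(tmp_path / "bad.yaml")


def test_config_rejects_invalid_purity():
    from hepaflux.errors import ConfigError
    with pytest.raises(ConfigError):
        hf.AnalysisConfig(tracer_purity=0.0)
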