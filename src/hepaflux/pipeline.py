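"""Per-subject analysis pipeline and the cohort report builder.

One subject flows: measured channels -> tracer partition -> (type 1
diabetes only) subcutaneous insulin fit and composite active profile ->
oral-minimal-model fit -> MRS quantification -> summary metrics. The
cohort report aggregates per-subject metrics into group summaries
(mean ± SD, SEM, 95% CI), pairwise contrasts, and the subgroup clustering
on tracer-glucose incremental AUCs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np

from .analysis import (
    ClusterResult,
    CohortReport,
    cluster_subgroups,
    iauc,
    peak_nadir,
    summarise,
    two_sample_t,
)
from .datamodel import AnalysisConfig, SubjectDataset, TimeSeries
from .errors import DataValidationError
from .gastro import GIParams
from .insulin import (
    InsulinExposure,
    SCInsulinParams,
    composite_active_insulin,
    fit_sc_model,
    simulate_sc_fast,
)
from .mrs import DMIQuantInput, dglc_concentration, glycogen_concentration
from .omm import (
    FitResult,
    OMMParams,
    egp_suppression,
    fit_omm,
    healthy_fixing,
    rd_fractional_increase,
    report_ge_disposal,
    t1d_fixing,
)
from .partition import PartitionResult, partition_glucose

logger = logging.getLogger("hepaflux")

#: generic starting values for the glucose-model fit (deliberately not any
#: profile's generating values — the estimator has to find those)
DEFAULT_OMM_INIT = {
    "SI_D": 8.0e-5, "p2": 0.025, "SI_P": 3.0e-3, "p2P": 0.020,
    "GE_P": 0.004, "k_max": 0.05, "k_min": 0.012, "k_abs": 0.12,
}
DEFAULT_SC_INIT = SCInsulinParams(k_d=0.02, k_a1=0.025, k_a2=0.010,
                                  k_e=0.10, V_I=0.12, F=0.80, I_b=20.0)


@dataclass(frozen=True)
class SubjectAnalysis:
    subject_id: str
    group: str
    partition: PartitionResult
    exposure: InsulinExposure | None  # None for healthy (measured insulin used)
    insulin_input: TimeSeries
    fit: FitResult | None
    hepatic_dglc: TimeSeries | None
    glycogen: TimeSeries | None
    metrics: dict[str, float]


def baseline_ratio_of(ds: SubjectDataset) -> float:
    """Mean of the pre-dose (t <= 0) enrichment samples."""
    r = ds.plasma_ratio
    pre = r.v[r.t <= 0]
    if pre.size == 0:
        raise DataValidationError("no pre-dose enrichment sample")
    return float(pre.mean())


def default_omm_init(ds: SubjectDataset, insulin_input: TimeSeries,
                     config: AnalysisConfig) -> OMMParams:
    """Population starting point with the group's fixing rules applied."""
    g = ds.plasma_total_glucose
    g_b = float(g.v[g.t <= -59][0]) if np.any(g.t <= -59) else float(g.v[0])
    i_b = float(np.interp(-60.0, insulin_input.t, insulin_input.v))
    init = dict(DEFAULT_OMM_INIT)
    if ds.group == "t1d":
        gezi = config.gezi_disposal_healthy * config.gezi_t1d_scale
        ge_p, fixed = 0.0, t1d_fixing()
    else:
        gezi = config.gezi_disposal_healthy
        ge_p, fixed = init["GE_P"], healthy_fixing()
    return OMMParams(
        V=config.glucose_volume, GEZI_D=gezi,
        SI_D=init["SI_D"], p2=init["p2"],
        SI_P=init["SI_P"], p2P=init["p2P"], GE_P=ge_p,
        G_b=g_b, I_b=i_b,
        gi=GIParams(k_max=init["k_max"], k_min=init["k_min"],
                    k_abs=init["k_abs"], f_bio=config.f_bio, D=ds.dose_mmol),
        fixed=fixed,
    )


def insulin_input_for(ds: SubjectDataset, config: AnalysisConfig,
                      sc_init: SCInsulinParams | None = None,
                      ) -> tuple[TimeSeries, InsulinExposure | None]:
    """The composite active insulin input for the glucose model.

    Healthy subjects: the measured insulin, linearly interpolated, is the
    input (no kinetic model). Type 1 diabetes: the fast-acting channel is
    described by the subcutaneous depot model (known bolus timing/dosing),
    and the active fraction of the long-acting analogue is superimposed.
    """
    fast = ds.plasma_insulin_fast
    if ds.group == "healthy":
        return fast, None
    sc_init = sc_init or DEFAULT_SC_INIT
    i_b_meas = float(fast.v[fast.t <= min(b.time_min for b in ds.bolus_events)][0]) \
        if ds.bolus_events else float(fast.v[0])
    sc_init = replace(sc_init, I_b=max(i_b_meas, 0.0))
    params, diag = fit_sc_model(
        fast, ds.bolus_events, ds.body_weight, sc_init,
        cv=config.channel_cv["insulin_fast"])
    dense = np.arange(fast.t[0], fast.t[-1] + 0.25, 0.5)
    fast_fit = simulate_sc_fast(params, ds.bolus_events, ds.body_weight, dense)
    long_series = ds.plasma_insulin_long
    long_dense = np.interp(dense, long_series.t, long_series.v) \
        if long_series is not None else np.zeros_like(dense)
    composite = composite_active_insulin(
        fast_fit, TimeSeries(tuple(dense), tuple(long_dense), "pmol/l", "long"),
        ds.basal_analogue, config.active_fractions)
    phi = config.active_fractions.get(ds.basal_analogue, 0.0) \
        if ds.basal_analogue != "none" else 0.0
    exposure = InsulinExposure(
        fast_params=params, fast_fit=fast_fit,
        long_active=TimeSeries(tuple(dense), tuple(phi * long_dense),
                               "pmol/l", "active long insulin"),
        composite=composite, analogue=ds.basal_analogue,
        rss=diag["rss"], parameter_cv=diag["parameter_cv"],
        converged=diag["converged"], warnings=diag["warnings"],
    )
    return composite, exposure


def _auc(series: TimeSeries, window: tuple[float, float]) -> float:
    """Plain (non-incremental) trapezoid AUC over the window."""
    t, v = series.t, series.v
    t0, t1 = window
    inner = (t > t0) & (t < t1)
    tt = np.concatenate(([t0], t[inner], [t1]))
    vv = np.concatenate(([np.interp(t0, t, v)], v[inner], [np.interp(t1, t, v)]))
    return float(np.trapezoid(vv, tt))


def analyse_subject(
    ds: SubjectDataset,
    config: AnalysisConfig | None = None,
    fit: bool = True,
    omm_init: OMMParams | None = None,
) -> SubjectAnalysis:
    """Run the full per-subject pipeline; ``fit=False`` skips model fitting
    (measured-channel metrics only, e.g. for clustering)."""
    config = config or AnalysisConfig()
    part = partition_glucose(
        ds.plasma_total_glucose, ds.plasma_ratio, baseline_ratio_of(ds),
        purity=config.tracer_purity,
        mole_percent_excess=config.mole_percent_excess)

    insulin_input, exposure = insulin_input_for(ds, config)

    hepatic = glycogen = None
    if ds.hepatic_dglc_amplitudes:
        hepatic = dglc_concentration(
            DMIQuantInput(ds.hepatic_dglc_amplitudes, ds.water_reference_amplitude),
            config)
    if ds.glycogen_amplitudes is not None and ds.glycogen_calibration is not None:
        glycogen = glycogen_concentration(ds.glycogen_amplitudes, ds.glycogen_calibration)

    metrics: dict[str, float] = {}
    g = ds.plasma_total_glucose
    metrics["glucose_basal"] = float(g.v[0])  # T−60 fasting draw
    pk, pkt, _, _ = peak_nadir(g)
    metrics["glucose_peak"], metrics["glucose_peak_time"] = pk, pkt
    pk, pkt, _, _ = peak_nadir(part.exogenous)
    metrics["exo_peak"], metrics["exo_peak_time"] = pk, pkt
    _, _, nd, ndt = peak_nadir(part.endogenous)
    metrics["endo_nadir"], metrics["endo_nadir_time"] = nd, ndt
    metrics["plasma_dglc_iauc_0_60"] = iauc(part.exogenous, (0, 60), 0.0).value
    metrics["plasma_dglc_iauc_0_180"] = iauc(part.exogenous, (0, 180), 0.0).value

    ins = composite_active_insulin(
        ds.plasma_insulin_fast,
        ds.plasma_insulin_long if ds.plasma_insulin_long is not None else 0.0,
        ds.basal_analogue, config.active_fractions)
    metrics["insulin_basal"] = float(ins.v[0])
    pk, pkt, _, _ = peak_nadir(ins)
    metrics["insulin_peak"], metrics["insulin_peak_time"] = pk, pkt
    metrics["insulin_auc_0_60"] = _auc(ins, (0, 60))
    metrics["insulin_auc_0_180"] = _auc(ins, (0, 180))
    metrics["insulin_auc_m60_180"] = _auc(ins, (-60, 180))
    metrics["insulin_mean"] = metrics["insulin_auc_m60_180"] / 240.0

    gl = ds.plasma_glucagon
    if gl is not None:
        metrics["glucagon_t0"] = float(np.interp(0.0, gl.t, gl.v))
        _, _, nd, ndt = peak_nadir(gl)
        metrics["glucagon_nadir"], metrics["glucagon_nadir_time"] = nd, ndt
        metrics["glucagon_iauc_0_60"] = iauc(gl, (0, 60), 0.0).value
        metrics["glucagon_iauc_0_180"] = iauc(gl, (0, 180), 0.0).value
        metrics["glucagon_mean"] = _auc(gl, (0, 180)) / 180.0

    if hepatic is not None:
        pk, pkt, _, _ = peak_nadir(hepatic)
        metrics["hepatic_dglc_peak"], metrics["hepatic_dglc_peak_time"] = pk, pkt
        metrics["hepatic_dglc_iauc_0_180"] = iauc(hepatic, (0, 180), 0.0).value
    if glycogen is not None:
        metrics["glycogen_basal"] = float(np.interp(0.0, glycogen.t, glycogen.v))
        metrics["glycogen_iauc_0_180"] = iauc(glycogen, (0, 180), 0.0).value

    fit_result = None
    if fit:
        init = omm_init or default_omm_init(ds, insulin_input, config)
        fit_result = fit_omm(
            part.exogenous, part.endogenous, insulin_input, init,
            ds.body_weight,
            cv_exo=config.channel_cv["ratio"],
            cv_endo=config.channel_cv["glucose_total"],
            sigma_floor=config.residual_floor_mmol,
            rtol=config.solver_rtol, atol=config.solver_atol)
        p = fit_result.params
        metrics["si_disposal"] = p.SI_D
        metrics["si_production"] = p.SI_P
        metrics["ge_production"] = p.GE_P
        metrics["ge_disposal"] = report_ge_disposal(p)
        sc = fit_result.fluxes.scalars
        metrics["egp_suppression_0_60"] = sc["egp_suppression_0_60"]
        metrics["egp_suppression_0_180"] = sc["egp_suppression_0_180"]
        metrics["rd_increase_0_60"] = sc["rd_fractional_increase_0_60"]
        metrics["rd_increase_0_180"] = sc["rd_fractional_increase_0_180"]
        metrics["iauc_ra_per_dose_60"] = sc["iauc_ra_per_dose_60"]
        metrics["iauc_ra_per_dose_180"] = sc["iauc_ra_per_dose_180"]
        if sc["t50_gr"] is not None:
            metrics["t50_gr"] = sc["t50_gr"]
        if not fit_result.converged:
            logger.warning("%s: glucose model fit did not converge", ds.subject_id)

    return SubjectAnalysis(
        subject_id=ds.subject_id, group=ds.group, partition=part,
        exposure=exposure, insulin_input=insulin_input, fit=fit_result,
        hepatic_dglc=hepatic, glycogen=glycogen, metrics=metrics)


#: metrics every full cohort report must carry (completeness manifest)
REPORT_METRICS = [
    "glucose_basal", "glucose_peak", "glucose_peak_time",
    "exo_peak", "exo_peak_time", "endo_nadir", "endo_nadir_time",
    "insulin_basal", "insulin_peak", "insulin_peak_time",
    "insulin_auc_0_60", "insulin_auc_0_180", "insulin_auc_m60_180", "insulin_mean",
    "glucagon_t0", "glucagon_nadir", "glucagon_nadir_time",
    "glucagon_iauc_0_60", "glucagon_iauc_0_180", "glucagon_mean",
    "hepatic_dglc_peak", "hepatic_dglc_peak_time", "hepatic_dglc_iauc_0_180",
    "glycogen_basal", "glycogen_iauc_0_180",
    "plasma_dglc_iauc_0_60", "plasma_dglc_iauc_0_180",
    "si_disposal", "si_production", "ge_disposal", "ge_production",
    "egp_suppression_0_60", "egp_suppression_0_180",
    "rd_increase_0_60", "rd_increase_0_180", "t50_gr",
]


def build_cohort_report(
    analyses: list[SubjectAnalysis],
    config: AnalysisConfig | None = None,
    cluster_t1d: bool = True,
) -> CohortReport:
    """Aggregate per-subject metrics into the cohort report.

    Group summaries and healthy-vs-t1d contrasts cover every metric present
    in at least two subjects per group; the type 1 diabetes arm is
    partitioned by Ward clustering on the plasma/hepatic tracer iAUCs and
    subgroup contrasts are reported over the resulting labels.
    """
    if not analyses:
        raise DataValidationError("no subjects")
    groups = sorted({a.group for a in analyses})
    by_group = {g: [a for a in analyses if a.group == g] for g in groups}
    for g, members in by_group.items():
        if not members:
            raise DataValidationError(f"group {g} has no subjects")

    metric_names = sorted({m for a in analyses for m in a.metrics})
    summaries = {
        g: {
            name: summarise([a.metrics[name] for a in members if name in a.metrics])
            for name in metric_names
            if sum(name in a.metrics for a in members) >= 1
        }
        for g, members in by_group.items()
    }

    comparisons = []

    def compare(label_a, members_a, label_b, members_b):
        for name in metric_names:
            va = [a.metrics[name] for a in members_a if name in a.metrics]
            vb = [a.metrics[name] for a in members_b if name in a.metrics]
            if len(va) >= 2 and len(vb) >= 2:
                comparisons.append(
                    two_sample_t(va, vb, metric=f"{name} ({label_a} vs {label_b})"))

    if "healthy" in by_group and "t1d" in by_group:
        compare("healthy", by_group["healthy"], "t1d", by_group["t1d"])

    cluster: ClusterResult | None = None
    cluster_ids: tuple[str, ...] = ()
    t1d = by_group.get("t1d", [])
    if cluster_t1d and len(t1d) >= 2:
        feats = np.array([[a.metrics["plasma_dglc_iauc_0_180"],
                           a.metrics["hepatic_dglc_iauc_0_180"]] for a in t1d])
        cluster = cluster_subgroups(feats, k=2)
        cluster_ids = tuple(a.subject_id for a in t1d)
        sub1 = [a for a, lbl in zip(t1d, cluster.labels) if lbl == 1]
        sub2 = [a for a, lbl in zip(t1d, cluster.labels) if lbl == 2]
        compare("subgroup1", sub1, "subgroup2", sub2)

    return CohortReport(
        subject_metrics={a.subject_id: dict(a.metrics) for a in analyses},
        group_of={a.subject_id: a.group for a in analyses},
        summaries=summaries,
        comparisons=comparisons,
        cluster=cluster,
        cluster_subjects=cluster_ids,
    )
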