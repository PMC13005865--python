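"""Summary metrics, group statistics and subgroup discovery.

Incremental AUCs use the trapezoid rule on the measured grid with linear
interpolation at window endpoints, relative to the value at a stated
baseline time (T0 for 0-anchored windows; T−60 for the whole-visit insulin
window). Group contrasts are pooled-variance two-sample t tests (Welch
optional) reported as mean ± SD with the 95% CI of the difference; no
multiple-testing correction is applied — each contrast stands alone at
two-sided alpha 0.05. Subgroup discovery is Ward-linkage hierarchical
clustering on z-scored per-subject incremental AUCs of plasma and hepatic
tracer glucose.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage
from sklearn.metrics import silhouette_score

from .datamodel import TimeSeries
from .errors import DataValidationError


@dataclass(frozen=True)
class SummaryMetric:
    name: str
    window: tuple[float, float]
    baseline_time: float
    value: float
    unit: str


@dataclass(frozen=True)
class GroupComparison:
    metric: str
    mean_a: float
    sd_a: float
    mean_b: float
    sd_b: float
    n_a: int
    n_b: int
    difference: float
    ci95: tuple[float, float]
    t_statistic: float
    p_value: float


@dataclass(frozen=True)
class ClusterResult:
    feature_names: tuple[str, ...]
    feature_means: tuple[float, ...]
    feature_sds: tuple[float, ...]
    linkage_matrix: np.ndarray
    labels: tuple[int, ...]  # 1-based; cluster 1 has the higher plasma iAUC
    silhouette: float | None


def iauc(
    series: TimeSeries,
    window: tuple[float, float],
    baseline_time: float,
    name: str = "",
) -> SummaryMetric:
    """Incremental area under the curve relative to the baseline sample.

    Additive over abutting windows that share a baseline (exact for the
    trapezoid rule). The unit is the series unit x min.
    """
    t_start, t_end = window
    t, v = series.t, series.v
    if t_end <= t_start:
        raise DataValidationError("window must be ordered and non-empty")
    for point in (t_start, t_end, baseline_time):
        if point < t[0] - 1e-9 or point > t[-1] + 1e-9:
            raise DataValidationError(
                f"time {point} outside series support [{t[0]}, {t[-1]}]")
    base = float(np.interp(baseline_time, t, v))
    inner = (t > t_start) & (t < t_end)
    tt = np.concatenate(([t_start], t[inner], [t_end]))
    vv = np.concatenate(([np.interp(t_start, t, v)], v[inner],
                         [np.interp(t_end, t, v)])) - base
    return SummaryMetric(
        name=name or f"iAUC {series.label}".strip(),
        window=window,
        baseline_time=baseline_time,
        value=float(np.trapezoid(vv, tt)),
        unit=f"{series.unit} x min",
    )


def peak_nadir(
    series: TimeSeries, exclude_before: float = 0.0
) -> tuple[float, float, float, float]:
    """(peak value, peak time, nadir value, nadir time) over t >= exclude_before.

    The default excludes the fasting T−60 draw but keeps T0. Ties go to the
    earliest time.
    """
    mask = series.t >= exclude_before
    if not np.any(mask):
        raise DataValidationError("all samples excluded from peak/nadir search")
    t, v = series.t[mask], series.v[mask]
    i_peak = int(np.argmax(v))
    i_nadir = int(np.argmin(v))
    return float(v[i_peak]), float(t[i_peak]), float(v[i_nadir]), float(t[i_nadir])


def two_sample_t(
    a: Sequence[float], b: Sequence[float], metric: str = "", welch: bool = False
) -> GroupComparison:
    """Independent two-sample t test with the 95% CI of the mean difference."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise DataValidationError("each group needs n >= 2")
    if not (np.all(np.isfinite(a)) and np.all(np.isfinite(b))):
        raise DataValidationError("non-finite values in t-test input")
    diff = float(a.mean() - b.mean())
    if welch:
        res = stats.ttest_ind(a, b, equal_var=False)
        t_stat, p = float(res.statistic), float(res.pvalue)
        se = float(np.sqrt(a.var(ddof=1) / len(a) + b.var(ddof=1) / len(b)))
        df = float(res.df)
    else:
        n_a, n_b = len(a), len(b)
        df = n_a + n_b - 2
        sp2 = ((n_a - 1) * a.var(ddof=1) + (n_b - 1) * b.var(ddof=1)) / df
        se = float(np.sqrt(sp2 * (1 / n_a + 1 / n_b)))
        if se == 0.0:
            t_stat, p = 0.0, 1.0
        else:
            t_stat = diff / se
            p = float(2 * stats.t.sf(abs(t_stat), df))
    half = float(stats.t.ppf(0.975, df)) * se if se > 0 else 0.0
    return GroupComparison(
        metric=metric,
        mean_a=float(a.mean()), sd_a=float(a.std(ddof=1)),
        mean_b=float(b.mean()), sd_b=float(b.std(ddof=1)),
        n_a=len(a), n_b=len(b),
        difference=diff, ci95=(diff - half, diff + half),
        t_statistic=t_stat, p_value=p,
    )


def cluster_subgroups(
    features: np.ndarray,
    k: int = 2,
    feature_names: tuple[str, ...] = ("iauc_plasma_dglc", "iauc_hepatic_dglc"),
    method: str = "ward",
) -> ClusterResult:
    """Hierarchical clustering of subjects on z-scored incremental AUCs.

    Features are standardised, clustered with Ward linkage on Euclidean
    distance and cut at ``k``; labels are renumbered so cluster 1 has the
    larger mean of the first feature (plasma tracer-glucose iAUC). With
    k = 1 a single all-inclusive cluster is returned and the silhouette is
    undefined (None).
    """
    X = np.asarray(features, dtype=float)
    if X.ndim != 2 or not np.all(np.isfinite(X)):
        raise DataValidationError("features must be a finite 2-D matrix")
    n = X.shape[0]
    if n < k:
        raise DataValidationError(f"cannot form {k} clusters from {n} subjects")
    mu, sd = X.mean(axis=0), X.std(axis=0, ddof=0)
    sd = np.where(sd == 0, 1.0, sd)
    Z = (X - mu) / sd
    if k == 1:
        return ClusterResult(feature_names, tuple(mu), tuple(sd),
                             linkage(Z, method=method) if n > 1 else np.empty((0, 4)),
                             tuple([1] * n), None)
    link = linkage(Z, method=method)
    raw = fcluster(link, t=k, criterion="maxclust")
    if len(np.unique(raw)) < k:
        raise DataValidationError("identical subjects prevent a k-way partition")
    # relabel by descending mean of the first feature
    order = sorted(np.unique(raw), key=lambda c: -X[raw == c, 0].mean())
    relabel = {old: new + 1 for new, old in enumerate(order)}
    labels = tuple(int(relabel[c]) for c in raw)
    sil = float(silhouette_score(Z, labels)) if 1 < k < n else None
    return ClusterResult(feature_names, tuple(mu), tuple(sd), link, labels, sil)


# ---------------------------------------------------------------------------
# cohort report


@dataclass
class CohortReport:
    """Per-group summaries, pairwise contrasts and the subgroup clustering."""

    subject_metrics: dict[str, dict[str, float]]  # subject_id -> metric -> value
    group_of: dict[str, str]
    summaries: dict[str, dict[str, dict[str, float]]]  # group -> metric -> stats
    comparisons: list[GroupComparison] = field(default_factory=list)
    cluster: ClusterResult | None = None
    cluster_subjects: tuple[str, ...] = ()

    def to_json(self) -> str:
        payload = {
            "subject_metrics": self.subject_metrics,
            "group_of": self.group_of,
            "summaries": self.summaries,
            "comparisons": [vars(c) for c in self.comparisons],
            "cluster_labels": (
                dict(zip(self.cluster_subjects, self.cluster.labels))
                if self.cluster else None
            ),
            "cluster_silhouette": self.cluster.silhouette if self.cluster else None,
        }
        return json.dumps(payload, indent=1, default=float)

    def to_markdown(self) -> str:
        lines = ["# Cohort report", "", "## Group summaries (mean ± SD, SEM, 95% CI)", ""]
        for group, metrics in self.summaries.items():
            lines.append(f"### {group}")
            lines.append("| metric | mean | SD | SEM | 95% CI | n |")
            lines.append("|---|---|---|---|---|---|")
            for metric, s in metrics.items():
                lines.append(
                    f"| {metric} | {s['mean']:.4g} | {s['sd']:.4g} | {s['sem']:.4g} "
                    f"| [{s['ci95_low']:.4g}, {s['ci95_high']:.4g}] | {int(s['n'])} |")
            lines.append("")
        if self.comparisons:
            lines += ["## Contrasts", "",
                      "| metric | groups | difference | 95% CI | t | p |", "|---|---|---|---|---|---|"]
            for c in self.comparisons:
                lines.append(
                    f"| {c.metric} | {c.n_a} vs {c.n_b} | {c.difference:.4g} | "
                    f"[{c.ci95[0]:.4g}, {c.ci95[1]:.4g}] | {c.t_statistic:.3f} | {c.p_value:.4g} |")
        if self.cluster:
            sizes = {lbl: self.cluster.labels.count(lbl) for lbl in set(self.cluster.labels)}
            lines += ["", f"## Subgroup clustering: sizes {sizes}, "
                          f"silhouette {self.cluster.silhouette}"]
        return "\n".join(lines)


def summarise(values: Sequence[float]) -> dict[str, float]:
    """mean, SD, SEM = SD/sqrt(n) and the t-based 95% CI of the mean."""
    x = np.asarray(values, dtype=float)
    n = len(x)
    mean = float(x.mean())
    sd = float(x.std(ddof=1)) if n > 1 else 0.0
    sem = sd / np.sqrt(n) if n > 0 else float("nan")
    half = float(stats.t.ppf(0.975, n - 1)) * sem if n > 1 else 0.0
    return {"mean": mean, "sd": sd, "sem": sem,
            "ci95_low": mean - half, "ci95_high": mean + half, "n": float(n)}
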