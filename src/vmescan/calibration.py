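"""Density/richness calibration against expert Yes/Maybe/No labels.

Reproduces the threshold-calibration analysis: after the small-image filter
and count-to-density conversion, densities are regressed on candidate
confounders (depth; percent *soft* substrate, taken as 100 − % hard), then
for each metric (richness per m², each focal taxon, each registry group and
the overall indicator density) the labelled groups are summarised
(mean ± sample SD), compared by one-way ANOVA, and contrasted pairwise with
Tukey's HSD (Tukey–Kramer for unequal group sizes).  Candidate thresholds
separating Yes from No images are derived by configurable estimators; the
study design deliberately leaves the final threshold choice open.

No multiple-testing correction is applied across metrics, matching the
per-metric reporting convention; the report records how many tests were run
so users can adjust.
"""

from __future__ import annotations

import itertools
import json
import math
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy import stats

from .annotations import AnnotationDataset, LABELS
from .densities import DensityTable, compute_densities, group_density
from .registry import IndicatorRegistry, TaxonGroup

__all__ = [
    "GroupStats",
    "AnovaResult",
    "TukeyResult",
    "RegressionResult",
    "ThresholdEstimate",
    "CalibrationReport",
    "summarize_by_label",
    "oneway_anova",
    "tukey_hsd",
    "covariate_regression",
    "derive_thresholds",
    "run_calibration_report",
]

THRESHOLD_METHODS = ("midpoint_means", "no_quantile", "min_misclassification")


class CalibrationError(ValueError):
    pass


@dataclass(frozen=True)
class GroupStats:
    """Per-label summary: n, mean ± sample SD (n−1 denominator), min, max."""

    label: str
    n: int
    mean: float
    sd: Optional[float]  # absent when n == 1
    min: float
    max: float
    units: str = "per_m2"


@dataclass(frozen=True)
class AnovaResult:
    F: float
    df_between: int
    df_within: int
    p: float


@dataclass(frozen=True)
class TukeyPair:
    label_a: str
    label_b: str
    mean_diff: float  # mean(b) - mean(a)
    p_adj: float


@dataclass(frozen=True)
class TukeyResult:
    pairs: tuple[TukeyPair, ...]

    def p_for(self, a: str, b: str) -> float:
        for pair in self.pairs:
            if {pair.label_a, pair.label_b} == {a, b}:
                return pair.p_adj
        raise KeyError((a, b))


@dataclass(frozen=True)
class RegressionResult:
    slope: float
    intercept: float
    p: float
    n: int
    n_dropped: int = 0


@dataclass(frozen=True)
class ThresholdEstimate:
    metric: str
    method: str
    value: float
    n_yes: int
    n_no: int


def _group_arrays(
    values: Sequence[float], labels: Sequence[Optional[str]]
) -> dict[str, np.ndarray]:
    values = np.asarray(values, dtype=float)
    if len(values) != len(labels):
        raise CalibrationError("values and labels must align")
    out: dict[str, np.ndarray] = {}
    for lab in LABELS:
        mask = np.array([l == lab for l in labels])
        if mask.any():
            out[lab] = values[mask]
    return out


def summarize_by_label(
    values: Sequence[float],
    labels: Sequence[Optional[str]],
    units: str = "per_m2",
) -> tuple[dict[str, GroupStats], int]:
    """Group statistics per expert label; unlabelled records are excluded
    and counted separately (second return value)."""
    groups = _group_arrays(values, labels)
    if not groups:
        raise CalibrationError("all records are unlabelled")
    n_unlabelled = sum(1 for l in labels if l not in LABELS)
    stats_out = {
        lab: GroupStats(
            label=lab,
            n=len(v),
            mean=float(np.mean(v)),
            sd=float(np.std(v, ddof=1)) if len(v) > 1 else None,
            min=float(np.min(v)),
            max=float(np.max(v)),
            units=units,
        )
        for lab, v in groups.items()
    }
    return stats_out, n_unlabelled


def _check_anova_groups(groups: dict[str, np.ndarray]) -> None:
    if len(groups) < 2:
        raise CalibrationError("need at least two labelled groups")
    if all(len(v) < 2 for v in groups.values()):
        raise CalibrationError("degenerate: every group has a single value")


def oneway_anova(
    values: Sequence[float], labels: Sequence[Optional[str]]
) -> AnovaResult:
    """One-way fixed-effects ANOVA across the labelled groups.

    F is the ratio of between- to within-group mean squares; p is the upper
    tail of F(k−1, N−k).
    """
    groups = _group_arrays(values, labels)
    _check_anova_groups(groups)
    arrays = list(groups.values())
    k = len(arrays)
    n_total = sum(len(a) for a in arrays)
    f_stat, p = stats.f_oneway(*arrays)
    if math.isnan(f_stat):  # zero variance everywhere -> no effect
        f_stat, p = 0.0, 1.0
    return AnovaResult(
        F=float(f_stat), df_between=k - 1, df_within=n_total - k, p=float(p)
    )


def tukey_hsd(
    values: Sequence[float], labels: Sequence[Optional[str]], alpha: float = 0.05
) -> TukeyResult:
    """Tukey HSD pairwise contrasts with studentized-range adjusted p.

    Unequal group sizes use the Tukey–Kramer form.  Degenerate inputs with
    zero pooled within-group variance get p = 1 for identical means and
    p = 0 for distinct means.
    """
    groups = _group_arrays(values, labels)
    _check_anova_groups(groups)
    names = list(groups)
    arrays = [groups[n] for n in names]
    pooled_var = _pooled_within_variance(arrays)
    pairs = []
    if pooled_var == 0.0:
        for i, j in itertools.combinations(range(len(names)), 2):
            diff = float(np.mean(arrays[j]) - np.mean(arrays[i]))
            pairs.append(TukeyPair(names[i], names[j], diff,
                                   1.0 if diff == 0.0 else 0.0))
        return TukeyResult(tuple(pairs))
    res = stats.tukey_hsd(*arrays)
    for i, j in itertools.combinations(range(len(names)), 2):
        diff = float(np.mean(arrays[j]) - np.mean(arrays[i]))
        pairs.append(TukeyPair(names[i], names[j], diff,
                               float(np.clip(res.pvalue[i, j], 0.0, 1.0))))
    return TukeyResult(tuple(pairs))


def _pooled_within_variance(arrays: list[np.ndarray]) -> float:
    ss = sum(float(np.sum((a - a.mean()) ** 2)) for a in arrays)
    df = sum(len(a) for a in arrays) - len(arrays)
    return ss / df if df > 0 else 0.0


def covariate_regression(
    values: Sequence[float], covariate: Sequence[Optional[float]]
) -> RegressionResult:
    """OLS of a per-image metric on one covariate with a two-sided slope
    t-test; records with missing covariate are dropped and counted."""
    y = np.asarray(values, dtype=float)
    x = np.array([np.nan if c is None else float(c) for c in covariate])
    keep = ~np.isnan(x) & ~np.isnan(y)
    n_dropped = int(len(y) - keep.sum())
    x, y = x[keep], y[keep]
    if len(x) < 3:
        raise CalibrationError("need at least 3 paired observations")
    if np.ptp(x) == 0:
        raise CalibrationError("covariate has zero variance")
    if np.ptp(y) == 0:
        # Constant response: slope exactly 0, no evidence of relationship.
        return RegressionResult(slope=0.0, intercept=float(y[0]), p=1.0,
                                n=len(x), n_dropped=n_dropped)
    fit = stats.linregress(x, y)
    return RegressionResult(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        p=float(fit.pvalue),
        n=len(x),
        n_dropped=n_dropped,
    )


def derive_thresholds(
    values: Sequence[float],
    labels: Sequence[Optional[str]],
    metric: str = "density",
    method: str = "midpoint_means",
    q: float = 0.95,
) -> ThresholdEstimate:
    """Candidate Yes-vs-No threshold for one metric.

    midpoint_means — midpoint of the Yes and No group means;
    no_quantile — the q-th quantile of the No group (lower interpolation);
    min_misclassification — the cut minimizing false-VME + missed-VME over
    observed values, ties broken toward the lower cut.  Maybe records are
    excluded throughout (the contrast is Yes vs No).
    """
    if method not in THRESHOLD_METHODS:
        raise CalibrationError(f"unknown threshold method {method!r}")
    groups = _group_arrays(values, labels)
    yes = groups.get("Yes", np.array([]))
    no = groups.get("No", np.array([]))
    if len(yes) == 0 or len(no) == 0:
        raise CalibrationError("both Yes and No groups must be non-empty")
    if method == "midpoint_means":
        value = (float(yes.mean()) + float(no.mean())) / 2.0
    elif method == "no_quantile":
        value = float(np.quantile(no, q, method="lower"))
    else:
        value = _min_misclassification_cut(yes, no)
    return ThresholdEstimate(metric=metric, method=method, value=value,
                             n_yes=len(yes), n_no=len(no))


def _min_misclassification_cut(yes: np.ndarray, no: np.ndarray) -> float:
    # Classify as VME when value >= cut; candidates are the observed values.
    candidates = np.unique(np.concatenate([yes, no]))
    best_cut, best_err = None, None
    for cut in candidates:  # ascending; ties keep the lower cut
        err = int((no >= cut).sum()) + int((yes < cut).sum())
        if best_err is None or err < best_err:
            best_cut, best_err = float(cut), err
    return best_cut


# ---------------------------------------------------------------------------
# Full report
# ---------------------------------------------------------------------------

@dataclass
class MetricReport:
    metric: str
    summary: dict[str, GroupStats]
    n_unlabelled: int
    anova: Optional[AnovaResult]
    tukey: Optional[TukeyResult]
    thresholds: list[ThresholdEstimate] = field(default_factory=list)


@dataclass
class CalibrationReport:
    n_images_input: int
    n_removed_area_filter: int
    min_area_m2: float
    body: str
    policy: str
    depth_regression: Optional[RegressionResult]
    substrate_regression: Optional[RegressionResult]
    metrics: dict[str, MetricReport]
    n_tests_run: int
    notes: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        def enc(obj):
            if obj is None:
                return None
            if isinstance(obj, (GroupStats, AnovaResult, RegressionResult,
                                ThresholdEstimate, TukeyPair)):
                return asdict(obj)
            if isinstance(obj, TukeyResult):
                return [asdict(p) for p in obj.pairs]
            return obj

        return {
            "n_images_input": self.n_images_input,
            "n_removed_area_filter": self.n_removed_area_filter,
            "n_analyzed": self.n_images_input - self.n_removed_area_filter,
            "min_area_m2": self.min_area_m2,
            "body": self.body,
            "policy": self.policy,
            "n_tests_run": self.n_tests_run,
            "notes": self.notes,
            "depth_regression": enc(self.depth_regression),
            "substrate_regression": enc(self.substrate_regression),
            "metrics": {
                name: {
                    "summary": {l: enc(s) for l, s in m.summary.items()},
                    "n_unlabelled": m.n_unlabelled,
                    "anova": enc(m.anova),
                    "tukey": enc(m.tukey),
                    "thresholds": [enc(t) for t in m.thresholds],
                }
                for name, m in self.metrics.items()
            },
        }

    def to_json(self, path: Union[str, Path], provenance: Optional[dict] = None) -> None:
        payload = self.to_dict()
        if provenance:
            payload = {"provenance": provenance, **payload}
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        path.write_text(json.dumps(payload, indent=2) + "\n", encoding="utf-8")

    def write_tables(self, out_dir: Union[str, Path]) -> None:
        """CSV tables mirroring the summary / ANOVA / Tukey structure."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        summary_rows, anova_rows, tukey_rows, thr_rows = [], [], [], []
        for name, m in self.metrics.items():
            for lab, s in m.summary.items():
                summary_rows.append({"metric": name, **asdict(s)})
            if m.anova:
                anova_rows.append({"metric": name, **asdict(m.anova)})
            if m.tukey:
                for pair in m.tukey.pairs:
                    tukey_rows.append({"metric": name, **asdict(pair)})
            for t in m.thresholds:
                thr_rows.append(asdict(t))
        pd.DataFrame(summary_rows).to_csv(out / "summary_stats.csv", index=False)
        pd.DataFrame(anova_rows).to_csv(out / "anova.csv", index=False)
        pd.DataFrame(tukey_rows).to_csv(out / "tukey_hsd.csv", index=False)
        pd.DataFrame(thr_rows).to_csv(out / "threshold_estimates.csv", index=False)


#: Focal taxa reported individually, in addition to registry groups.
FOCAL_TAXA = ("Alcyonacea", "Scleractinia", "Porifera")


def _metric_vectors(
    table: DensityTable, registry: IndicatorRegistry
) -> dict[str, tuple[np.ndarray, list[Optional[str]]]]:
    labels = [r.label for r in table.records]
    metrics: dict[str, tuple[np.ndarray, list[Optional[str]]]] = {}
    metrics["richness_per_m2"] = (
        np.array([r.richness_density for r in table.records]), labels
    )
    for taxon in FOCAL_TAXA:
        vals = group_density(table, taxon, registry)["density"].to_numpy()
        metrics[taxon] = (vals, labels)
    for grp in (TaxonGroup.CNIDARIA, TaxonGroup.ECHINODERMATA, TaxonGroup.OTHER_TAXA):
        vals = group_density(table, grp, registry)["density"].to_numpy()
        metrics[f"group_{grp.value}"] = (vals, labels)
    metrics["overall_density"] = (
        np.array([r.total_density for r in table.records]), labels
    )
    return metrics


def run_calibration_report(
    dataset: AnnotationDataset,
    registry: IndicatorRegistry,
    body: str = "union",
    policy: str = "qualified_counts",
    min_area_m2: float = 1.0,
    threshold_methods: Sequence[str] = ("midpoint_means",),
    quantile_q: float = 0.95,
) -> CalibrationReport:
    """Run the full calibration sequence on an annotation dataset.

    Order: area filter -> densities -> depth and substrate regressions on
    overall density -> per-metric summaries, ANOVA, Tukey and threshold
    estimates.  Metrics whose labelled groups are too degenerate for a test
    are reported with summaries only.
    """
    table = compute_densities(dataset, registry, body=body, policy=policy,
                              min_area_m2=min_area_m2)
    notes = []
    if table.unresolved_taxa:
        notes.append(f"unresolved taxon columns excluded: {list(table.unresolved_taxa)}")
    notes.append("substrate regression uses percent soft substrate = 100 - percent hard")

    overall = np.array([r.total_density for r in table.records])
    depth = [r.depth_m for r in table.records]
    soft = [None if r.pct_hard_substrate is None else 100.0 - r.pct_hard_substrate
            for r in table.records]

    def safe_regression(cov):
        try:
            return covariate_regression(overall, cov)
        except CalibrationError:
            return None

    depth_reg = safe_regression(depth)
    substrate_reg = safe_regression(soft)

    metrics: dict[str, MetricReport] = {}
    n_tests = sum(r is not None for r in (depth_reg, substrate_reg))
    for name, (vals, labels) in _metric_vectors(table, registry).items():
        try:
            summary, n_unlab = summarize_by_label(vals, labels)
        except CalibrationError:
            continue
        try:
            anova = oneway_anova(vals, labels)
            tukey = tukey_hsd(vals, labels)
            n_tests += 1
        except CalibrationError:
            anova, tukey = None, None
        thresholds = []
        for method in threshold_methods:
            try:
                thresholds.append(
                    derive_thresholds(vals, labels, metric=name, method=method,
                                      q=quantile_q)
                )
            except CalibrationError:
                pass
        metrics[name] = MetricReport(
            metric=name, summary=summary, n_unlabelled=n_unlab,
            anova=anova, tukey=tukey, thresholds=thresholds,
        )

    return CalibrationReport(
        n_images_input=table.n_input,
        n_removed_area_filter=table.n_removed,
        min_area_m2=min_area_m2,
        body=body,
        policy=policy,
        depth_regression=depth_reg,
        substrate_regression=substrate_reg,
        metrics=metrics,
        n_tests_run=n_tests,
        notes=notes,
    )


def label_boxplots(report_table: DensityTable, registry: IndicatorRegistry,
                   out_path: Union[str, Path]) -> None:
    """Boxplots of each focal metric per expert label (optional figure)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    metrics = _metric_vectors(report_table, registry)
    names = ["richness_per_m2", *FOCAL_TAXA, "overall_density"]
    fig, axes = plt.subplots(1, len(names), figsize=(4 * len(names), 4))
    for ax, name in zip(np.atleast_1d(axes), names):
        vals, labels = metrics[name]
        data = [vals[[l == lab for l in labels]] for lab in LABELS]
        ax.boxplot(data, tick_labels=list(LABELS))
        ax.set_title(name)
        ax.set_ylabel("per m²")
    fig.tight_layout()
    fig.savefig(out_path, dpi=120)
    plt.close(fig)
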