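"""Knockout-ground-truth benchmarking of pathway enrichment methods.

The ground truth for a knockout experiment is structural: a pathway is a
true knockout pathway iff its gene set contains the knocked-out gene.
Crossing that label with a method's per-pathway p-values at a significance
level yields TPKO/FPKO/TNKO/FNKO confusion counts; sweeping the level over
every possible p-value yields an ROC curve.  This module computes the
curve, its full and partial AUCs (90-100% specificity and sensitivity
regions, raw and McClish-standardised), the Youden-optimal p-threshold and
the metric set collected there, percentile-bootstrap confidence intervals,
paired curve/statistic comparisons (bootstrap and Venkatraman permutation),
and cross-method/cross-dataset aggregation with paired Wilcoxon tests.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .enrich import adjust_pvalues
from .kgml import PathwayGraph

__all__ = [
    "GroundTruth",
    "ConfusionCounts",
    "ROCCurve",
    "build_ground_truth",
    "classify_confusion",
    "compute_metrics",
    "build_roc",
    "partial_auc",
    "youden_threshold",
    "bootstrap_ci",
    "compare_rocs",
    "aggregate_benchmark",
    "evidence_plot_data",
]

GroundTruth = dict[str, bool]

METRIC_NAMES = [
    "FDR",
    "FPR",
    "FNR",
    "sensitivity",
    "specificity",
    "accuracy",
    "precision",
    "recall",
]


def build_ground_truth(
    collection: Sequence[PathwayGraph], ko_genes: Iterable[str]
) -> GroundTruth:
    """Pathway id -> does the pathway's gene set contain any KO gene."""
    ko = set(ko_genes)
    if not ko:
        raise ValueError("ko_genes must be non-empty")
    truth = {pw.pathway_id: bool(pw.genes & ko) for pw in collection}
    if not any(truth.values()):
        raise ValueError("no positive class: KO gene(s) in no pathway")
    return truth


@dataclass(frozen=True)
class ConfusionCounts:
    """TPKO/FPKO/TNKO/FNKO counts at one significance level."""

    TPKO: int
    FPKO: int
    TNKO: int
    FNKO: int
    alpha: float
    p_field: str = "pG"

    @property
    def total(self) -> int:
        return self.TPKO + self.FPKO + self.TNKO + self.FNKO

    def to_dict(self) -> dict:
        return {
            "TPKO": self.TPKO,
            "FPKO": self.FPKO,
            "TNKO": self.TNKO,
            "FNKO": self.FNKO,
            "alpha": self.alpha,
            "p_field": self.p_field,
        }


def _pvalue_map(
    results: pd.DataFrame | Mapping[str, float], p_field: str
) -> dict[str, float]:
    if isinstance(results, pd.DataFrame):
        return dict(zip(results["pathway_id"], results[p_field].astype(float)))
    return {k: float(v) for k, v in results.items()}


def classify_confusion(
    results: pd.DataFrame | Mapping[str, float],
    truth: GroundTruth,
    alpha: float,
    p_field: str = "pG",
    *,
    missing_p: float = 1.0,
) -> ConfusionCounts:
    """Classify every pathway in the truth set at significance level alpha.

    A pathway is called positive when its p-value is strictly below alpha;
    pathways absent from the results get ``missing_p`` (default 1, i.e.
    never called significant).
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    pmap = _pvalue_map(results, p_field)
    tp = fp = tn = fn = 0
    for pid, is_ko in truth.items():
        p = pmap.get(pid, missing_p)
        if math.isnan(p):
            p = missing_p
        called = p < alpha
        if is_ko and called:
            tp += 1
        elif is_ko:
            fn += 1
        elif called:
            fp += 1
        else:
            tn += 1
    return ConfusionCounts(tp, fp, tn, fn, alpha, p_field)


def compute_metrics(counts: ConfusionCounts) -> dict[str, float]:
    """The rate metrics at one confusion table; 0/0 yields NaN."""

    def ratio(num: int, den: int) -> float:
        return num / den if den else float("nan")

    c = counts
    return {
        "FDR": ratio(c.FPKO, c.FPKO + c.TPKO),
        "FPR": ratio(c.FPKO, c.FPKO + c.TNKO),
        "FNR": ratio(c.FNKO, c.FNKO + c.TPKO),
        "sensitivity": ratio(c.TPKO, c.TPKO + c.FNKO),
        "specificity": ratio(c.TNKO, c.TNKO + c.FPKO),
        "accuracy": ratio(c.TPKO + c.TNKO, c.total),
        "precision": ratio(c.TPKO, c.TPKO + c.FPKO),
        "recall": ratio(c.TPKO, c.TPKO + c.FNKO),
    }


@dataclass
class ROCCurve:
    """An ROC curve over p-value thresholds (smaller p = more positive).

    ``thresholds[i]`` classifies p < thresholds[i] as positive and realises
    the operating point (specificity[i], sensitivity[i]).  The raw
    p-values and labels are kept for bootstrap resampling.
    """

    thresholds: np.ndarray
    specificity: np.ndarray
    sensitivity: np.ndarray
    auc: float
    p: np.ndarray
    labels: np.ndarray

    @property
    def n_positive(self) -> int:
        return int(self.labels.sum())

    @property
    def n_negative(self) -> int:
        return int((~self.labels).sum())


def build_roc(
    results: pd.DataFrame | Mapping[str, float] | np.ndarray,
    truth: GroundTruth | np.ndarray,
    p_field: str = "pG",
    *,
    missing_p: float = 1.0,
) -> ROCCurve:
    """Build the ROC curve of p-values against the knockout ground truth.

    Accepts either a results table plus truth mapping, or raw aligned
    arrays of p-values and boolean labels.  Thresholds are the midpoints
    between consecutive distinct p-values plus -inf/+inf sentinels; AUC is
    the trapezoidal area, which with tied p-values equals the half-weight
    pair-counting concordance.
    """
    if isinstance(truth, dict):
        pmap = _pvalue_map(results, p_field)
        pids = sorted(truth)
        p = np.array([pmap.get(pid, missing_p) for pid in pids], float)
        p = np.where(np.isnan(p), missing_p, p)
        labels = np.array([truth[pid] for pid in pids], bool)
    else:
        p = np.asarray(results, float)
        labels = np.asarray(truth, bool)
    n_pos = int(labels.sum())
    n_neg = int((~labels).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("single-class truth: need both positive and negative pathways")

    distinct = np.unique(p)
    mids = (distinct[:-1] + distinct[1:]) / 2.0
    thresholds = np.concatenate(([-np.inf], mids, [np.inf]))
    # positive call: p < threshold
    pos_p = np.sort(p[labels])
    neg_p = np.sort(p[~labels])
    tp = np.searchsorted(pos_p, thresholds, side="left")
    fp = np.searchsorted(neg_p, thresholds, side="left")
    sens = tp / n_pos
    spec = (n_neg - fp) / n_neg
    fpr = 1.0 - spec
    auc = float(np.trapezoid(sens, fpr))
    return ROCCurve(
        thresholds=thresholds,
        specificity=spec,
        sensitivity=sens,
        auc=auc,
        p=p,
        labels=labels,
    )


def _segment_area(x: np.ndarray, y: np.ndarray, lo: float, hi: float) -> float:
    """Trapezoid area of the piecewise-linear path y(x) restricted to [lo, hi].

    The path is traversed in the given vertex order; x must be monotone
    along the path (non-decreasing or non-increasing)."""
    area = 0.0
    for (x0, y0), (x1, y1) in zip(zip(x[:-1], y[:-1]), zip(x[1:], y[1:])):
        if x1 < x0:
            x0, x1, y0, y1 = x1, x0, y1, y0
        a, b = max(x0, lo), min(x1, hi)
        if b <= a:
            continue
        if x1 == x0:
            continue
        ya = y0 + (y1 - y0) * (a - x0) / (x1 - x0)
        yb = y0 + (y1 - y0) * (b - x0) / (x1 - x0)
        area += 0.5 * (ya + yb) * (b - a)
    return area


def partial_auc(
    curve: ROCCurve, region: str = "SP", *, corrected: bool = False
) -> float:
    """Partial AUC over the 90-100% specificity (SP) or sensitivity (SE) region.

    The raw value is the trapezoid area of the curve restricted to the
    region (in [0, 0.1]); with ``corrected`` it is McClish-standardised to
    0.5*(1 + (pAUC - min)/(max - min)) where min = 0.005 is the chance
    area and max = 0.1 the perfect area, mapping chance to 0.5 and a
    perfect curve to 1.
    """
    lo, hi = 0.9, 1.0
    if region.upper() == "SP":
        x, y = curve.specificity, curve.sensitivity
    elif region.upper() == "SE":
        x, y = curve.sensitivity, curve.specificity
    else:
        raise ValueError("region must be 'SP' or 'SE'")
    raw = _segment_area(x, y, lo, hi)
    if not corrected:
        return raw
    chance = 0.5 * (hi - lo) ** 2  # 0.005: diagonal sens = 1 - spec
    perfect = hi - lo  # 0.1
    return 0.5 * (1.0 + (raw - chance) / (perfect - chance))


def youden_threshold(curve: ROCCurve) -> tuple[float, tuple[float, float]]:
    """The p-threshold maximising specificity + sensitivity.

    Ties resolve to the higher specificity, then the smaller threshold.
    Returns ``(threshold, (specificity, sensitivity))``.
    """
    j = curve.specificity + curve.sensitivity
    best = None
    for i in range(len(j)):
        key = (j[i], curve.specificity[i], -curve.thresholds[i])
        if best is None or key > best[0]:
            best = (key, i)
    i = best[1]
    return float(curve.thresholds[i]), (
        float(curve.specificity[i]),
        float(curve.sensitivity[i]),
    )


def _roc_stat(p: np.ndarray, labels: np.ndarray, target: str):
    curve = build_roc(p, labels)
    if target == "AUC":
        return curve.auc
    if target == "pAUC_SP":
        return partial_auc(curve, "SP")
    if target == "pAUC_SE":
        return partial_auc(curve, "SE")
    if target == "point":
        return youden_threshold(curve)[1]
    raise ValueError(f"unknown target {target!r}")


def bootstrap_ci(
    curve: ROCCurve,
    target: str = "AUC",
    *,
    B: int = 2000,
    seed: int = 0,
    level: float = 0.95,
):
    """Stratified percentile bootstrap CI for an ROC statistic.

    Positives and negatives are resampled separately (class sizes
    preserved).  For ``target='point'`` the CI covers the Youden-point
    specificity and sensitivity separately.
    """
    if B < 200:
        raise ValueError("need at least 200 bootstrap replicates")
    rng = np.random.default_rng(seed)
    pos_idx = np.flatnonzero(curve.labels)
    neg_idx = np.flatnonzero(~curve.labels)
    qs = [100 * (1 - level) / 2, 100 * (1 + level) / 2]
    vals = []
    for _ in range(B):
        pi = rng.choice(pos_idx, size=pos_idx.size, replace=True)
        ni = rng.choice(neg_idx, size=neg_idx.size, replace=True)
        idx = np.concatenate([pi, ni])
        vals.append(_roc_stat(curve.p[idx], curve.labels[idx], target))
    if target == "point":
        arr = np.asarray(vals, float)
        spec_ci = tuple(np.percentile(arr[:, 0], qs))
        sens_ci = tuple(np.percentile(arr[:, 1], qs))
        return spec_ci, sens_ci
    arr = np.asarray(vals, float)
    return tuple(np.percentile(arr, qs))


def _venkatraman_stat(pa: np.ndarray, pb: np.ndarray, labels: np.ndarray) -> float:
    """Integrated absolute difference between the two rank-based curves."""
    n = pa.size
    ra = stats.rankdata(pa)
    rb = stats.rankdata(pb)
    n_pos = labels.sum()
    n_neg = n - n_pos
    total = 0.0
    for k in range(1, n):
        ca = ra <= k  # called positive by curve a at rank cutoff k
        cb = rb <= k
        sens_a = (ca & labels).sum() / n_pos
        sens_b = (cb & labels).sum() / n_pos
        spec_a = (~ca & ~labels).sum() / n_neg
        spec_b = (~cb & ~labels).sum() / n_neg
        total += abs(sens_a - sens_b) + abs(spec_a - spec_b)
    return total


def compare_rocs(
    curve_a: ROCCurve,
    curve_b: ROCCurve,
    *,
    test: str = "bootstrap",
    target: str = "AUC",
    B: int = 2000,
    seed: int = 0,
) -> float:
    """Paired two-sided comparison of two ROC curves on the same truth.

    ``test='bootstrap'``: normal-approximation p-value from the paired
    stratified bootstrap distribution of the target-statistic difference.
    ``test='venkatraman'``: permutation test on the integrated absolute
    difference between the rank-based curves, exchanging the paired
    predictor values within each pathway.
    """
    if not np.array_equal(curve_a.labels, curve_b.labels):
        raise ValueError("curves must share the same truth labels (paired design)")
    labels = curve_a.labels
    pa, pb = curve_a.p, curve_b.p
    rng = np.random.default_rng(seed)
    if test == "bootstrap":
        obs = _roc_stat(pa, labels, target) - _roc_stat(pb, labels, target)
        pos_idx = np.flatnonzero(labels)
        neg_idx = np.flatnonzero(~labels)
        diffs = np.empty(B)
        for i in range(B):
            pi = rng.choice(pos_idx, size=pos_idx.size, replace=True)
            ni = rng.choice(neg_idx, size=neg_idx.size, replace=True)
            idx = np.concatenate([pi, ni])
            diffs[i] = _roc_stat(pa[idx], labels[idx], target) - _roc_stat(
                pb[idx], labels[idx], target
            )
        sd = float(np.std(diffs, ddof=1))
        if sd == 0:
            return 1.0
        z = obs / sd
        return float(2.0 * stats.norm.sf(abs(z)))
    if test == "venkatraman":
        obs = _venkatraman_stat(pa, pb, labels)
        count = 0
        for _ in range(B):
            swap = rng.random(pa.size) < 0.5
            a2 = np.where(swap, pb, pa)
            b2 = np.where(swap, pa, pb)
            if _venkatraman_stat(a2, b2, labels) >= obs:
                count += 1
        return (count + 1) / (B + 1)
    raise ValueError("test must be 'bootstrap' or 'venkatraman'")


def aggregate_benchmark(
    metrics_long: pd.DataFrame,
    *,
    alternative: str = "two-sided",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Cross-dataset, cross-method aggregation with pairwise Wilcoxon tests.

    ``metrics_long`` must have columns (dataset, method, metric, value).
    Returns the long summary table (sorted) and a pairwise paired Wilcoxon
    signed-rank table per metric and method pair.  Zero-difference pairs
    are dropped (signed-rank convention); if every pair is zero the p-value
    is NaN and ``n_effective`` is 0.
    """
    required = {"dataset", "method", "metric", "value"}
    if not required <= set(metrics_long.columns):
        raise ValueError(f"metrics_long needs columns {sorted(required)}")
    methods = sorted(metrics_long["method"].unique())
    datasets = sorted(metrics_long["dataset"].unique())
    if len(methods) < 2 or len(datasets) < 2:
        raise ValueError("need at least 2 methods and 2 datasets")
    summary = metrics_long.sort_values(
        ["metric", "method", "dataset"]
    ).reset_index(drop=True)

    rows = []
    wide = metrics_long.pivot_table(
        index=["metric", "dataset"], columns="method", values="value"
    )
    for metric in sorted(metrics_long["metric"].unique()):
        sub = wide.loc[metric]
        for i, ma in enumerate(methods):
            for mb in methods[i + 1 :]:
                paired = sub[[ma, mb]].dropna()
                d = paired[ma] - paired[mb]
                nz = d[d != 0]
                if len(nz) == 0:
                    p = float("nan")
                else:
                    p = float(
                        stats.wilcoxon(
                            paired[ma],
                            paired[mb],
                            zero_method="wilcox",
                            alternative=alternative,
                        ).pvalue
                    )
                rows.append(
                    {
                        "metric": metric,
                        "method_a": ma,
                        "method_b": mb,
                        "n_effective": int(len(nz)),
                        "p": p,
                    }
                )
    return summary, pd.DataFrame(rows)


def evidence_plot_data(
    results: pd.DataFrame,
    *,
    alpha: float = 0.05,
    correction: str = "BH",
) -> tuple[pd.DataFrame, float | None]:
    """Two-dimensional evidence plot coordinates and the significance line.

    Each topology-method pathway maps to (-ln pNDE, -ln pPERT).  The
    oblique significance line is the locus x + y = -ln c* where c* solves
    c(1 - ln c) = pG*, with pG* the largest raw combined p still
    significant at ``alpha`` after the chosen correction; pathways on or
    above the line are exactly those significant after correction.

    Returns ``(table, intercept)``; intercept is None when nothing is
    significant.
    """
    valid = results.dropna(subset=["pNDE", "pPERT", "pG"]).copy()
    if valid.empty:
        raise ValueError("no topology-method rows with pNDE/pPERT")
    tiny = np.nextafter(0.0, 1.0)
    valid["x"] = -np.log(np.maximum(valid["pNDE"].to_numpy(float), tiny))
    valid["y"] = -np.log(np.maximum(valid["pPERT"].to_numpy(float), tiny))
    adj = adjust_pvalues(valid["pG"], correction)
    valid["significant"] = adj <= alpha
    table = valid[["pathway_id", "x", "y", "pG", "significant"]].reset_index(
        drop=True
    )
    if not valid["significant"].any():
        return table, None
    pg_star = float(valid.loc[valid["significant"], "pG"].max())
    if pg_star >= 1.0:
        return table, 0.0
    c_star = optimize.brentq(
        lambda c: c - c * math.log(c) - pg_star, 1e-300, 1.0 - 1e-15
    )
    return table, float(-math.log(c_star))
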