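"""KO ground truth, confusion metrics, ROC/pAUC/Youden and comparisons."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from kopath.benchmark import (
    ConfusionCounts,
    aggregate_benchmark,
    bootstrap_ci,
    build_ground_truth,
    build_roc,
    classify_confusion,
    compare_rocs,
    compute_metrics,
    evidence_plot_data,
    partial_auc,
    youden_threshold,
)
from kopath.enrich import combine_fisher
from kopath.kgml import PathwayGraph


def _pw(pid, genes):
    return PathwayGraph(
        pathway_id=pid, name=pid, organism="t", genes=frozenset(genes), edges=()
    )


def pair_counting_auc(p, labels):
    """Concordance of (positive, negative) pairs; ties count half."""
    p = np.asarray(p, float)
    labels = np.asarray(labels, bool)
    pos = p[labels]
    neg = p[~labels]
    wins = sum((pp < nn) + 0.5 * (pp == nn) for pp in pos for nn in neg)
    return wins / (len(pos) * len(neg))


class TestGroundTruth:
    def test_counts_on_default_collection(self, default_study):
        truth = build_ground_truth(default_study["collection"], {"syn:1"})
        assert sum(truth.values()) == 21
        assert len(truth) - sum(truth.values()) == 9

    def test_union_semantics_for_multiple_ko_genes(self):
        col = [_pw("A", ["x", "y"]), _pw("B", ["z"]), _pw("C", ["q"])]
        truth = build_ground_truth(col, {"x", "z"})
        assert truth == {"A": True, "B": True, "C": False}

    def test_no_positive_class_error(self):
        with pytest.raises(ValueError, match="no positive"):
            build_ground_truth([_pw("A", ["x"])], {"zz"})

    def test_all_positive_fails_at_roc_stage(self):
        truth = {"A": True, "B": True}
        with pytest.raises(ValueError, match="single-class"):
            build_roc({"A": 0.1, "B": 0.2}, truth)


class TestConfusion:
    def test_all_p_one_nothing_called(self):
        truth = {"A": True, "B": True, "C": False}
        c = classify_confusion({k: 1.0 for k in truth}, truth, 0.05)
        assert (c.TPKO, c.FPKO, c.TNKO, c.FNKO) == (0, 0, 1, 2)

    def test_missing_pathways_default_to_p_one(self):
        truth = {"A": True, "B": False}
        c = classify_confusion({}, truth, 0.05)
        assert (c.TPKO, c.FNKO, c.TNKO, c.FPKO) == (0, 1, 1, 0)

    def test_conservation_across_alphas(self, default_study):
        truth = build_ground_truth(default_study["collection"], {"syn:1"})
        pvals = {pid: 0.01 * i for i, pid in enumerate(sorted(truth))}
        for alpha in (0.001, 0.05, 0.5, 0.99):
            c = classify_confusion(pvals, truth, alpha)
            assert c.total == len(truth)

    def test_metric_formulas(self):
        m = compute_metrics(ConfusionCounts(3, 1, 5, 1, alpha=0.05))
        assert m["FDR"] == pytest.approx(0.25)
        assert m["FPR"] == pytest.approx(1 / 6)
        assert m["FNR"] == pytest.approx(0.25)
        assert m["sensitivity"] == pytest.approx(0.75)
        assert m["specificity"] == pytest.approx(5 / 6)
        assert m["accuracy"] == pytest.approx(0.8)
        assert m["precision"] == pytest.approx(0.75)
        assert m["recall"] == m["sensitivity"]

    def test_zero_over_zero_is_nan(self):
        m = compute_metrics(ConfusionCounts(0, 0, 5, 2, alpha=0.05))
        assert math.isnan(m["FDR"]) and math.isnan(m["precision"])

    def test_perfect_counts(self):
        m = compute_metrics(ConfusionCounts(4, 0, 6, 0, alpha=0.05))
        assert m["accuracy"] == m["precision"] == m["recall"] == 1.0


FOUR_P = np.array([0.001, 0.2, 0.05, 0.5])
FOUR_L = np.array([True, True, False, False])


class TestROC:
    def test_worked_example_auc(self):
        curve = build_roc(FOUR_P, FOUR_L)
        assert curve.auc == pytest.approx(0.75)
        assert curve.auc == pytest.approx(pair_counting_auc(FOUR_P, FOUR_L))

    def test_perfect_separation(self):
        curve = build_roc(np.array([0.01, 0.02, 0.6, 0.9]), FOUR_L)
        assert curve.auc == pytest.approx(1.0)

    def test_all_ties_is_chance(self):
        curve = build_roc(np.full(6, 0.3), np.array([1, 1, 1, 0, 0, 0], bool))
        assert curve.auc == pytest.approx(0.5)

    @pytest.mark.parametrize("seed", range(6))
    def test_trapezoid_equals_pair_counting(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(10, 500))
        labels = rng.random(n) < 0.4
        if labels.all() or not labels.any():
            labels[0] = True
            labels[1] = False
        # coarse grid forces ties so the half-weight convention is exercised
        p = rng.integers(0, 12, n) / 12.0
        curve = build_roc(p, labels)
        assert curve.auc == pytest.approx(pair_counting_auc(p, labels), abs=1e-12)


class TestPartialAUC:
    def test_perfect_curve_geometry(self):
        curve = build_roc(np.array([0.01, 0.02, 0.6, 0.9]), FOUR_L)
        for region in ("SP", "SE"):
            assert partial_auc(curve, region) == pytest.approx(0.1)
            assert partial_auc(curve, region, corrected=True) == pytest.approx(1.0)

    def test_chance_diagonal_geometry(self):
        curve = build_roc(np.full(6, 0.3), np.array([1, 1, 1, 0, 0, 0], bool))
        assert partial_auc(curve, "SP") == pytest.approx(0.005)
        assert partial_auc(curve, "SP", corrected=True) == pytest.approx(0.5)
        assert partial_auc(curve, "SE", corrected=True) == pytest.approx(0.5)

    def test_matches_fine_grid_numeric_integration(self):
        curve = build_roc(FOUR_P, FOUR_L)
        # independent oracle: sample the empirical ROC as a function of
        # specificity on a fine grid and integrate with the trapezoid rule
        spec_grid = np.linspace(0.9, 1.0, 100_001)
        path_spec = curve.specificity[::-1]
        path_sens = curve.sensitivity[::-1]
        sens_interp = np.interp(spec_grid, path_spec, path_sens)
        oracle = float(np.trapezoid(sens_interp, spec_grid))
        assert partial_auc(curve, "SP") == pytest.approx(oracle, abs=1e-6)

    def test_bounded_by_full_auc(self, default_study):
        rng = np.random.default_rng(0)
        labels = rng.random(40) < 0.5
        labels[:2] = [True, False]
        p = rng.random(40)
        curve = build_roc(p, labels)
        assert 0 <= partial_auc(curve, "SP") <= 0.1
        assert partial_auc(curve, "SP") <= curve.auc


class TestYouden:
    def test_perfect_separation_returns_gap_midpoint(self):
        p = np.array([0.01, 0.02, 0.6, 0.9])
        curve = build_roc(p, FOUR_L)
        thr, (spec, sens) = youden_threshold(curve)
        assert (spec, sens) == (1.0, 1.0)
        assert thr == pytest.approx((0.02 + 0.6) / 2)

    def test_tie_resolved_to_higher_specificity(self):
        curve = build_roc(FOUR_P, FOUR_L)
        thr, (spec, sens) = youden_threshold(curve)
        assert spec + sens == pytest.approx(1.5)
        assert spec == 1.0
        assert 0.001 < thr < 0.05

    def test_point_lies_on_curve_and_maximizes_j(self):
        rng = np.random.default_rng(4)
        p = rng.random(30)
        labels = rng.random(30) < 0.5
        labels[:2] = [True, False]
        curve = build_roc(p, labels)
        thr, (spec, sens) = youden_threshold(curve)
        on_curve = any(
            s == spec and t == sens
            for s, t in zip(curve.specificity, curve.sensitivity)
        )
        assert on_curve
        assert spec + sens >= np.max(curve.specificity + curve.sensitivity) - 1e-12


class TestBootstrap:
    def test_degenerate_perfect_separation_ci(self):
        p = np.concatenate([np.full(8, 0.001), np.full(8, 0.9)])
        labels = np.array([True] * 8 + [False] * 8)
        curve = build_roc(p, labels)
        lo, hi = bootstrap_ci(curve, "AUC", B=300, seed=0)
        assert (lo, hi) == (1.0, 1.0)

    def test_coverage_at_known_auc(self):
        """Percentile CI covers the generating AUC in >= 90% of replications.

        Binormal score model with separation tuned to AUC = 0.8
        (mu = sqrt(2) * Phi^-1(0.8)).
        """
        mu = math.sqrt(2) * sps.norm.ppf(0.8)
        rng = np.random.default_rng(123)
        n_pos, n_neg = 40, 40
        covered = 0
        for i in range(100):
            pos = sps.norm.cdf(-rng.normal(mu, 1, n_pos))  # smaller p = positive
            neg = sps.norm.cdf(-rng.normal(0, 1, n_neg))
            p = np.concatenate([pos, neg])
            labels = np.array([True] * n_pos + [False] * n_neg)
            curve = build_roc(p, labels)
            lo, hi = bootstrap_ci(curve, "AUC", B=200, seed=i)
            covered += lo - 1e-9 <= 0.8 <= hi + 1e-9
        assert covered >= 90

    def test_stability_across_replicate_counts(self):
        rng = np.random.default_rng(7)
        p = rng.random(60)
        labels = np.concatenate([rng.random(30) < 0.8, rng.random(30) < 0.2])
        curve = build_roc(p, labels)
        ci_small = bootstrap_ci(curve, "AUC", B=500, seed=1)
        ci_big = bootstrap_ci(curve, "AUC", B=5000, seed=2)
        assert abs(ci_small[0] - ci_big[0]) < 0.02
        assert abs(ci_small[1] - ci_big[1]) < 0.02


class TestCompareROCs:
    def test_curve_against_itself_is_null(self):
        curve = build_roc(FOUR_P, FOUR_L)
        assert compare_rocs(curve, curve, test="bootstrap", B=200, seed=0) == 1.0
        assert compare_rocs(curve, curve, test="venkatraman", B=99, seed=0) == pytest.approx(
            1.0
        )

    def test_two_sided_symmetry(self):
        rng = np.random.default_rng(2)
        labels = np.array([True] * 10 + [False] * 10)
        a = build_roc(rng.random(20), labels)
        b = build_roc(rng.random(20), labels)
        p_ab = compare_rocs(a, b, test="bootstrap", B=300, seed=5)
        p_ba = compare_rocs(b, a, test="bootstrap", B=300, seed=5)
        assert p_ab == pytest.approx(p_ba, abs=0.02)

    def test_unpaired_inputs_rejected(self):
        labels = np.array([True] * 5 + [False] * 5)
        a = build_roc(np.random.default_rng(0).random(10), labels)
        b = build_roc(np.random.default_rng(1).random(10), ~labels)
        with pytest.raises(ValueError, match="paired"):
            compare_rocs(a, b)

    def test_power_against_a_random_method(self):
        """Strong (AUC ~0.95) vs random (AUC ~0.5) detected in >= 90% of runs."""
        mu = math.sqrt(2) * sps.norm.ppf(0.95)
        rng = np.random.default_rng(11)
        wins = 0
        n_pos = n_neg = 20
        labels = np.array([True] * n_pos + [False] * n_neg)
        for i in range(50):
            strong = np.concatenate(
                [sps.norm.cdf(-rng.normal(mu, 1, n_pos)), sps.norm.cdf(-rng.normal(0, 1, n_neg))]
            )
            random_p = rng.random(n_pos + n_neg)
            a = build_roc(strong, labels)
            b = build_roc(random_p, labels)
            wins += compare_rocs(a, b, test="bootstrap", B=200, seed=i) < 0.05
        assert wins >= 45


class TestAggregate:
    @staticmethod
    def _long(values_by_method, metric="AUC"):
        rows = []
        for method, vals in values_by_method.items():
            for i, v in enumerate(vals):
                rows.append(
                    {"dataset": f"d{i}", "method": method, "metric": metric, "value": v}
                )
        return pd.DataFrame(rows)

    def test_identical_vectors_yield_nan_policy(self):
        long = self._long({"A": [0.7, 0.8, 0.9], "B": [0.7, 0.8, 0.9]})
        _, wx = aggregate_benchmark(long)
        assert math.isnan(wx["p"].iloc[0]) and wx["n_effective"].iloc[0] == 0

    def test_dominating_method_exact_one_sided_p(self):
        long = self._long({"A": [0.9, 0.8, 0.85, 0.95, 0.88], "B": [0.7, 0.6, 0.65, 0.75, 0.68]})
        _, wx = aggregate_benchmark(long, alternative="greater")
        assert wx["p"].iloc[0] == pytest.approx(1 / 32)

    def test_summary_row_cardinality(self):
        long = pd.concat(
            [
                self._long({"A": [0.7, 0.8], "B": [0.6, 0.9]}, metric=m)
                for m in ("AUC", "pAUC_SP", "FDR")
            ]
        )
        summary, wx = aggregate_benchmark(long)
        assert len(summary) == 2 * 2 * 3
        assert len(wx) == 3  # one A-vs-B row per metric


class TestEvidencePlot:
    @staticmethod
    def _results(pnde, ppert):
        rows = []
        for i, (a, b) in enumerate(zip(pnde, ppert)):
            rows.append(
                {
                    "pathway_id": f"P{i}",
                    "pNDE": a,
                    "pPERT": b,
                    "pG": combine_fisher(a, b),
                }
            )
        return pd.DataFrame(rows)

    def test_unit_evidence_sits_at_origin(self):
        res = self._results([1.0, 0.001], [1.0, 0.001])
        table, intercept = evidence_plot_data(res, alpha=0.05)
        origin = table[table.pathway_id == "P0"].iloc[0]
        assert origin.x == 0 and origin.y == 0
        assert intercept is not None and origin.x + origin.y < intercept

    def test_line_solves_fisher_threshold_equation(self):
        res = self._results([0.001, 0.01, 0.2, 0.9], [0.002, 0.05, 0.4, 0.8])
        table, intercept = evidence_plot_data(res, alpha=0.05)
        c_star = math.exp(-intercept)
        pg_star = float(table.loc[table.significant, "pG"].max())
        assert c_star - c_star * math.log(c_star) == pytest.approx(pg_star, rel=1e-9)

    def test_significant_points_lie_on_or_above_line(self):
        rng = np.random.default_rng(3)
        res = self._results(rng.uniform(1e-6, 1, 40), rng.uniform(1e-6, 1, 40))
        table, intercept = evidence_plot_data(res, alpha=0.25)
        if intercept is not None:
            sig = table[table.significant]
            assert np.all(sig.x + sig.y >= intercept - 1e-9)
            insig = table[~table.significant]
            assert np.all(insig.x + insig.y < intercept + 1e-9)
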