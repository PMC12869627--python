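"""Metrics, margin/confidence analysis, survival, DDR and enrichment."""

import itertools

import numpy as np
import pytest
from scipy import stats

from pansubnet import (
    ConfusionTable,
    ExpressionMatrix,
    classification_metrics,
    confusion_metrics,
    ddr_composite_score,
    km_logrank,
    margin_confidence_analysis,
    overrepresentation_test,
)
from pansubnet.evaluation import SurvivalRecord, km_survival_at
from pansubnet.model import PredictionResult


def brute_force_auc(y, p):
    """Exhaustive pair counting; ties count one half."""
    pos = [pi for yi, pi in zip(y, p) if yi == 1]
    neg = [pi for yi, pi in zip(y, p) if yi == 0]
    wins = sum(1.0 if a > b else (0.5 if a == b else 0.0)
               for a in pos for b in neg)
    return wins / (len(pos) * len(neg))


class TestClassificationMetrics:
    def test_printed_confusion_arithmetic(self):
        table = ConfusionTable(n_basal=99, err_basal=14, n_classical=90, err_classical=15)
        m = confusion_metrics(table)
        assert m["accuracy"] == pytest.approx(160 / 189)
        assert round(m["accuracy"], 3) == 0.847
        assert m["n_errors"] == 29
        assert m["error_rate_basal"] == pytest.approx(0.141, abs=5e-4)
        assert m["error_rate_classical"] == pytest.approx(0.167, abs=5e-4)

    def test_perfect_classifier(self):
        y = ["basal_like"] * 3 + ["classical"] * 3
        p = [0.9, 0.8, 0.99, 0.1, 0.2, 0.05]
        report, table = classification_metrics(y, p)
        assert report.auc == report.accuracy == report.sensitivity == report.specificity == 1.0
        assert table.n_errors == 0

    def test_auc_matches_brute_force_pair_counting(self, rng):
        y = rng.integers(0, 2, size=20)
        while len(np.unique(y)) < 2:
            y = rng.integers(0, 2, size=20)
        p = np.round(rng.random(20), 1)  # rounding makes ties likely
        labels = ["basal_like" if v else "classical" for v in y]
        report, _ = classification_metrics(labels, p)
        assert report.auc == pytest.approx(brute_force_auc(y, p), abs=1e-12)

    def test_auc_monotone_transform_invariance(self, rng):
        y = ["basal_like"] * 10 + ["classical"] * 10
        p = rng.random(20)
        a1, _ = classification_metrics(y, p)
        a2, _ = classification_metrics(y, 1 / (1 + np.exp(-5 * p)))
        assert a1.auc == pytest.approx(a2.auc)

    def test_balanced_accuracy_identity(self, rng):
        y = ["basal_like"] * 12 + ["classical"] * 8
        p = rng.random(20)
        report, _ = classification_metrics(y, p)
        assert report.balanced_accuracy == pytest.approx(
            (report.sensitivity + report.specificity) / 2)

    def test_confusion_round_trip(self):
        table = ConfusionTable(50, 7, 40, 3)
        m = confusion_metrics(table)
        assert round(table.n_basal * (1 - m["sensitivity"])) == 7
        assert round(table.n_classical * (1 - m["specificity"])) == 3

    def test_single_class_truth_is_error(self):
        with pytest.raises(ValueError, match="single class"):
            classification_metrics(["basal_like"] * 4, [0.5] * 4)


def _pred(p, sid="s"):
    return PredictionResult.from_probability(sid, p, np.ones(1))


class TestMarginAnalysis:
    def test_margin_definition(self):
        assert _pred(0.5).margin == 0.0
        assert _pred(0.9).margin == pytest.approx(0.4)

    def test_high_confidence_error_share(self):
        results = [_pred(p) for p in (0.05, 0.95, 0.5, 0.6)]
        out = margin_confidence_analysis(results, [False, False, False, True])
        assert out["n_errors"] == 3
        assert out["n_high_confidence_errors"] == 2
        assert out["high_confidence_error_share"] == pytest.approx(2 / 3)

    def test_mannwhitney_matches_exact_enumeration(self):
        """Two 5-element vectors: p equals exhaustive enumeration of rank splits."""
        a = [0.41, 0.44, 0.46, 0.48, 0.40]
        b = [0.30, 0.35, 0.28, 0.33, 0.42]
        results = [_pred(0.5 + m) for m in a] + [_pred(0.5 + m) for m in b]
        out = margin_confidence_analysis(results, [True] * 5 + [False] * 5)
        # enumeration oracle: all C(10,5) assignments of the pooled values
        pooled = a + b
        u_obs = sum(1 for x in a for y in b if x > y) \
            + 0.5 * sum(1 for x in a for y in b if x == y)
        count = 0
        total = 0
        for comb in itertools.combinations(range(10), 5):
            grp = [pooled[i] for i in comb]
            rest = [pooled[i] for i in range(10) if i not in comb]
            u = sum(1 for x in grp for y in rest if x > y) \
                + 0.5 * sum(1 for x in grp for y in rest if x == y)
            total += 1
            if abs(u - 12.5) >= abs(u_obs - 12.5) - 1e-12:
                count += 1
        assert out["mannwhitney_p"] == pytest.approx(count / total, abs=1e-9)

    def test_full_margin_definition_flag(self):
        out = margin_confidence_analysis([_pred(0.9), _pred(0.4)], [True, False],
                                         margin_def="full")
        assert out["median_margin_correct"] == pytest.approx(0.8)

    def test_empty_group_skips_test_with_notice(self):
        out = margin_confidence_analysis([_pred(0.9)], [True])
        assert out["mannwhitney_p"] is None
        assert "skipped" in out["note"]


def make_records(times, events, group):
    return [SurvivalRecord(f"{group}{i}", t, e, group)
            for i, (t, e) in enumerate(zip(times, events))]


class TestSurvival:
    def test_hand_product_limit(self):
        """Times (1,2,3), events (1,1,0): S(2) = (1 - 1/3)(1 - 1/2) = 1/3."""
        recs = make_records([1, 2, 3], [1, 1, 0], "a") + \
            make_records([1, 2, 3], [1, 1, 0], "b")
        est = km_logrank(recs, include_censored=True)
        assert km_survival_at(est.groups["a"], 2.0) == pytest.approx(1 / 3)

    def test_identical_groups_null_logrank(self):
        recs = make_records([3, 5, 8, 11], [1, 1, 1, 1], "a") + \
            make_records([3, 5, 8, 11], [1, 1, 1, 1], "b")
        est = km_logrank(recs, include_censored=True)
        assert est.logrank_chi2 == pytest.approx(0.0, abs=1e-10)
        assert est.logrank_p == pytest.approx(1.0)

    def test_no_events_survival_stays_one(self):
        recs = make_records([1, 2], [0, 0], "a") + make_records([1, 2], [1, 1], "b")
        est = km_logrank(recs, include_censored=True)
        assert np.all(est.groups["a"].survival == 1.0)
        assert est.groups["a"].median_os is None  # not reached

    def test_events_only_default_drops_censored(self):
        recs = make_records([1, 2, 50], [1, 1, 0], "a") + \
            make_records([4, 5, 60], [1, 1, 0], "b")
        est = km_logrank(recs)  # events-only
        assert est.groups["a"].n == 2
        assert est.groups["a"].n_events == 2

    def test_km_equals_empirical_survival_without_censoring(self, rng):
        times = rng.exponential(10, size=40)
        recs = make_records(times, np.ones(40, dtype=int), "a") + \
            make_records(rng.exponential(10, size=10), np.ones(10, dtype=int), "b")
        est = km_logrank(recs, include_censored=True)
        g = est.groups["a"]
        for t in [1.0, 5.0, 15.0]:
            assert km_survival_at(g, t) == pytest.approx(np.mean(times > t))

    def test_median_ordering_under_hazard_ratio(self):
        from pansubnet import SurvivalSimConfig, simulate_survival

        recs = simulate_survival(SurvivalSimConfig(n_per_group=200, seed=3))
        est = km_logrank(recs, include_censored=True)
        assert est.groups["basal_like"].median_os < est.groups["classical"].median_os
        lo, hi = est.groups["classical"].median_ci
        assert lo < est.groups["classical"].median_os < hi


class TestDdrScore:
    def test_opposite_gradients_cancel(self):
        m = ExpressionMatrix(["BRCA1", "BRCA2"], ["s1", "s2", "s3"],
                             [[1.0, 2.0, 3.0], [3.0, 2.0, 1.0]], unit="TPM", subset=True)
        scores = ddr_composite_score(m)
        np.testing.assert_allclose(scores.to_numpy(), 0.0, atol=1e-12)

    def test_constant_genes_score_zero(self):
        m = ExpressionMatrix(["ATM"], ["a", "b"], [[2.0, 2.0]], unit="TPM", subset=True)
        with pytest.warns(UserWarning, match="missing"):
            scores = ddr_composite_score(m)
        np.testing.assert_array_equal(scores.to_numpy(), [0.0, 0.0])

    def test_scores_sum_to_zero(self, rng):
        genes = ["BRCA1", "BRCA2", "PALB2", "RAD51", "ATM", "CHEK1", "BG1"]
        m = ExpressionMatrix(genes, [f"s{i}" for i in range(9)],
                             rng.uniform(1, 100, size=(7, 9)), unit="TPM", subset=True)
        assert ddr_composite_score(m).sum() == pytest.approx(0.0, abs=1e-8)

    def test_no_ddr_genes_is_error(self):
        m = ExpressionMatrix(["X"], ["a", "b"], [[1.0, 2.0]], unit="TPM", subset=True)
        with pytest.raises(ValueError, match="DDR"):
            ddr_composite_score(m)


class TestOverrepresentation:
    def test_selected_equals_universe_gives_p_one(self):
        universe = {f"g{i}" for i in range(30)}
        terms = {"t1": {f"g{i}" for i in range(5)}}
        res = overrepresentation_test(universe, terms, universe)
        assert res[0].p == pytest.approx(1.0)

    def test_exact_tail_oracle(self):
        universe = {f"g{i}" for i in range(1000)}
        term = {f"g{i}" for i in range(10)}
        selected = {f"g{i}" for i in range(5)} | {f"g{i}" for i in range(100, 120)}
        res = overrepresentation_test(selected, {"t": term}, universe)
        # direct summation of the hypergeometric tail P(X >= 5)
        tail = sum(stats.hypergeom.pmf(k, 1000, 10, 25) for k in range(5, 11))
        assert res[0].p == pytest.approx(tail, rel=1e-9)
        assert res[0].overlap == 5

    def test_bh_adjustment_monotone(self, rng):
        universe = {f"g{i}" for i in range(200)}
        selected = set(rng.choice(sorted(universe), 20, replace=False))
        terms = {f"t{j}": set(rng.choice(sorted(universe), 15, replace=False))
                 for j in range(8)}
        res = overrepresentation_test(selected, terms, universe)
        assert all(r.p_adjusted >= r.p - 1e-15 for r in res)
        assert [r.p_adjusted for r in res] == sorted(r.p_adjusted for r in res)

    def test_empty_selection_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            overrepresentation_test(set(), {"t": {"a"}}, {"a"})
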