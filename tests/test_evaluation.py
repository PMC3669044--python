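import numpy as np
import pytest
from hypothesis import given, strategies as st

from gosvm import evaluation as ev
from oracles import oracle_gene_precision, oracle_pr, oracle_precision_at_recall

# random PR instances: probabilities may tie, at least one positive label
pr_instances = st.integers(2, 50).flatmap(lambda n: st.tuples(
    st.lists(st.sampled_from([round(0.05 * k, 2) for k in range(1, 20)]),
             min_size=n, max_size=n),
    st.lists(st.sampled_from([1.0, -1.0]), min_size=n, max_size=n)
    .filter(lambda ls: any(l > 0 for l in ls)),
))


class TestPrPoints:
    def test_worked_example(self):
        curve = ev.pr_points([0.9, 0.8, 0.7, 0.6], [1, 1, -1, 1])
        i = list(curve.thresholds).index(0.7)
        assert curve.precision[i] == pytest.approx(2 / 3)
        assert curve.recall[i] == pytest.approx(2 / 3)

    def test_perfect_ranking(self):
        curve = ev.pr_points([0.9, 0.8, 0.2, 0.1], [1, 1, -1, -1])
        assert np.all(curve.precision[curve.thresholds >= 0.8] == 1.0)

    def test_all_probs_equal_single_point(self):
        curve = ev.pr_points([0.5] * 10, [1, 1, -1, -1, -1, -1, -1, -1, -1, -1])
        assert len(curve.thresholds) == 1
        assert curve.precision[0] == pytest.approx(0.2)  # prevalence
        assert curve.recall[0] == 1.0

    def test_no_positives_errors(self):
        with pytest.raises(ValueError):
            ev.pr_points([0.5, 0.4], [-1, -1])

    @given(pr_instances)
    def test_matches_enumeration_oracle(self, inst):
        probs, labels = inst
        curve = ev.pr_points(probs, labels)
        expected = oracle_pr(probs, labels)
        assert len(curve.thresholds) == len(expected)
        for (t, p, r), tt, pp, rr in zip(
                expected, curve.thresholds, curve.precision, curve.recall):
            assert tt == pytest.approx(t)
            assert pp == pytest.approx(p)
            assert rr == pytest.approx(r)


class TestPrecisionAtRecall:
    def test_top_two_positives_reach_one(self):
        # 5 positives among 25, the two best-scored rows are positives:
        # at recall 0.4 (2 of 5) precision 1.0 is attainable
        probs = np.linspace(0.99, 0.1, 25)
        labels = -np.ones(25)
        labels[[0, 1, 10, 15, 20]] = 1
        curve = ev.pr_points(probs, labels)
        assert ev.precision_at_recall(curve, 0.4) == 1.0

    def test_uniform_scores_give_prevalence(self, rng):
        vals = []
        for _ in range(60):
            probs = rng.random(200)
            labels = np.r_[np.ones(40), -np.ones(160)]
            vals.append(ev.precision_at_recall(ev.pr_points(probs, labels), 0.4))
        assert np.mean(vals) == pytest.approx(0.2, abs=0.05)

    def test_perfect_classifier_everywhere(self):
        probs = [0.9, 0.8, 0.3, 0.2]
        labels = [1, 1, -1, -1]
        curve = ev.pr_points(probs, labels)
        for r in (0.2, 0.5, 1.0):
            assert ev.precision_at_recall(curve, r) == 1.0

    def test_non_increasing_in_recall_level(self, rng):
        probs = rng.random(40)
        labels = np.where(rng.random(40) < 0.3, 1.0, -1.0)
        if not (labels > 0).any():
            labels[0] = 1.0
        curve = ev.pr_points(probs, labels)
        vals = [ev.precision_at_recall(curve, r) for r in np.linspace(0.05, 1.0, 20)]
        assert all(a >= b - 1e-12 for a, b in zip(vals, vals[1:]))

    def test_threshold_mode_and_bounds(self):
        curve = ev.pr_points([0.9, 0.8, 0.7, 0.6], [1, -1, 1, -1])
        assert ev.precision_at_recall(curve, 1.0, mode="threshold") == pytest.approx(2 / 3)
        with pytest.raises(ValueError):
            ev.precision_at_recall(curve, 0.0)

    @given(pr_instances, st.sampled_from([0.2, 0.3, 0.4, 0.7, 1.0]))
    def test_matches_enumeration_oracle(self, inst, r):
        probs, labels = inst
        curve = ev.pr_points(probs, labels)
        assert ev.precision_at_recall(curve, r) == pytest.approx(
            oracle_precision_at_recall(probs, labels, r))


class TestVerticalAverage:
    def test_identical_curves_unchanged(self):
        c = ev.pr_points([0.9, 0.5, 0.2], [1, -1, 1])
        grid, avg = ev.vertical_average([c, c, c])
        assert np.allclose(avg, np.interp(grid, c.recall, c.precision))

    def test_two_constant_curves(self):
        c1 = ev.PRCurve(np.array([0.5]), np.array([0.8]), np.array([1.0]))
        c2 = ev.PRCurve(np.array([0.5]), np.array([0.6]), np.array([1.0]))
        _, avg = ev.vertical_average([c1, c2])
        assert np.allclose(avg, 0.7)

    def test_average_bounded_by_fold_curves(self, rng):
        curves = []
        for _ in range(4):
            probs = rng.random(30)
            labels = np.where(rng.random(30) < 0.25, 1.0, -1.0)
            if not (labels > 0).any():
                labels[0] = 1.0
            curves.append(ev.pr_points(probs, labels))
        grid, avg = ev.vertical_average(curves)
        per = np.vstack([np.interp(grid, c.recall, c.precision) for c in curves])
        assert np.all(avg >= per.min(axis=0) - 1e-12)
        assert np.all(avg <= per.max(axis=0) + 1e-12)

    def test_empty_grid_errors(self):
        c = ev.pr_points([0.9, 0.5], [1, -1])
        with pytest.raises(ValueError):
            ev.vertical_average([c, c], grid=np.array([]))


class TestGenePrecision:
    def curve(self):
        return ev.PRCurve(
            thresholds=np.array([0.9, 0.7, 0.5]),
            precision=np.array([1.0, 0.8, 0.6]),
            recall=np.array([0.2, 0.6, 1.0]),
        )

    def test_worked_example(self):
        assert ev.gene_precision(0.75, self.curve()) == 0.8

    def test_above_all_thresholds_gets_curve_max(self):
        assert ev.gene_precision(0.95, self.curve()) == 1.0

    def test_below_all_thresholds_scores_zero(self):
        assert ev.gene_precision(0.3, self.curve()) == 0.0

    def test_monotone_in_probability(self):
        c = self.curve()
        ps = np.linspace(0.01, 0.99, 50)
        scores = [ev.gene_precision(p, c) for p in ps]
        assert all(a <= b + 1e-12 for a, b in zip(scores, scores[1:]))

    def test_probability_domain_enforced(self):
        with pytest.raises(ValueError):
            ev.gene_precision(1.0, self.curve())

    @given(pr_instances, st.floats(0.01, 0.99))
    def test_matches_enumeration_oracle(self, inst, p_gene):
        probs, labels = inst
        curve = ev.pr_points(probs, labels)
        assert ev.gene_precision(p_gene, curve) == pytest.approx(
            oracle_gene_precision(p_gene, probs, labels))


class TestSummarizeCategory:
    def make_inputs(self, rng):
        fold_probs = []
        for _ in range(4):
            probs = rng.random(25)
            labels = np.r_[np.ones(5), -np.ones(20)]
            probs[:5] += 1.0
            probs = probs / probs.max() * 0.99
            fold_probs.append((probs, labels))
        unl = {100 + i: list(rng.uniform(0.05, 0.95, 4)) for i in range(6)}
        return fold_probs, unl

    def test_fold_means_are_arithmetic_means(self, rng):
        fold_probs, unl = self.make_inputs(rng)
        perf, records, curves = ev.summarize_category("GO:T", fold_probs, unl)
        for r, vals in perf.per_fold_prec_at.items():
            assert len(vals) == 4
            assert perf.mean_prec_at[r] == pytest.approx(np.mean(vals))
        for rec in records:
            assert rec.mean_score == pytest.approx(np.mean(rec.per_fold_score))
        assert len(curves) == 4

    def test_within_fold_score_ordering_follows_probability(self, rng):
        """Within a fold, gene precision sorted by probability is
        non-decreasing — confidence tracks the probability estimate."""
        fold_probs, unl = self.make_inputs(rng)
        _, records, curves = ev.summarize_category("GO:T", fold_probs, unl)
        for fold in range(4):
            pairs = sorted((r.per_fold_prob[fold], r.per_fold_score[fold])
                           for r in records)
            scores = [s for _, s in pairs]
            assert all(a <= b + 1e-12 for a, b in zip(scores, scores[1:]))

    def test_incomplete_folds_rejected(self, rng):
        fold_probs, unl = self.make_inputs(rng)
        with pytest.raises(ValueError):
            ev.summarize_category("GO:T", fold_probs[:3], unl)
        bad_unl = {101: [0.5, 0.5, 0.5]}
        with pytest.raises(ValueError):
            ev.summarize_category("GO:T", fold_probs, bad_unl)
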