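"""Decision stump, confusion metrics, ROC/AUC and the split protocol."""

import itertools
import math

import numpy as np
import pytest

from acmkit.screening import (
    ClassificationReport,
    ThresholdRule,
    best_threshold,
    compare_variables,
    evaluate_rule,
    roc_auc,
    split_protocol,
)


def entropy(pos, neg):
    out = 0.0
    n = pos + neg
    for k in (pos, neg):
        if 0 < k < n:
            out -= (k / n) * math.log2(k / n)
    return out


def brute_force_stump(values, labels, positive="B"):
    """Independent exhaustive midpoint enumeration scored by information gain."""
    values = np.asarray(values, float)
    y = np.asarray(labels) == positive
    distinct = sorted(set(values))
    parent = entropy(int(y.sum()), int((~y).sum()))
    best = None
    for a, b in zip(distinct[:-1], distinct[1:]):
        c = (a + b) / 2
        above = values > c
        n_a, n_b = int(above.sum()), int((~above).sum())
        child = (
            n_a * entropy(int((y & above).sum()), int((~y & above).sum()))
            + n_b * entropy(int((y & ~above).sum()), int((~y & ~above).sum()))
        ) / values.size
        gain = parent - child
        agree_gt = ((y & above).sum() + (~y & ~above).sum()) / values.size
        agree_le = ((y & ~above).sum() + (~y & above).sum()) / values.size
        key = (round(gain, 12), round(max(agree_gt, agree_le), 12), -c)
        if best is None or key > best[0]:
            best = (key, c, "gt" if agree_gt >= agree_le else "le")
    return best[1], best[2]


class TestBestThreshold:
    def test_perfect_separation(self):
        rule = best_threshold([1, 2, 8, 9], ["A", "A", "B", "B"], positive_class="B")
        assert rule.cutoff == pytest.approx(5.0)
        assert rule.direction == "gt"
        rep = evaluate_rule(rule, [1, 2, 8, 9], ["A", "A", "B", "B"])
        assert rep.agreement == 1.0

    def test_all_identical_values_rejected(self):
        with pytest.raises(ValueError):
            best_threshold([3, 3, 3, 3], ["A", "B", "A", "B"])

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            best_threshold([1, 2, 3], ["A", "A", "A"])

    def test_interleaved_matches_oracle(self):
        values, labels = [1, 2, 3, 4], ["A", "B", "A", "B"]
        rule = best_threshold(values, labels, positive_class="B")
        c, d = brute_force_stump(values, labels)
        assert rule.cutoff == pytest.approx(c)
        assert rule.direction == d

    @pytest.mark.parametrize("n", [4, 6, 8])
    def test_exhaustive_labelings_match_oracle(self, n):
        # every two-class labeling of fixed value vectors, with and without ties
        for values in (np.arange(n, dtype=float), np.array([0, 0, 1, 2] * (n // 4) + [3] * (n % 4), float)):
            if len(set(values)) < 2:
                continue
            for bits in itertools.product("AB", repeat=n):
                labels = np.array(bits)
                if len(set(bits)) < 2:
                    continue
                rule = best_threshold(values, labels, positive_class="B")
                c, d = brute_force_stump(values, labels)
                assert rule.cutoff == pytest.approx(c), (values, bits)
                assert rule.direction == d, (values, bits)

    @pytest.mark.parametrize("seed", range(20))
    def test_random_data_matches_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 13))
        values = np.round(rng.normal(size=n), 1)
        labels = rng.choice(["A", "B"], size=n)
        if len(set(labels)) < 2 or len(set(values)) < 2:
            return
        rule = best_threshold(values, labels, positive_class="B")
        c, _ = brute_force_stump(values, labels)
        assert rule.cutoff == pytest.approx(c)


class TestClassificationReport:
    def test_published_cpap_confusion_matrix(self):
        # implied matrix from the printed CPAP stump operating point
        rep = ClassificationReport(tp=15, tn=11, fp=4, fn=0, positive_class="pre", negative_class="cpap")
        assert round(100 * rep.agreement, 1) == 86.7
        assert round(100 * rep.ppv, 1) == 78.9
        assert round(100 * rep.sensitivity, 1) == 100.0
        assert round(100 * rep.specificity, 1) == 73.3
        assert round(100 * rep.npv, 1) == 100.0

    def test_perfect_classifier(self):
        rule = best_threshold([1, 2, 8, 9], ["A", "A", "B", "B"], positive_class="B")
        rep = evaluate_rule(rule, [0, 1, 9, 10], ["A", "A", "B", "B"])
        assert rep.sensitivity == rep.specificity == rep.ppv == rep.npv == rep.agreement == 1.0
        assert rep.auc == 1.0

    def test_always_positive_rule(self):
        rule = ThresholdRule("v", -np.inf, "gt", "B", "A")
        labels = ["A"] * 6 + ["B"] * 4
        rep = evaluate_rule(rule, np.arange(10), labels)
        assert rep.sensitivity == 1.0
        assert rep.specificity == 0.0
        assert rep.agreement == pytest.approx(0.4)  # prevalence

    @pytest.mark.parametrize("seed", range(10))
    def test_metric_identities_against_counting(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 40))
        values = rng.normal(size=n)
        labels = rng.choice(["A", "B"], size=n)
        if len(set(labels)) < 2:
            return
        rule = ThresholdRule("v", float(rng.normal()), "gt", "B", "A")
        rep = evaluate_rule(rule, values, labels)
        tp = sum(1 for v, l in zip(values, labels) if l == "B" and v > rule.cutoff)
        fp = sum(1 for v, l in zip(values, labels) if l == "A" and v > rule.cutoff)
        fn = sum(1 for v, l in zip(values, labels) if l == "B" and v <= rule.cutoff)
        tn = n - tp - fp - fn
        assert (rep.tp, rep.fp, rep.tn, rep.fn) == (tp, fp, tn, fn)
        assert rep.agreement == pytest.approx((tp + tn) / n)
        if tp + fp:
            assert rep.ppv == pytest.approx(tp / (tp + fp))

    def test_swapped_orientation(self):
        rep = ClassificationReport(tp=15, tn=11, fp=4, fn=0, positive_class="pre", negative_class="cpap")
        sw = rep.swapped()
        assert sw.sensitivity == rep.specificity
        assert sw.ppv == rep.npv
        assert sw.agreement == rep.agreement


class TestRocAuc:
    def test_perfect_separation(self):
        _, auc = roc_auc([1, 2, 8, 9], ["A", "A", "B", "B"], positive_class="B")
        assert auc == 1.0

    def test_all_tied_values(self):
        _, auc = roc_auc([5, 5, 5, 5], ["A", "B", "A", "B"], positive_class="B")
        assert auc == pytest.approx(0.5)

    def test_roc_shape(self):
        rng = np.random.default_rng(0)
        roc, _ = roc_auc(rng.normal(size=30), rng.choice(["A", "B"], 30), positive_class="B")
        assert tuple(roc[0]) == (0.0, 0.0)
        assert tuple(roc[-1]) == (1.0, 1.0)
        assert (np.diff(roc[:, 0]) >= 0).all() and (np.diff(roc[:, 1]) >= 0).all()

    @pytest.mark.parametrize("seed", range(10))
    def test_trapezoid_equals_pair_counting(self, seed):
        # AUC identity with the two-sample U statistic, ties as one half
        rng = np.random.default_rng(seed)
        values = np.round(rng.normal(size=50), 1)  # rounding forces ties
        labels = rng.choice(["A", "B"], size=50)
        if len(set(labels)) < 2:
            return
        _, auc = roc_auc(values, labels, positive_class="B")
        pos = values[labels == "B"]
        neg = values[labels == "A"]
        wins = sum(1.0 if p > q else 0.5 if p == q else 0.0 for p in pos for q in neg)
        assert auc == pytest.approx(wins / (pos.size * neg.size), abs=1e-12)


class TestSplitProtocol:
    def test_degenerate_protocol_equals_full_fit(self):
        values = [1, 2, 3, 8, 9, 10]
        labels = ["A"] * 3 + ["B"] * 3
        res = split_protocol(values, labels, n_iter=1, train_frac=1.0, seed=0, positive_class="B")
        full = best_threshold(values, labels, positive_class="B")
        assert res.best_rule == full
        assert res.refit_rule == full

    def test_reproducible_from_seed(self):
        rng = np.random.default_rng(4)
        values = rng.normal(size=30)
        labels = np.array(["A"] * 15 + ["B"] * 15)
        a = split_protocol(values, labels, n_iter=20, seed=99, positive_class="B")
        b = split_protocol(values, labels, n_iter=20, seed=99, positive_class="B")
        assert a.best_rule == b.best_rule
        assert a.best_iteration == b.best_iteration
        np.testing.assert_array_equal(a.test_agreements, b.test_agreements)

    def test_best_iteration_is_max_test_agreement(self):
        rng = np.random.default_rng(8)
        values = np.concatenate([rng.normal(0, 1, 20), rng.normal(1.5, 1, 20)])
        labels = np.array(["A"] * 20 + ["B"] * 20)
        res = split_protocol(values, labels, n_iter=50, seed=3, positive_class="B")
        assert res.best_report.agreement == pytest.approx(np.nanmax(res.test_agreements))

    def test_stratified_splits_keep_both_classes(self):
        values = np.arange(10.0)
        labels = np.array(["A"] * 7 + ["B"] * 3)
        res = split_protocol(values, labels, n_iter=30, seed=1, positive_class="B")
        for rec in res.per_iteration:
            assert rec["rule"] is not None
            train = set(rec["train_idx"])
            assert train & set(range(7)) and train & set(range(7, 10))

    def test_well_separated_groups_reach_high_agreement(self):
        # Gaussian means 3 sd apart, n = 30 + 30
        hits = 0
        for protocol_seed in range(20):
            rng = np.random.default_rng(1000 + protocol_seed)
            values = np.concatenate([rng.normal(0, 1, 30), rng.normal(3, 1, 30)])
            labels = np.array(["A"] * 30 + ["B"] * 30)
            res = split_protocol(values, labels, n_iter=100, seed=protocol_seed, positive_class="B")
            if res.best_report.agreement >= 0.90:
                hits += 1
        assert hits >= 19

    def test_class_too_small_rejected(self):
        with pytest.raises(ValueError):
            split_protocol([1, 2, 3], ["A", "A", "B"], positive_class="B")


class TestCompareVariables:
    def test_identical_sequences_degenerate(self):
        res = compare_variables([0.5] * 10, [0.5] * 10)
        assert res.degenerate
        assert res.p_value == 1.0

    def test_constant_shift_highly_significant(self):
        rng = np.random.default_rng(2)
        a = rng.uniform(size=100)
        res = compare_variables(a, a + 0.1)
        assert res.p_value < 0.001

    def test_antisymmetric_differences_not_significant(self):
        a = np.zeros(20)
        b = np.concatenate([np.full(10, 0.1), np.full(10, -0.1)])
        res = compare_variables(a, b)
        assert res.p_value > 0.5
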