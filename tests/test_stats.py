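"""ROC/Youden, Fisher, rank-sum and power machinery."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats as sps

from cgps.stats import (auc_score, contingency_eval, fisher_exact_2x2,
                        power_at, required_sample_size, roc_with_youden,
                        wilcoxon_rank_sum)


def pair_counting_auc(scores, labels):
    """Independent oracle: Σ[s+ > s−] + ½Σ[s+ = s−] over all pairs."""
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


class TestROC:
    def test_separable_scores_give_perfect_operating_point(self):
        res = roc_with_youden([0.1, 0.2, 0.8, 0.9], [0, 0, 1, 1],
                              n_boot=10, seed=0)
        assert res.auc == pytest.approx(1.0)
        assert 0.2 < res.youden_threshold <= 0.8
        assert res.sensitivity == pytest.approx(1.0)
        assert res.specificity == pytest.approx(1.0)
        assert res.accuracy == pytest.approx(1.0)

    def test_roc_points_span_origin_to_one_one(self, rng):
        scores = rng.normal(size=60)
        labels = rng.integers(0, 2, 60)
        labels[:2] = [0, 1]
        res = roc_with_youden(scores, labels, n_boot=5, seed=0)
        assert tuple(res.points[0]) == (0.0, 0.0)
        assert tuple(res.points[-1]) == (1.0, 1.0)

    def test_auc_equals_pair_counting_on_random_score_sets(self, rng):
        for _ in range(60):
            n = int(rng.integers(6, 40))
            # integer scores force ties; mix in continuous sets too
            scores = (rng.integers(0, 6, n).astype(float)
                      if rng.random() < 0.5 else rng.normal(size=n))
            labels = rng.integers(0, 2, n)
            if labels.min() == labels.max():
                labels[0] = 1 - labels[0]
            assert auc_score(scores, labels) == pytest.approx(
                pair_counting_auc(scores, labels), abs=1e-12)

    def test_uninformative_scores_give_auc_near_half(self, rng):
        scores = rng.normal(size=200)
        labels = rng.integers(0, 2, 200)
        labels[:2] = [0, 1]
        assert abs(auc_score(scores, labels) - 0.5) < 0.1

    def test_identical_scores_give_auc_half(self):
        assert auc_score([1.0] * 10, [0, 1] * 5) == pytest.approx(0.5)

    def test_monotone_transform_leaves_auc_and_classification_unchanged(
            self, rng):
        scores = rng.normal(size=50)
        labels = rng.integers(0, 2, 50)
        labels[:2] = [0, 1]
        r1 = roc_with_youden(scores, labels, n_boot=5, seed=3)
        r2 = roc_with_youden(np.exp(scores), labels, n_boot=5, seed=3)
        assert r1.auc == pytest.approx(r2.auc, abs=1e-12)
        np.testing.assert_array_equal(scores > r1.youden_threshold,
                                      np.exp(scores) > r2.youden_threshold)

    def test_bootstrap_cis_contain_point_estimates(self, rng):
        scores = np.concatenate([rng.normal(0, 1, 25), rng.normal(1.5, 1, 25)])
        labels = np.array([0] * 25 + [1] * 25)
        res = roc_with_youden(scores, labels, n_boot=300, seed=1)
        for key, est in (("auc", res.auc),
                         ("threshold", res.youden_threshold),
                         ("sensitivity", res.sensitivity),
                         ("specificity", res.specificity),
                         ("accuracy", res.accuracy)):
            lo, hi = res.ci_95[key]
            assert lo <= est <= hi

    def test_one_class_input_is_an_error(self):
        with pytest.raises(ValueError, match="both classes"):
            roc_with_youden([1.0, 2.0], [1, 1], n_boot=5, seed=0)

    def test_tie_break_is_reproducible_under_seed(self, rng):
        scores = rng.integers(0, 4, 30).astype(float)
        labels = rng.integers(0, 2, 30)
        labels[:2] = [0, 1]
        a = roc_with_youden(scores, labels, n_boot=5, seed=9)
        b = roc_with_youden(scores, labels, n_boot=5, seed=9)
        assert a.youden_threshold == b.youden_threshold


class TestContingency:
    def test_retrospective_split_gives_eighty_percent_event_fraction(self):
        # 10 subjects at/below the cut all stable; 5 above of whom 4 active
        scores = [0.5] * 10 + [2.0] * 5
        events = [False] * 10 + [True] * 4 + [False]
        summ = contingency_eval(scores, events, threshold=1.15)
        assert summ.fractions["above_event"] == (4, 5)
        assert summ.above_event_fraction == pytest.approx(0.80)
        assert summ.fractions["below_event"] == (0, 10)

    def test_boundary_value_counts_as_below(self):
        summ = contingency_eval([1.15, 1.16], [True, True], threshold=1.15)
        assert summ.table[0].sum() == 1  # only the 1.16 subject is above

    def test_fisher_p_matches_hypergeometric_enumeration(self):
        p = fisher_exact_2x2([[4, 1], [0, 10]])
        assert p == pytest.approx(0.00366, abs=5e-5)
        assert p == pytest.approx(enumerate_fisher(4, 1, 0, 10), rel=1e-9)

    def test_degenerate_table_has_p_one(self):
        summ = contingency_eval([0.1, 0.2, 0.3], [False] * 3, threshold=1.0)
        assert summ.fisher_p == pytest.approx(1.0)
        assert summ.fractions["below_event"] == (0, 3)

    def test_empty_records_are_an_error(self):
        with pytest.raises(ValueError, match="no records"):
            contingency_eval([], [], threshold=1.0)


def enumerate_fisher(a, b, c, d):
    """Independent oracle: full hypergeometric enumeration at fixed margins."""
    n = a + b + c + d
    r1, c1 = a + b, a + c
    lo, hi = max(0, r1 + c1 - n), min(r1, c1)
    pmf = {k: sps.hypergeom.pmf(k, n, c1, r1) for k in range(lo, hi + 1)}
    obs = pmf[a]
    return sum(p for p in pmf.values() if p <= obs * (1 + 1e-9))


class TestWilcoxon:
    def test_exact_two_tail_example(self):
        res = wilcoxon_rank_sum([1, 2], [3, 4])
        assert res.mode == "exact"
        assert res.p_value == pytest.approx(2 / 6)

    def test_identical_samples_give_p_one(self):
        res = wilcoxon_rank_sum([1.0, 2.0, 2.0], [1.0, 2.0, 2.0])
        assert res.p_value == pytest.approx(1.0)

    def test_complete_separation_small_n(self):
        # all of x above all of y at n=5 vs 5: the two extreme splits
        res = wilcoxon_rank_sum([6, 7, 8, 9, 10], [1, 2, 3, 4, 5])
        assert res.p_value == pytest.approx(2 / 252)

    def test_exact_mode_matches_value_level_enumeration_with_ties(self, rng):
        for _ in range(25):
            m = int(rng.integers(2, 6))
            n = int(rng.integers(2, 6))
            x = rng.integers(0, 4, m).astype(float)
            y = rng.integers(0, 4, n).astype(float)
            res = wilcoxon_rank_sum(x, y, mode="exact")
            assert res.p_value == pytest.approx(
                brute_force_ranksum_p(x, y), abs=1e-12)

    def test_exact_mode_matches_scipy_exact_without_ties(self, rng):
        for _ in range(25):
            m = int(rng.integers(2, 7))
            n = int(rng.integers(2, 7))
            vals = rng.permutation(np.arange(1.0, m + n + 1))
            x, y = vals[:m], vals[m:]
            ours = wilcoxon_rank_sum(x, y, mode="exact").p_value
            ref = sps.mannwhitneyu(x, y, alternative="two-sided",
                                   method="exact").pvalue
            assert ours == pytest.approx(ref, abs=1e-12)

    def test_normal_approximation_close_to_exact_for_small_samples(self, rng):
        for _ in range(20):
            m = int(rng.integers(3, 7))
            n = int(rng.integers(3, 7))
            x = rng.normal(size=m)
            y = rng.normal(size=n)
            exact = wilcoxon_rank_sum(x, y, mode="exact").p_value
            approx = wilcoxon_rank_sum(x, y, mode="normal").p_value
            assert abs(exact - approx) <= 0.05

    @settings(max_examples=25, deadline=None)
    @given(st.lists(st.integers(-5000, 5000).map(lambda v: v / 100),
                    min_size=2, max_size=5),
           st.lists(st.integers(-5000, 5000).map(lambda v: v / 100),
                    min_size=2, max_size=5))
    def test_invariance_under_common_monotone_transform(self, x, y):
        base = wilcoxon_rank_sum(x, y).p_value
        fx = [np.arcsinh(v) * 2 + 1 for v in x]
        fy = [np.arcsinh(v) * 2 + 1 for v in y]
        assert wilcoxon_rank_sum(fx, fy).p_value == pytest.approx(
            base, abs=1e-12)

    def test_empty_sample_is_an_error(self):
        with pytest.raises(ValueError):
            wilcoxon_rank_sum([], [1.0])


def brute_force_ranksum_p(x, y):
    """Independent oracle via pairwise U counting over all splits."""
    pooled = np.concatenate([x, y])
    m = len(x)

    def u_stat(xs, ys):
        return sum((a > b) + 0.5 * (a == b) for a in xs for b in ys)

    mu = m * len(y) / 2
    obs = abs(u_stat(x, y) - mu)
    hits = total = 0
    for idx in itertools.combinations(range(len(pooled)), m):
        xs = pooled[list(idx)]
        ys = np.delete(pooled, list(idx))
        total += 1
        if abs(u_stat(xs, ys) - mu) >= obs - 1e-9:
            hits += 1
    return hits / total


class TestPower:
    def test_printed_sample_size_for_medium_effect(self):
        n, unrounded = required_sample_size(d=0.5, alpha=0.05, power=0.8)
        assert n == 34          # i.e. "> 33"
        assert unrounded == pytest.approx(33.4, abs=0.1)

    def test_printed_power_at_ten_subjects(self):
        assert power_at(10, 0.5, 0.05) == pytest.approx(0.30, abs=0.01)

    def test_power_increases_with_n_and_effect_size(self):
        ns = [5, 10, 20, 40, 80]
        powers = [power_at(n, 0.5) for n in ns]
        assert all(a < b for a, b in zip(powers, powers[1:]))
        ds = [0.2, 0.4, 0.6, 0.8]
        powers = [power_at(20, d) for d in ds]
        assert all(a < b for a, b in zip(powers, powers[1:]))

    def test_required_n_is_the_smallest_sufficient_integer(self):
        for d, power in ((0.5, 0.8), (0.3, 0.9), (0.8, 0.95)):
            n, _ = required_sample_size(d, 0.05, power)
            assert power_at(n, d) >= power
            assert power_at(n - 1, d) < power

    def test_out_of_range_parameters_rejected(self):
        with pytest.raises(ValueError):
            power_at(1, 0.5)
        with pytest.raises(ValueError):
            power_at(10, -0.2)
        with pytest.raises(ValueError):
            power_at(10, 0.5, alpha=1.5)
        with pytest.raises(ValueError):
            required_sample_size(0.5, power=1.2)
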