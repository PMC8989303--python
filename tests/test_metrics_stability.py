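import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from stablecv.metrics_stability import (AggregateResult, PFIList, aggregate,
                                        auc, fri, fri_bottom_k,
                                        fri_sampling_analysis, logloss,
                                        normalize_importances,
                                        precision_sampling_analysis,
                                        rank_importances,
                                        standardized_ci_width)


def pairwise_auc(y, s):
    """Oracle: exhaustive pair counting."""
    wins = ties = total = 0
    for (yi, si), (yj, sj) in itertools.product(zip(y, s), repeat=2):
        if yi == 1 and yj == 0:
            total += 1
            wins += si > sj
            ties += si == sj
    return (wins + 0.5 * ties) / total


def pfi_from_ranks(ranks):
    """A PFIList whose importance ordering realizes the given ranks."""
    f = len(ranks)
    features = [f"f{i}" for i in range(f)]
    imp = [(f - r + 1) / f for r in ranks]
    return PFIList(features=tuple(features), importances=tuple(imp))


class TestLogloss:
    def test_perfect_prediction(self):
        assert logloss([1, 0], [1.0, 0.0]) < 1e-12

    def test_uninformative(self):
        assert logloss([1, 0], [0.5, 0.5]) == pytest.approx(math.log(2), abs=1e-12)

    def test_hand_computed(self):
        expected = -(math.log(0.9) + math.log(0.8) + math.log(0.7)) / 3
        assert logloss([1, 1, 0], [0.9, 0.8, 0.3]) == pytest.approx(expected, abs=1e-12)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            logloss([], [])


class TestAuc:
    def test_perfect_separation(self):
        assert auc([0, 0, 1, 1], [0.1, 0.2, 0.8, 0.9]) == 1.0

    def test_all_tied(self):
        assert auc([0, 1, 0, 1], [0.3, 0.3, 0.3, 0.3]) == 0.5

    def test_hand_enumerated(self):
        assert auc([1, 0, 1, 0], [0.9, 0.8, 0.7, 0.1]) == 0.75

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            auc([1, 1], [0.2, 0.3])

    def test_oracle_equivalence(self):
        rng = np.random.default_rng(0)
        for _ in range(200):
            n = int(rng.integers(2, 13))
            y = rng.integers(0, 2, n)
            if y.min() == y.max():
                y[0] = 1 - y[0]
            s = rng.choice([0.1, 0.25, 0.5, 0.7, 0.9], n)  # ties likely
            assert auc(y, s) == pytest.approx(pairwise_auc(y, s), abs=1e-12)


class TestAggregate:
    def test_constant_values(self):
        agg = aggregate([0.4, 0.4, 0.4])
        assert agg.mean == pytest.approx(0.4, abs=1e-12)
        assert agg.ci_width == pytest.approx(0.0, abs=1e-12)

    def test_two_values_t_table(self):
        agg = aggregate([0.6, 0.7])
        assert agg.mean == pytest.approx(0.65)
        # t(0.975, df=1) = 12.706..., SE = 0.05
        half = stats.t.ppf(0.975, 1) * 0.05
        assert agg.ci_high - agg.mean == pytest.approx(half, rel=1e-9)
        assert half == pytest.approx(0.635, abs=5e-4)

    def test_coverage(self):
        rng = np.random.default_rng(42)
        hits = 0
        draws = 2000
        for _ in range(draws):
            agg = aggregate(rng.normal(0, 1, 25))
            hits += agg.ci_low <= 0 <= agg.ci_high
        assert 0.93 < hits / draws < 0.97

    def test_too_few(self):
        with pytest.raises(ValueError):
            aggregate([0.5])


class TestStandardizedCiWidth:
    def _agg(self, mean, lo, hi):
        return AggregateResult("m", 3, mean, lo, hi, (mean,) * 3)

    def test_direct_substitution(self):
        assert standardized_ci_width(self._agg(0.5, 0.4875, 0.5125)) == pytest.approx(5.0)

    def test_zero_width(self):
        assert standardized_ci_width(self._agg(0.7, 0.7, 0.7)) == 0.0

    def test_scale_invariance(self):
        a = standardized_ci_width(aggregate([0.5, 0.6, 0.7]))
        b = standardized_ci_width(aggregate([1.0, 1.2, 1.4]))
        assert a == pytest.approx(b, rel=1e-12)

    def test_zero_mean_rejected(self):
        with pytest.raises(ValueError):
            standardized_ci_width(self._agg(0.0, -0.1, 0.1))


class TestFri:
    def test_identity(self):
        p = pfi_from_ranks([1, 2, 3])
        assert fri(p, p) == 0.0

    def test_hand_example(self):
        assert fri(pfi_from_ranks([1, 2, 3]), pfi_from_ranks([2, 1, 3])) == 2.0

    def test_symmetry(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            f = int(rng.integers(2, 10))
            p = pfi_from_ranks(rng.permutation(f) + 1)
            q = pfi_from_ranks(rng.permutation(f) + 1)
            assert fri(p, q) == fri(q, p)

    @pytest.mark.parametrize("f", range(2, 9))
    def test_reversal_maximum(self, f):
        forward = pfi_from_ranks(list(range(1, f + 1)))
        reverse = pfi_from_ranks(list(range(f, 0, -1)))
        expected = f * f / 2 if f % 2 == 0 else (f * f - 1) / 2
        assert fri(forward, reverse) == expected
        # brute force over all permutations: reversal is the maximum
        ref = list(range(1, f + 1))
        brute_max = max(sum(abs(a - b) for a, b in zip(ref, perm))
                        for perm in itertools.permutations(ref))
        assert brute_max == expected

    def test_l1_equivalence_brute_force(self):
        rng = np.random.default_rng(2)
        for _ in range(50):
            f = int(rng.integers(2, 9))
            rp = rng.permutation(f) + 1
            rq = rng.permutation(f) + 1
            assert fri(pfi_from_ranks(rp), pfi_from_ranks(rq)) == \
                sum(abs(int(a) - int(b)) for a, b in zip(rp, rq))

    @settings(max_examples=50, deadline=None)
    @given(st.integers(2, 12), st.integers(0, 10_000))
    def test_triangle_inequality(self, f, seed):
        rng = np.random.default_rng(seed)
        p, q, r = (pfi_from_ranks(rng.permutation(f) + 1) for _ in range(3))
        assert fri(p, r) <= fri(p, q) + fri(q, r) + 1e-12

    def test_shared_subset_reranked(self):
        p = PFIList(("a", "b", "c"), (1.0, 0.6, 0.2))
        q = PFIList(("b", "c", "d"), (1.0, 0.1, 0.5))
        # shared {b, c}: both rank b above c -> 0
        assert fri(p, q) == 0.0

    def test_empty_intersection_rejected(self):
        with pytest.raises(ValueError):
            fri(PFIList(("a",), (1.0,)), PFIList(("b",), (1.0,)))


class TestFriBottomK:
    def test_identical(self):
        p = pfi_from_ranks([1, 2, 3, 4, 5])
        for k in range(1, 6):
            assert fri_bottom_k(p, p, k) == 0.0

    def test_single_term(self):
        # bottom feature moves up 3 ranks, others shift to fill
        p = pfi_from_ranks([1, 2, 3, 4, 5])
        q = pfi_from_ranks([1, 2, 4, 5, 3])  # last feature rises to rank 3
        assert fri_bottom_k(p, q, 1) == 2.0  # |5 - 3|
        p2 = pfi_from_ranks([1, 2, 3, 4])
        q2 = pfi_from_ranks([2, 3, 4, 1])
        assert fri_bottom_k(p2, q2, 1) == 3.0

    def test_k_equals_f_reduces_to_fri(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            f = int(rng.integers(2, 9))
            p = pfi_from_ranks(rng.permutation(f) + 1)
            q = pfi_from_ranks(rng.permutation(f) + 1)
            assert fri_bottom_k(p, q, f) == fri(p, q)

    def test_invalid_k(self):
        p = pfi_from_ranks([1, 2])
        with pytest.raises(ValueError):
            fri_bottom_k(p, p, 0)


class TestRanking:
    def test_ties_break_by_name(self):
        ranks = rank_importances(["b", "a", "c"], [0.5, 0.5, 1.0])
        assert list(ranks) == [3, 2, 1]  # c first, then a (name), then b

    def test_normalization(self):
        pl = normalize_importances(["a", "b"], [-0.2, 0.4])
        assert pl.importances == (0.0, 1.0)

    def test_all_zero_stays_zero(self):
        pl = normalize_importances(["a", "b"], [0.0, -1.0])
        assert pl.importances == (0.0, 0.0)


class TestPrecisionSampling:
    def test_identical_performances_zero_curve(self):
        curve = precision_sampling_analysis([0.6] * 10, n_draws=20, seed=0)
        assert all(abs(m) < 1e-5 for m in curve.means)

    def test_shrinkage_vs_analytic(self):
        rng = np.random.default_rng(5)
        values = rng.normal(0.6, 0.03, 150)
        curve = precision_sampling_analysis(values, n_draws=400, seed=1)
        w2, w25 = curve.value_at(2), curve.value_at(25)
        assert w25 < 0.5 * w2
        # analytic E[width_m] = 2 t_{m-1} c4(m) sigma / (sqrt(m) mu) * 100

        def c4(n):
            return math.sqrt(2 / (n - 1)) * math.gamma(n / 2) / math.gamma((n - 1) / 2)

        def analytic(m):
            return 2 * stats.t.ppf(0.975, m - 1) * c4(m) * 0.03 / (math.sqrt(m) * 0.6) * 100

        assert w25 == pytest.approx(analytic(25), rel=0.08)
        assert w2 == pytest.approx(analytic(2), rel=0.08)

    def test_deterministic_and_order_invariant(self):
        rng = np.random.default_rng(8)
        values = rng.normal(0.5, 0.05, 30)
        a = precision_sampling_analysis(values, n_draws=50, seed=4)
        b = precision_sampling_analysis(values, n_draws=50, seed=4)
        shuffled = values[rng.permutation(30)]
        c = precision_sampling_analysis(shuffled, n_draws=50, seed=4)
        assert a.means == b.means == c.means
        assert a.ci_low == b.ci_low == c.ci_low

    def test_too_few_results(self):
        with pytest.raises(ValueError):
            precision_sampling_analysis([0.5], n_draws=10, seed=0)


class TestFriSampling:
    def _noisy_lists(self, n_projects, f, noise, seed):
        rng = np.random.default_rng(seed)
        truth = np.linspace(1.0, 0.0, f)
        out = []
        for _ in range(n_projects):
            raw = np.maximum(truth + rng.normal(0, noise, f), 0)
            out.append(normalize_importances([f"f{i}" for i in range(f)], raw))
        return out

    def test_shared_list_zero_curve(self):
        pl = PFIList(("a", "b", "c"), (1.0, 0.5, 0.1))
        curve = fri_sampling_analysis([pl] * 8, n_draws=10, seed=0)
        assert all(m == 0 for m in curve.means)

    def test_decreases_with_aggregation(self):
        lists = self._noisy_lists(60, 15, noise=0.25, seed=9)
        curve = fri_sampling_analysis(lists, n_draws=100, seed=2)
        assert curve.value_at(2) > curve.means[-1]
        # roughly monotone decreasing expectation
        first5 = np.mean(curve.means[:5])
        last5 = np.mean(curve.means[-5:])
        assert last5 < 0.5 * first5

    def test_bottom_k_below_full_curve(self):
        lists = self._noisy_lists(30, 10, noise=0.3, seed=10)
        full = fri_sampling_analysis(lists, n_draws=60, seed=3)
        bottom = fri_sampling_analysis(lists, n_draws=60, seed=3, bottom_k=5)
        assert all(b <= f + 1e-12 for b, f in zip(bottom.means, full.means))

    def test_deterministic_and_order_invariant(self):
        lists = self._noisy_lists(20, 8, noise=0.2, seed=11)
        a = fri_sampling_analysis(lists, n_draws=40, seed=5)
        b = fri_sampling_analysis(list(reversed(lists)), n_draws=40, seed=5)
        assert a.means == b.means

    def test_curve_frame_columns(self):
        lists = self._noisy_lists(5, 4, noise=0.1, seed=12)
        frame = fri_sampling_analysis(lists, n_draws=10, seed=0).to_frame()
        assert list(frame.columns) == ["size", "mean", "ci_low", "ci_high"]
        assert frame["size"].tolist() == [2, 3, 4, 5]
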