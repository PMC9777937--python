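"""Splitting simulator: closed forms, brute-force oracles, invariants."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import ks_2samp

from lanesplit.readset import ReadSet
from lanesplit.splitsim import (
    SplitSpec,
    expected_recovery,
    expected_unique,
    mc_unique_counts,
    recovery_ratio,
    split_count_matrix,
    split_counts,
    split_reads,
)


def brute_force_expected_unique(multiplicities, sizes):
    """Enumerate every combination of subsample draws on a tiny instance."""
    items = []
    for i, m in enumerate(multiplicities):
        items.extend([i] * m)
    n = len(items)
    total_p = 0.0
    per_seq_absent = np.zeros(len(multiplicities))
    for s in sizes:
        combos = list(itertools.combinations(range(n), s))
        for i, m in enumerate(multiplicities):
            absent = sum(1 for c in combos if all(items[j] != i for j in c))
            per_seq_absent[i] += math.log(absent / len(combos)) if absent else -math.inf
    return float(np.sum(1.0 - np.exp(per_seq_absent)))


class TestExpectedUnique:
    def test_singleton_closed_form(self):
        # P(lost) = 0.5 * 0.5 for a singleton under a 50-50 two-way split
        m = np.ones(100, dtype=int)
        assert expected_recovery(m, [50, 50]) == pytest.approx(0.75, abs=1e-9)
        assert expected_recovery(m, [90, 10]) == pytest.approx(0.91, abs=1e-9)

    def test_saturated_sequence_always_recovered(self):
        # a sequence holding the whole depth must appear in any draw
        assert expected_unique([50], [10, 1]) == pytest.approx(1.0, abs=1e-12)

    def test_hypergeometric_arithmetic(self):
        # N=4: one sequence with m=2 and two singletons, sizes (2,2)
        # P_absent(m=2) = (C(2,2)/C(4,2))^2 = 1/36 -> contribution 35/36
        val = expected_unique([2, 1, 1], [2, 2])
        assert val == pytest.approx(35 / 36 + 2 * (1 - 0.25), abs=1e-12)

    @pytest.mark.parametrize(
        "mult,sizes",
        [([2, 1, 1], [2, 2]), ([3, 1], [2, 1]), ([1, 1, 1, 1], [2, 2]), ([2, 2], [1, 3])],
    )
    def test_matches_brute_force_enumeration(self, mult, sizes):
        assert expected_unique(mult, sizes) == pytest.approx(
            brute_force_expected_unique(mult, sizes), abs=1e-10
        )

    def test_monotone_decreasing_in_k(self):
        m = np.ones(600, dtype=int)
        vals = [
            expected_unique(m, [600 // k] * k) for k in (2, 3, 4, 5, 10)
        ]
        assert all(a > b for a, b in zip(vals, vals[1:]))

    def test_minimised_at_equal_proportions(self):
        m = np.ones(1000, dtype=int)
        grid = [(int(1000 * p), 1000 - int(1000 * p)) for p in np.arange(0.5, 0.96, 0.05)]
        vals = [expected_unique(m, s) for s in grid]
        assert all(a < b for a, b in zip(vals, vals[1:]))

    def test_oversized_subsample_rejected(self):
        with pytest.raises(ValueError):
            expected_unique([1, 1], [3])


class TestSplitCounts:
    def test_single_sequence_uniqueness_one(self):
        out = split_counts([10], [4, 3])
        assert out[0] == 7

    def test_two_singletons_matches_enumeration(self, rng):
        # sizes (1,1) over two singletons: 4 equally likely draw pairs, so
        # P(seq A drawn at least once) = 3/4 and counts sum to 2 always
        draws = np.array([split_counts([1, 1], [1, 1], np.random.default_rng(s)) for s in range(4000)])
        assert (draws.sum(axis=1) == 2).all()
        p_a_present = (draws[:, 0] > 0).mean()
        assert p_a_present == pytest.approx(0.75, abs=3 * np.sqrt(0.75 * 0.25 / 4000))

    def test_mc_mean_matches_analytic(self, rng):
        m = rng.integers(1, 6, size=50)
        sizes = [int(m.sum() // 3)] * 2
        uniq = mc_unique_counts(m, sizes, 1000, seed=7)
        expect = expected_unique(m, sizes)
        se = uniq.std(ddof=1) / np.sqrt(len(uniq))
        assert abs(uniq.mean() - expect) < 3 * se

    def test_negative_sizes_rejected(self):
        with pytest.raises(ValueError):
            split_counts([1, 1], [-1, 2])

    def test_agrees_with_read_level_distribution(self):
        """split_counts and split_reads give indistinguishable unique counts."""
        seqs = [f"S{i:03d}" for i in range(50)]
        mult = (np.arange(50) % 4) + 1
        gt = ReadSet.from_counts(dict(zip(seqs, mult)))
        sizes = SplitSpec.equal(2).subsample_sizes(gt.n)
        spec = SplitSpec.equal(2, n_iterations=200, seed=5)
        read_level = np.array(
            [split_reads(gt, spec, it).concatenated.n_unique for it in range(200)]
        )
        count_level = mc_unique_counts(mult, sizes, 200, seed=17)
        assert ks_2samp(read_level, count_level).pvalue > 0.01


@settings(max_examples=60, deadline=None, derandomize=True)
@given(
    mult=st.lists(st.integers(1, 8), min_size=2, max_size=30),
    k=st.integers(1, 4),
)
def test_expected_unique_bounds_and_split_penalty(mult, k):
    """E[U] lies in (0, n_distinct]; adding lanes at fixed depth never helps."""
    n = sum(mult)
    sizes_one = [n]
    eu_one = expected_unique(mult, sizes_one)
    assert eu_one == pytest.approx(len(mult))  # one full lane recovers all
    sizes_k = [n // k] * k
    if min(sizes_k) >= 1:
        eu_k = expected_unique(mult, sizes_k)
        assert 0 < eu_k <= len(mult) + 1e-9
        assert eu_k <= eu_one + 1e-9


class TestSplitReads:
    def test_identity_split(self, singleton_reads):
        res = split_reads(singleton_reads, SplitSpec.equal(1, seed=1), 0)
        assert sorted(res.concatenated.sequences) == sorted(singleton_reads.sequences)
        assert recovery_ratio(singleton_reads, res.concatenated) == 1.0

    def test_within_subsample_distinctness(self):
        gt = ReadSet.from_sequences(["A", "B", "C", "D"])
        res = split_reads(gt, SplitSpec.equal(2, seed=9), 0)
        for sub in res.subsamples:
            assert sub.n == 2
            # instance-distinct: no GT record drawn twice within one subsample
            assert len({rid.rsplit("/", 1)[0] for rid in sub.ids}) == 2
        assert res.concatenated.n == 4
        assert 2 <= res.concatenated.n_unique <= 4

    def test_depth_conservation_and_sizes(self, singleton_reads):
        spec = SplitSpec(k=3, proportions=(0.5, 0.3, 0.2), seed=2)
        res = split_reads(singleton_reads, spec, 0)
        assert res.sizes == [500, 300, 200]
        assert res.concatenated.n == singleton_reads.n

    def test_remainder_goes_to_last_subsample(self):
        gt = ReadSet.from_sequences([f"x{i}" for i in range(7)])
        res = split_reads(gt, SplitSpec.equal(2, seed=0), 0)
        assert res.sizes == [3, 4]

    def test_deterministic_per_seed_and_iteration(self, singleton_reads):
        spec = SplitSpec.equal(2, n_iterations=3, seed=4)
        a = split_reads(singleton_reads, spec, 1)
        b = split_reads(singleton_reads, spec, 1)
        c = split_reads(singleton_reads, spec, 2)
        assert a.concatenated.sequences == b.concatenated.sequences
        assert a.concatenated.sequences != c.concatenated.sequences

    def test_mean_recovery_singletons(self, singleton_reads):
        spec = SplitSpec.equal(2, n_iterations=30, seed=8)
        recs = [
            recovery_ratio(singleton_reads, split_reads(singleton_reads, spec, it).concatenated)
            for it in range(30)
        ]
        se = np.std(recs, ddof=1) / np.sqrt(len(recs))
        assert abs(np.mean(recs) - 0.75) < 3 * se

    def test_uneven_split_recovers_more(self, singleton_reads):
        even = SplitSpec(k=2, proportions=(0.5, 0.5), n_iterations=10, seed=3)
        skew = SplitSpec(k=2, proportions=(0.9, 0.1), n_iterations=10, seed=3)
        rec_even = np.mean(
            [split_reads(singleton_reads, even, i).concatenated.n_unique for i in range(10)]
        )
        rec_skew = np.mean(
            [split_reads(singleton_reads, skew, i).concatenated.n_unique for i in range(10)]
        )
        assert rec_even < rec_skew

    def test_degenerate_split_rejected(self):
        gt = ReadSet.from_sequences(["A", "B", "C"])
        with pytest.raises(ValueError, match="degenerate"):
            split_reads(gt, SplitSpec(k=2, proportions=(0.001, 0.999), seed=0), 0)


class TestSplitSpec:
    def test_proportions_must_sum_to_one(self):
        with pytest.raises(ValueError):
            SplitSpec(k=2, proportions=(0.6, 0.6))

    def test_proportion_count_must_match_k(self):
        with pytest.raises(ValueError):
            SplitSpec(k=3, proportions=(0.5, 0.5))


class TestSplitCountMatrix:
    def test_depth_conserved_and_deterministic(self, sc_truth):
        spec = SplitSpec.equal(2, n_iterations=2, seed=6)
        s1 = split_count_matrix(sc_truth.counts, spec, 0)
        s2 = split_count_matrix(sc_truth.counts, spec, 0)
        assert s1.equals(s2)
        assert s1.to_numpy().sum() == sc_truth.counts.to_numpy().sum()
        # splitting can only lose distinct (gene, cell) categories in S
        assert ((s1 > 0) & (sc_truth.counts == 0)).to_numpy().sum() == 0
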