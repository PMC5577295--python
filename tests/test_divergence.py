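import itertools
import math

import numpy as np
import pytest

from barcodegap.distances import DistanceMatrix
from barcodegap.divergence import (
    divergence_summary,
    gap_distributions,
    median_test,
    wilcoxon_two_sample,
)


def dm_from(labels, pairs):
    n = len(labels)
    values = np.zeros((n, n))
    idx = {l: i for i, l in enumerate(labels)}
    for (a, b), v in pairs.items():
        values[idx[a], idx[b]] = values[idx[b], idx[a]] = v
    return DistanceMatrix(list(labels), values)


class TestSummary:
    def test_hand_enumerated_two_species(self):
        # intra {0.01, 0.03}; the four inter pairs all 0.1
        dm = dm_from(
            ["a1", "a2", "b1", "b2"],
            {
                ("a1", "a2"): 0.01, ("b1", "b2"): 0.03,
                ("a1", "b1"): 0.1, ("a1", "b2"): 0.1,
                ("a2", "b1"): 0.1, ("a2", "b2"): 0.1,
            },
        )
        sp = {"a1": "A", "a2": "A", "b1": "B", "b2": "B"}
        s = divergence_summary(dm, sp)
        assert s.mean_intraspecific == pytest.approx(0.02)
        assert s.theta == pytest.approx(0.02)
        assert s.coalescent_depth == pytest.approx(0.03)
        assert s.mean_interspecific == pytest.approx(0.1)
        assert s.theta_prime == pytest.approx(0.1)
        assert s.min_interspecific == pytest.approx(0.1)
        assert (s.n_inter_pairs, s.n_intra_pairs, s.n_undefined_skipped) == (4, 2, 0)

    def test_all_identical_gives_zero_parameters(self):
        dm = dm_from(["a1", "a2", "b1"], {})
        sp = {"a1": "A", "a2": "A", "b1": "B"}
        s = divergence_summary(dm, sp)
        for v in (s.mean_interspecific, s.theta_prime, s.min_interspecific,
                  s.mean_intraspecific, s.theta, s.coalescent_depth):
            assert v == 0.0

    def test_singleton_species_excluded_from_intra(self):
        dm = dm_from(["a1", "b1", "b2"], {("a1", "b1"): 0.2, ("a1", "b2"): 0.2})
        sp = {"a1": "A", "b1": "B", "b2": "B"}
        s = divergence_summary(dm, sp)
        assert s.n_intra_pairs == 1
        assert s.mean_intraspecific == 0.0
        assert s.theta == 0.0

    def test_all_singletons_report_not_available(self):
        dm = dm_from(["a", "b"], {("a", "b"): 0.1})
        s = divergence_summary(dm, {"a": "A", "b": "B"})
        assert s.mean_intraspecific is None
        assert s.theta is None
        assert s.coalescent_depth is None
        assert s.n_intra_pairs == 0

    def test_undefined_pairs_skipped_and_counted(self):
        dm = dm_from(["a1", "a2", "b1"],
                     {("a1", "a2"): np.nan, ("a1", "b1"): 0.1, ("a2", "b1"): 0.2})
        s = divergence_summary(dm, {"a1": "A", "a2": "A", "b1": "B"})
        assert s.n_undefined_skipped == 1
        assert s.mean_intraspecific is None

    def test_invariant_under_relabeling(self):
        rng = np.random.default_rng(1)
        n = 8
        m = np.round(rng.random((n, n)), 3)
        m = (m + m.T) / 2
        np.fill_diagonal(m, 0)
        labels = [f"s{i}" for i in range(n)]
        sp = {l: f"sp{i % 3}" for i, l in enumerate(labels)}
        s1 = divergence_summary(DistanceMatrix(labels, m), sp)
        perm = rng.permutation(n)
        labels2 = [labels[i] for i in perm]
        s2 = divergence_summary(
            DistanceMatrix(labels2, m[np.ix_(perm, perm)]), sp
        )
        for attr in vars(s1):
            assert getattr(s1, attr) == pytest.approx(getattr(s2, attr)), attr

    def test_theta_prime_modes_differ_under_unbalanced_sampling(self):
        dm = dm_from(
            ["a1", "a2", "a3", "b1", "c1"],
            {
                ("a1", "b1"): 0.1, ("a2", "b1"): 0.1, ("a3", "b1"): 0.1,
                ("a1", "c1"): 0.4, ("a2", "c1"): 0.4, ("a3", "c1"): 0.4,
                ("b1", "c1"): 0.1,
            },
        )
        sp = {"a1": "A", "a2": "A", "a3": "A", "b1": "B", "c1": "C"}
        pair_mean = divergence_summary(dm, sp).theta_prime
        all_pairs = divergence_summary(dm, sp, theta_prime_mode="all_pairs").theta_prime
        assert pair_mean == pytest.approx((0.1 + 0.4 + 0.1) / 3)
        assert all_pairs == pytest.approx((3 * 0.1 + 3 * 0.4 + 0.1) / 7)


class TestGapDistributions:
    def test_bin_placement(self):
        dm = dm_from(["a1", "a2", "b1"],
                     {("a1", "a2"): 0.0, ("a1", "b1"): 0.1, ("a2", "b1"): 0.1})
        g = gap_distributions(dm, {"a1": "A", "a2": "A", "b1": "B"}, bin_width=0.05)
        assert g.intra_counts[0] == 1
        assert g.inter_counts[2] == 2
        assert sum(g.intra_counts) == len(g.intra_values)
        assert sum(g.inter_counts) == len(g.inter_values)

    def test_overlap_flag(self):
        dm = dm_from(["a1", "a2", "b1"],
                     {("a1", "a2"): 0.02, ("a1", "b1"): 0.01, ("a2", "b1"): 0.01})
        g = gap_distributions(dm, {"a1": "A", "a2": "A", "b1": "B"}, 0.005)
        assert g.overlap
        dm2 = dm_from(["a1", "a2", "b1"],
                      {("a1", "a2"): 0.01, ("a1", "b1"): 0.3, ("a2", "b1"): 0.3})
        assert not gap_distributions(dm2, {"a1": "A", "a2": "A", "b1": "B"}, 0.005).overlap

    def test_empty_inter_list_allowed(self):
        dm = dm_from(["a1", "a2"], {("a1", "a2"): 0.0})
        g = gap_distributions(dm, {"a1": "A", "a2": "A"}, 0.05)
        assert g.inter_values == []

    def test_nonpositive_bin_width_rejected(self):
        dm = dm_from(["a1", "a2"], {("a1", "a2"): 0.0})
        with pytest.raises(ValueError):
            gap_distributions(dm, {"a1": "A", "a2": "A"}, 0.0)


class TestWilcoxon:
    def test_exact_small_example(self):
        # enumeration of C(4,2)=6 assignments: only {1,2} and {3,4} are extreme
        r = wilcoxon_two_sample([1, 2], [3, 4])
        assert r.method == "exact"
        assert r.p_value == pytest.approx(2 / 6)
        assert r.statistic == 3.0

    def test_exact_unequal_sizes(self):
        # C(5,3)=10 assignments; extremes are rank-sums 6 and 12 -> 2/10
        r = wilcoxon_two_sample([1, 2, 3], [4, 5])
        assert r.p_value == pytest.approx(2 / 10)

    def test_identical_samples_p_one(self):
        r = wilcoxon_two_sample([5, 5, 5], [5, 5, 5])
        assert r.p_value == 1.0

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            wilcoxon_two_sample([], [1.0])

    def test_normal_approximation_close_to_exact(self):
        # largest size where full enumeration is still cheap
        rng = np.random.default_rng(5)
        for _ in range(5):
            a = list(rng.normal(0, 1, 10))
            b = list(rng.normal(0.5, 1, 10))
            exact = wilcoxon_two_sample(a, b)
            approx = wilcoxon_two_sample(a, b, exact_limit=1)
            assert exact.method == "exact"
            assert approx.method == "normal_approximation"
            assert approx.p_value == pytest.approx(exact.p_value, abs=0.02)

    def test_exact_matches_scipy_without_ties(self):
        from scipy.stats import mannwhitneyu

        rng = np.random.default_rng(9)
        for _ in range(10):
            perm = rng.permutation(100).astype(float)
            a = list(perm[:6])
            b = list(perm[6:13])
            ours = wilcoxon_two_sample(a, b)
            ref = mannwhitneyu(a, b, method="exact", alternative="two-sided")
            assert ours.p_value == pytest.approx(ref.pvalue, abs=1e-12)


class TestMedianTest:
    def test_fully_separated_groups(self):
        r = median_test([1, 2, 3], [4, 5, 6])
        assert r.table == [[0, 3], [3, 0]]
        assert r.method == "fisher_exact"
        assert r.p_value == pytest.approx(0.1)

    def test_identical_groups_p_one(self):
        r = median_test([1, 2, 3, 4], [1, 2, 3, 4])
        assert r.p_value == 1.0

    def test_small_sample_takes_fisher_path(self):
        r = median_test([1], [2])
        assert r.method == "fisher_exact"

    def test_large_sample_takes_chi_square_path(self):
        rng = np.random.default_rng(2)
        a = list(rng.normal(0, 1, 60))
        b = list(rng.normal(2, 1, 60))
        r = median_test(a, b)
        assert r.method == "chi_square"
        assert r.p_value < 1e-6

    def test_ties_at_median_count_as_not_above(self):
        # pooled median is 2; the two 2s in group a are "not above"
        r = median_test([2, 2, 5], [1, 1, 3])
        assert r.table[0] == [1, 2]
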