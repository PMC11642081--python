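"""Log-likelihood clustering: costs, distances, agglomeration, k-selection."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from comorbinet import (ClusterSummary, TwoStepCluster, agglomerate,
                        cluster_cost, default_spec, generate, ll_distance,
                        precluster, select_k)

LN2 = np.log(2.0)


def summary(flags):
    return ClusterSummary.from_flags(np.atleast_2d(np.array(flags)))


class TestClusterCost:
    def test_pure_cluster_zero_cost(self):
        assert cluster_cost(summary([[1, 0, 1]] * 5)) == pytest.approx(0.0)

    def test_fair_binary_split_cost(self):
        # two members disagreeing on one attribute: xi = 2 * ln 2
        assert cluster_cost(summary([[0], [1]])) == pytest.approx(2 * LN2)

    def test_merge_of_identical_pure_clusters_stays_pure(self):
        a = summary([[1, 1, 0]] * 3)
        b = summary([[1, 1, 0]] * 4)
        assert cluster_cost(a.merge(b)) == pytest.approx(0.0)

    def test_empty_cluster_rejected(self):
        with pytest.raises(ValueError):
            ClusterSummary(n=0, ones=np.zeros(3))


class TestLLDistance:
    def test_identical_pure_singletons(self):
        assert ll_distance(summary([[1, 0]]), summary([[1, 0]])) == pytest.approx(0.0)

    def test_opposite_singletons(self):
        assert ll_distance(summary([[1]]), summary([[0]])) == pytest.approx(2 * LN2)

    def test_attribute_mismatch_rejected(self):
        with pytest.raises(ValueError):
            ll_distance(summary([[1, 0]]), summary([[1]]))

    @settings(max_examples=50, derandomize=True, deadline=None)
    @given(st.integers(0, 2 ** 31 - 1))
    def test_symmetry_and_superadditivity(self, seed):
        """d(a,b) = d(b,a) >= 0: pooling cannot reduce total entropy cost."""
        rng = np.random.default_rng(seed)
        a = summary((rng.random((rng.integers(1, 9), 6)) < rng.random()).astype(int))
        b = summary((rng.random((rng.integers(1, 9), 6)) < rng.random()).astype(int))
        d_ab, d_ba = ll_distance(a, b), ll_distance(b, a)
        assert d_ab == pytest.approx(d_ba)
        assert d_ab >= -1e-9
        assert cluster_cost(a.merge(b)) >= cluster_cost(a) + cluster_cost(b) - 1e-9


class TestPrecluster:
    def test_zero_threshold_gives_distinct_profiles(self):
        rng = np.random.default_rng(1)
        flags = (rng.random((60, 5)) < 0.4).astype(int)
        leaves = precluster(flags, threshold=0.0)
        n_profiles = len(np.unique(flags, axis=0))
        assert len(leaves) == n_profiles
        assert sum(s.n for s in leaves) == 60

    def test_infinite_threshold_single_leaf(self):
        rng = np.random.default_rng(2)
        flags = (rng.random((40, 5)) < 0.4).astype(int)
        leaves = precluster(flags, threshold=np.inf)
        assert len(leaves) == 1 and leaves[0].n == 40

    def test_leaf_cap_triggers_threshold_doubling(self):
        rng = np.random.default_rng(3)
        flags = (rng.random((200, 10)) < 0.5).astype(int)
        assert len(np.unique(flags, axis=0)) > 16  # zero threshold would overflow
        leaves = precluster(flags, threshold=0.0, max_leaves=16)
        assert 1 <= len(leaves) <= 16
        assert sum(s.n for s in leaves) == 200

    def test_partition_on_planted_cohort(self):
        cohort, _ = generate(default_spec(n=600, seed=21))
        leaves, assign = precluster(cohort.comorbid(1).flags_matrix(),
                                    return_assignments=True)
        sizes = np.bincount(assign)
        assert sizes.sum() == len(cohort.comorbid(1).frame)
        assert all(leaves[i].n == s for i, s in enumerate(sizes) if s)

    def test_max_leaves_below_two_rejected(self):
        with pytest.raises(ValueError):
            precluster(np.zeros((3, 2), int), max_leaves=1)


class TestAgglomerate:
    def test_each_merge_reduces_count_by_one(self):
        rng = np.random.default_rng(5)
        leaves = precluster((rng.random((50, 6)) < 0.4).astype(int))
        res = agglomerate(leaves, J_max=10)
        before = [m[0] for m in res.merge_history]
        assert before == list(range(len(leaves), 1, -1))

    def test_separated_blocks_merge_last(self):
        """Two pure blocks on disjoint diseases join only at the final merge."""
        flags = np.zeros((40, 6), int)
        flags[:20, :3] = 1
        flags[20:, 3:] = 1
        leaves, assign = precluster(flags, return_assignments=True)
        res = agglomerate(leaves, J_max=5)
        rep2 = res.partitions[2][assign]
        assert len(np.unique(rep2[:20])) == 1
        assert len(np.unique(rep2[20:])) == 1
        assert rep2[0] != rep2[-1]

    def test_oracle_equivalence_with_singleton_agglomeration(self):
        """Leader pass at threshold 0 + agglomeration equals agglomerating all
        singleton records directly (record-level oracle)."""
        rng = np.random.default_rng(6)
        flags = (rng.random((120, 5)) < 0.35).astype(int)
        leaves, assign = precluster(flags, threshold=0.0, return_assignments=True)
        res_fast = agglomerate(leaves, J_max=6, n_records=120)
        singletons = [ClusterSummary.from_flags(f) for f in flags]
        res_slow = agglomerate(singletons, J_max=6, n_records=120)
        for J in range(1, 7):
            np.testing.assert_allclose(res_fast.bic_trace[J], res_slow.bic_trace[J],
                                       rtol=1e-12)
            part_fast = res_fast.partitions[J][assign]
            part_slow = res_slow.partitions[J]
            groups_fast = {tuple(np.flatnonzero(part_fast == c))
                           for c in np.unique(part_fast)}
            groups_slow = {tuple(np.flatnonzero(part_slow == c))
                           for c in np.unique(part_slow)}
            assert groups_fast == groups_slow

    def test_needs_two_leaves(self):
        with pytest.raises(ValueError):
            agglomerate([summary([[1, 0]])])


class TestSelectK:
    def test_planted_two_class_cohort_selects_two(self, default_cohort):
        cohort, _ = default_cohort
        res = TwoStepCluster(cohort.comorbid(1), seed=1).fit()
        assert res.k == 2

    def test_single_profile_cohort_selects_one(self, cohort_builder):
        flags = np.tile([1, 0] + [0] * 24, (30, 1))
        res = TwoStepCluster(cohort_builder(flags), seed=0).fit()
        assert res.k == 1

    def test_three_disjoint_blocks_select_three(self):
        rng = np.random.default_rng(9)
        blocks = []
        for b in range(3):
            f = np.zeros((150, 12), int)
            cols = slice(4 * b, 4 * b + 4)
            f[:, cols] = (rng.random((150, 4)) < 0.7).astype(int)
            keep = f.sum(axis=1) > 0
            blocks.append(f[keep])
        flags = np.vstack(blocks)
        res = TwoStepCluster(flags, seed=0).fit()
        assert res.k == 3

    def test_degenerate_trace_returns_one(self):
        assert select_k({1: 100.0, 2: 100.0, 3: 100.0}, {2: 1.0, 3: 1.0}) == 1


class TestFit:
    def test_deterministic_given_seed(self, default_cohort):
        cohort, _ = default_cohort
        sub = cohort.comorbid(1)
        a = TwoStepCluster(sub, seed=4).fit()
        b = TwoStepCluster(sub, seed=4).fit()
        assert a.k == b.k
        assert (a.assignments == b.assignments).all()

    def test_cardiometabolic_profile_coherent(self, default_cohort):
        """The hypertension-rich cluster is also the diabetes-rich cluster."""
        cohort, _ = default_cohort
        res = TwoStepCluster(cohort.comorbid(1), seed=1).fit()
        assert res.k == 2
        hyp = res.profiles["hypertension"]
        dm = res.profiles["diabetes_mellitus"]
        assert hyp.idxmax() == dm.idxmax()

    def test_assignments_cover_all_records(self, default_cohort):
        cohort, _ = default_cohort
        sub = cohort.comorbid(1)
        res = TwoStepCluster(sub, seed=1).fit()
        assert res.assignments.size == len(sub)
        assert set(np.unique(res.assignments)) == set(range(1, res.k + 1))

    def test_profiles_match_cluster_means(self, default_cohort):
        cohort, _ = default_cohort
        sub = cohort.comorbid(1)
        res = TwoStepCluster(sub, seed=1).fit()
        flags = sub.flags_matrix()
        for c in range(1, res.k + 1):
            np.testing.assert_allclose(res.profiles.loc[c].to_numpy(),
                                       flags[res.assignments == c].mean(axis=0))

    def test_summary_mentions_k(self, default_cohort):
        cohort, _ = default_cohort
        res = TwoStepCluster(cohort.comorbid(1), seed=1).fit()
        assert f"selected k: {res.k}" in res.summary()
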