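"""Dirichlet-multinomial likelihood, prior, and incremental move deltas."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import betabinom

import hierbaps as hb
from conftest import random_planted_snp, snp_from_columns
from oracles import (
    exhaustive_map,
    locus_log_ml_oracle,
    partition_log_ml_oracle,
    restricted_growth_partitions,
)


class TestClusterLocusLogMl:
    @pytest.mark.parametrize(
        "counts, alpha, expected",
        [
            ((0, 0), 0.5, 0.0),
            ((1, 1), 0.5, math.log(0.125)),
            ((2, 0), 0.5, math.log(0.375)),
        ],
    )
    def test_hand_derived_values(self, counts, alpha, expected):
        assert hb.cluster_locus_log_ml(counts, alpha) == pytest.approx(expected, abs=1e-12)

    def test_homogeneous_scores_above_split(self):
        # the model's clustering signal: (2,0) likelier than (1,1)
        assert hb.cluster_locus_log_ml((2, 0), 0.5) > hb.cluster_locus_log_ml((1, 1), 0.5)

    @pytest.mark.parametrize("bad", [((-1, 2), 0.5), ((1, 1), 0.0), ((1, 1), -1.0)])
    def test_invalid_arguments(self, bad):
        counts, alpha = bad
        with pytest.raises(ValueError):
            hb.cluster_locus_log_ml(counts, alpha)

    @given(
        st.lists(st.integers(0, 50), min_size=1, max_size=4),
        st.floats(0.05, 5.0),
    )
    @settings(max_examples=100, deadline=None)
    def test_matches_pure_python_oracle(self, counts, alpha):
        ours = hb.cluster_locus_log_ml(counts, alpha)
        assert ours == pytest.approx(locus_log_ml_oracle(counts, alpha), abs=1e-9)
        assert np.isfinite(ours)

    @given(st.integers(0, 30), st.integers(0, 30), st.floats(0.1, 3.0))
    @settings(max_examples=60, deadline=None)
    def test_beta_binomial_limit(self, n1, n2, alpha):
        # for one biallelic locus the marginal is the beta-binomial pmf
        # without the ordering coefficient C(n, n1)
        n = n1 + n2
        expected = betabinom.logpmf(n1, n, alpha, alpha) - (
            math.lgamma(n + 1) - math.lgamma(n1 + 1) - math.lgamma(n2 + 1)
        )
        assert hb.cluster_locus_log_ml((n1, n2), alpha) == pytest.approx(expected, abs=1e-9)


class TestPartitionLogMl:
    def test_additivity_over_clusters(self, twin_pairs_snp):
        snp = twin_pairs_snp
        part = hb.Partition(np.array([1, 1, 2, 2]), k_max=4)
        total = hb.partition_log_ml(snp, part)
        table = hb.AlleleCountTable.from_partition(snp, part)
        alpha = hb.Hyperparameters.from_snp(snp).alpha
        from hierbaps.likelihood import cluster_contributions

        per_cluster = cluster_contributions(table.counts, alpha)
        assert total == pytest.approx(per_cluster.sum(), abs=1e-12)
        assert per_cluster.shape == (2,)

    def test_label_permutation_invariance(self, twin_pairs_snp):
        # the score depends on the set partition, not on which block is "1":
        # permuting the cluster axis of the count table leaves the total fixed
        snp = twin_pairs_snp
        part = hb.Partition(np.array([1, 1, 2, 3]), k_max=4)
        table = hb.AlleleCountTable.from_partition(snp, part)
        alpha = hb.Hyperparameters.from_snp(snp).alpha
        from hierbaps.likelihood import cluster_contributions

        base = cluster_contributions(table.counts, alpha).sum()
        for perm in ([2, 0, 1], [1, 2, 0], [2, 1, 0]):
            permuted = cluster_contributions(table.counts[perm], alpha).sum()
            assert permuted == pytest.approx(base, abs=1e-12)
        assert hb.partition_log_ml(snp, part) == pytest.approx(base, abs=1e-12)

    def test_twin_toy_map_is_two_cluster_split(self, twin_pairs_snp):
        """Exhaustive enumeration of all 15 partitions of 4 items."""
        snp = twin_pairs_snp
        scores = {}
        for labels in restricted_growth_partitions(4, 4):
            part = hb.Partition(labels.copy(), k_max=4)
            scores[tuple(labels)] = hb.partition_log_ml(snp, part)
        assert len(scores) == 15
        best = max(scores, key=scores.get)
        assert best == (1, 1, 2, 2)
        # posterior argmax agrees on this toy
        post = {
            lab: hb.log_posterior(snp, hb.Partition(np.array(lab), k_max=4))
            for lab in scores
        }
        assert max(post, key=post.get) == (1, 1, 2, 2)

    @given(st.integers(0, 2**31 - 2))
    @settings(max_examples=15, deadline=None)
    def test_matches_independent_oracle(self, seed):
        snp, _ = random_planted_snp(seed, n=6, n_loci=10)
        rng = np.random.default_rng(seed)
        labels = hb.Partition.compact(rng.integers(1, 4, size=6))
        part = hb.Partition(labels, k_max=6)
        assert hb.partition_log_ml(snp, part) == pytest.approx(
            partition_log_ml_oracle(snp, labels), abs=1e-9
        )


class TestPrior:
    def test_log_stirling2_known_values(self):
        assert hb.log_stirling2(4, 2) == pytest.approx(math.log(7))
        assert hb.log_stirling2(4, 1) == 0.0
        assert hb.log_stirling2(10, 10) == 0.0

    def test_fixed_k_prior_cancels(self, twin_pairs_snp):
        snp = twin_pairs_snp
        a = hb.Partition(np.array([1, 1, 2, 2]), k_max=3)
        b = hb.Partition(np.array([1, 2, 2, 1]), k_max=3)
        d_post = hb.log_posterior(snp, a) - hb.log_posterior(snp, b)
        d_ml = hb.partition_log_ml(snp, a) - hb.partition_log_ml(snp, b)
        assert d_post == pytest.approx(d_ml, abs=1e-12)

    def test_kmax_one_is_constant_shift(self, twin_pairs_snp):
        part = hb.Partition(np.ones(4, dtype=int), k_max=1)
        shift = hb.log_posterior(twin_pairs_snp, part) - hb.partition_log_ml(
            twin_pairs_snp, part
        )
        assert shift == pytest.approx(-math.log(1) - hb.log_stirling2(4, 1))


class TestMoveDeltas:
    def _state(self, snp, labels, k_max, seed=0):
        part = hb.Partition(np.asarray(labels), k_max=k_max)
        return hb.SearchState.from_partition(snp, part, seed=seed)

    def test_move_and_return_nets_zero(self, twin_pairs_snp):
        state = self._state(twin_pairs_snp, [1, 1, 2, 2], k_max=3)
        d1, empties = hb.delta_log_ml_move(state, 0, 1, 2)
        assert not empties
        hb.apply_move(state, 0, 2)
        d2, _ = hb.delta_log_ml_move(state, 0, 2, 1)  # cluster 1 still exists
        assert d1 + d2 == pytest.approx(0.0, abs=1e-9)

    def test_twin_rejoining_is_favourable(self, twin_pairs_snp):
        # sequence 1 sits alone; moving it onto its identical twin must help
        state = self._state(twin_pairs_snp, [1, 2, 3, 3], k_max=4)
        delta, empties = hb.delta_log_ml_move(state, 1, 2, 1)
        assert empties  # cluster 2 had a sole member
        assert delta >= 0

    def test_sole_member_move_flags_empty_cluster(self, twin_pairs_snp):
        state = self._state(twin_pairs_snp, [1, 2, 3, 3], k_max=4)
        _, empties = hb.delta_log_ml_move(state, 0, 1, 3)
        assert empties
        hb.apply_move(state, 0, 3)
        assert state.k == 2 and list(np.unique(state.labels)) == [1, 2]

    def test_invalid_moves_raise(self, twin_pairs_snp):
        state = self._state(twin_pairs_snp, [1, 1, 2, 2], k_max=2)
        with pytest.raises(ValueError):
            hb.delta_log_ml_move(state, 0, 2, 1)  # wrong source cluster
        with pytest.raises(ValueError):
            hb.delta_log_ml_move(state, 0, 1, 1)  # no-op move
        with pytest.raises(ValueError):
            hb.delta_log_ml_move(state, 0, 1, 3)  # K = K_max, no new cluster

    @given(st.integers(0, 2**31 - 2))
    @settings(max_examples=20, deadline=None)
    def test_delta_equals_full_recomputation(self, seed):
        snp, _ = random_planted_snp(seed, n=8, n_loci=20)
        rng = np.random.default_rng(seed + 1)
        state = self._state(
            snp, hb.Partition.compact(rng.integers(1, 4, size=8)), k_max=5, seed=seed
        )
        for _ in range(25):
            s = int(rng.integers(8))
            f = int(state.labels[s])
            options = [c for c in range(1, state.k + 1) if c != f]
            if state.k < state.k_max and state.cluster_sizes[f - 1] > 1:
                options.append(state.k + 1)
            t = int(rng.choice(options))
            before = state.recompute_log_ml()
            delta, _ = hb.delta_log_ml_move(state, s, f, t)
            hb.apply_move(state, s, t)
            after = state.recompute_log_ml()
            assert delta == pytest.approx(after - before, abs=1e-9)
            assert state.log_ml == pytest.approx(after, abs=1e-9)


class TestExhaustiveOracle:
    @given(st.integers(0, 2**31 - 2))
    @settings(max_examples=8, deadline=None)
    def test_package_scores_agree_with_oracle_over_all_partitions(self, seed):
        snp, _ = random_planted_snp(seed, n=6, n_loci=12)
        k_max = 3
        for labels in restricted_growth_partitions(6, k_max):
            part = hb.Partition(labels.copy(), k_max=k_max)
            assert hb.partition_log_ml(snp, part) == pytest.approx(
                partition_log_ml_oracle(snp, labels), abs=1e-9
            )

    def test_exhaustive_map_on_triples(self, triple_groups_snp):
        labels, score = exhaustive_map(triple_groups_snp, k_max=3)
        assert list(labels) == [1, 1, 1, 2, 2, 2]
        part = hb.Partition(np.array([1, 1, 1, 2, 2, 2]), k_max=3)
        assert score == pytest.approx(
            hb.partition_log_ml(triple_groups_snp, part), abs=1e-9
        )
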