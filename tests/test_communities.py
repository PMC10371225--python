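"""Signed modularity, Leiden optimisation, z-rand consensus, WPGMA."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from sklearn.metrics import adjusted_rand_score

import receptome as rc
from receptome.matrices import SimilarityMatrix

from .oracles import (
    brute_signed_quality,
    exhaustive_pair_null_mean,
    masked_signed_quality,
    pair_count,
    set_partitions,
    wpgma_by_hand,
)


def _sim(values):
    return SimilarityMatrix(values=np.asarray(values, dtype=float))


class TestSignedQuality:
    def test_uniform_positive_single_community_is_zero(self):
        vals = np.full((6, 6), 0.4)
        np.fill_diagonal(vals, 1.0)
        q = rc.signed_quality(_sim(vals), np.zeros(6, dtype=int), gamma=1.0)
        assert q == pytest.approx(0.0, abs=1e-12)

    def test_planted_two_block_beats_single_community(self):
        vals = np.array([
            [1.0, 1.0, -1.0, -1.0],
            [1.0, 1.0, -1.0, -1.0],
            [-1.0, -1.0, 1.0, 1.0],
            [-1.0, -1.0, 1.0, 1.0],
        ])
        planted = np.array([0, 0, 1, 1])
        q_planted = rc.signed_quality(_sim(vals), planted, 1.0)
        q_single = rc.signed_quality(_sim(vals), np.zeros(4, dtype=int), 1.0)
        assert q_planted > q_single
        assert q_planted == pytest.approx(brute_signed_quality(vals, planted, 1.0),
                                          abs=1e-12)

    def test_matches_brute_force_on_random_matrices(self):
        rng = np.random.default_rng(0)
        for trial in range(5):
            vals = rng.uniform(-1, 1, size=(15, 15))
            vals = 0.5 * (vals + vals.T)
            np.fill_diagonal(vals, 1.0)
            labels = rng.integers(0, 4, 15)
            q = rc.signed_quality(_sim(vals), labels, gamma=0.8 + 0.2 * trial)
            assert q == pytest.approx(
                brute_signed_quality(vals, labels, 0.8 + 0.2 * trial), abs=1e-12
            )

    def test_best_partition_matches_exhaustive_enumeration(self):
        rng = np.random.default_rng(3)
        vals = rng.uniform(-1, 1, size=(8, 8))
        vals = 0.5 * (vals + vals.T)
        np.fill_diagonal(vals, 1.0)
        mat = _sim(vals)
        best_q = max(masked_signed_quality(vals, labels, 1.0)
                     for labels in set_partitions(8))
        part = rc.leiden_partition(mat, gamma=1.0, seed=4)
        assert rc.signed_quality(mat, part, 1.0) == pytest.approx(best_q, abs=1e-10)

    def test_all_zero_matrix_rejected(self):
        with pytest.raises(ValueError):
            rc.signed_quality(_sim(np.eye(4)), np.zeros(4, dtype=int))


class TestLeiden:
    def test_recovers_planted_blocks(self, blocks60):
        mat, truth = blocks60
        part = rc.leiden_partition(mat, gamma=1.0, seed=0)
        assert adjusted_rand_score(truth.planted_partition, part.labels) == 1.0

    def test_low_gamma_positive_graph_single_community(self):
        vals = np.full((10, 10), 0.5)
        np.fill_diagonal(vals, 1.0)
        part = rc.leiden_partition(_sim(vals), gamma=1e-3, seed=1)
        assert part.n_communities == 1

    def test_determinism_under_seed(self, blocks60):
        mat, _ = blocks60
        p1 = rc.leiden_partition(mat, gamma=2.0, seed=5)
        p2 = rc.leiden_partition(mat, gamma=2.0, seed=5)
        assert np.array_equal(p1.labels, p2.labels)

    def test_quality_never_decreases_across_phases(self, blocks60):
        mat, _ = blocks60
        for seed in range(5):
            part = rc.leiden_partition(mat, gamma=1.5, seed=seed)
            assert np.all(np.diff(part.quality_history) >= -1e-12)


class TestZRand:
    def test_symmetry_and_self_positivity(self):
        rng = np.random.default_rng(1)
        for _ in range(10):
            p = rng.integers(0, 3, 20)
            q = rng.integers(0, 4, 20)
            assert rc.zrand(p, q) == pytest.approx(rc.zrand(q, p), abs=1e-12)
        p = np.array([0, 0, 1, 1, 2, 2])
        assert rc.zrand(p, p) > 0

    def test_pair_count_and_null_mean_match_exhaustive_enumeration(self):
        from receptome.communities import pair_statistics

        rng = np.random.default_rng(2)
        for _ in range(5):
            p = rng.integers(0, 3, 8)
            q = rng.integers(0, 3, 8)
            w, mu, _ = pair_statistics(p, q)
            assert w == pair_count(p, q)
            assert mu == pytest.approx(exhaustive_pair_null_mean(p, q), abs=1e-9)

    def test_monte_carlo_mean_near_zero(self):
        rng = np.random.default_rng(3)
        zs = [rc.zrand(rng.integers(0, 3, 30), rng.integers(0, 3, 30))
              for _ in range(1000)]
        assert abs(np.mean(zs)) < 0.1

    def test_null_variance_matches_permutation_simulation(self):
        # empirical z over relabelings should be ~standard normal if the
        # analytic mean/variance are right
        rng = np.random.default_rng(4)
        p = rng.integers(0, 3, 60)
        q = rng.integers(0, 3, 60)
        zs = [rc.zrand(p, q[rng.permutation(60)]) for _ in range(2000)]
        assert abs(np.mean(zs)) < 0.1
        assert 0.85 < np.std(zs) < 1.15

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            rc.zrand(np.zeros(5, dtype=int), np.zeros(6, dtype=int))


class TestPartitionEnsemble:
    def test_stated_gamma_grid_sizes(self):
        assert rc.cortical_gamma_grid().size == 191
        assert rc.subcortical_gamma_grid().size == 19

    def test_consensus_attains_max_mean_zrand(self, blocks60):
        mat, _ = blocks60
        ens = rc.partition_ensemble(mat, np.array([1.0]), n_reps=6, seed=0)
        mean = ens.mean_zrand[1.0]
        chosen = ens.consensus[1.0]
        idx = ens.partitions[1.0].index(chosen)
        assert mean[idx] == pytest.approx(mean.max())

    def test_planted_fixture_stable_near_gamma_one(self, blocks60):
        mat, truth = blocks60
        grid = np.array([0.8, 1.0, 1.2])
        ens = rc.partition_ensemble(mat, grid, n_reps=5, seed=1)
        for g in grid:
            assert adjusted_rand_score(truth.planted_partition,
                                       ens.consensus[g].labels) == 1.0
            assert ens.zrand_variance[g] == pytest.approx(0.0, abs=1e-9)

    def test_bad_arguments(self, blocks60):
        mat, _ = blocks60
        with pytest.raises(ValueError):
            rc.partition_ensemble(mat, np.array([]), n_reps=5)
        with pytest.raises(ValueError):
            rc.partition_ensemble(mat, np.array([1.0]), n_reps=1)


class TestModularStability:
    def test_formula_example(self):
        part = rc.Partition(labels=np.array([0, 0, 1, 1, 2, 2, 3, 3]), gamma=1.0)
        roi = np.array([1, 1, 0, 0, 0, 0, 0, 0], dtype=bool)  # inside community 0
        out = rc.modular_stability([part], roi)[0]
        assert out["Cmax"] == 1.0 and out["Cin"] == 1 and out["Ctot"] == 4
        assert out["s"] == 0.25
        assert out["score"] == pytest.approx(0.1875)

    def test_fully_fragmented_roi_scores_zero(self):
        part = rc.Partition(labels=np.array([0, 1, 2, 3]), gamma=1.0)
        out = rc.modular_stability([part], np.ones(4, dtype=bool))[0]
        assert out["score"] == 0.0

    def test_nested_roi_beats_split_roi(self):
        labels = np.concatenate([np.repeat(np.arange(8), 2)])
        part = rc.Partition(labels=labels, gamma=1.0)
        nested = np.zeros(16, dtype=bool)
        nested[:2] = True           # entirely inside one of 8 communities
        split = np.zeros(16, dtype=bool)
        split[[0, 2]] = True        # spread over two communities
        s_nested = rc.modular_stability([part], nested)[0]["score"]
        s_split = rc.modular_stability([part], split)[0]["score"]
        assert s_nested > s_split

    @settings(derandomize=True, max_examples=30)
    @given(st.integers(0, 2**31 - 1))
    def test_relabeling_invariance(self, seed):
        rng = np.random.default_rng(seed)
        labels = rng.integers(0, 5, 30)
        labels = np.unique(labels, return_inverse=True)[1]
        roi = rng.random(30) < 0.4
        if not roi.any():
            roi[0] = True
        part1 = rc.Partition(labels=labels, gamma=1.0)
        perm = rng.permutation(labels.max() + 1)
        relabeled = np.unique(perm[labels], return_inverse=True)[1]
        part2 = rc.Partition(labels=relabeled, gamma=1.0)
        s1 = rc.modular_stability([part1], roi)[0]["score"]
        s2 = rc.modular_stability([part2], roi)[0]["score"]
        assert s1 == pytest.approx(s2, abs=1e-12)

    def test_empty_roi_rejected(self):
        part = rc.Partition(labels=np.zeros(4, dtype=int), gamma=1.0)
        with pytest.raises(ValueError):
            rc.modular_stability([part], np.zeros(4, dtype=bool))


class TestWPGMA:
    def test_two_leaves(self):
        d = rc.wpgma_cluster(np.array([[0.0], [3.0]]))
        assert d.merges.shape == (1, 4)
        assert d.merges[0, 2] == pytest.approx(3.0)

    def test_four_point_line_matches_hand_recursion(self):
        points = np.array([0.0, 1.0, 10.0, 11.0])
        d = rc.wpgma_cluster(points[:, None])
        heights = sorted(d.merges[:, 2])
        assert heights == pytest.approx(sorted(wpgma_by_hand(points)))
        # the two tight pairs merge first, final merge at the WPGMA height 10
        assert d.merges[-1, 2] == pytest.approx(10.0)

    def test_mirrored_hemispheres_merge_first(self):
        rng = np.random.default_rng(5)
        base = rng.standard_normal((5, 19)) * 3
        features = np.vstack([base, base + 0.01 * rng.standard_normal((5, 19))])
        ids = [f"L_{i}" for i in range(5)] + [f"R_{i}" for i in range(5)]
        d = rc.wpgma_cluster(features, ids)
        first_merges = d.merges[:5, :2].astype(int)
        for a, b in first_merges:
            if a < 10 and b < 10:
                assert abs(a - b) == 5  # leaf i merges with its mirror i+5

    def test_heights_non_decreasing_along_root_path(self):
        rng = np.random.default_rng(6)
        d = rc.wpgma_cluster(rng.standard_normal((12, 4)))
        # scipy linkage rows are sorted by merge height for monotone linkages
        assert np.all(np.diff(d.merges[:, 2]) >= -1e-12)

    def test_duplicate_leaf_ids_rejected(self):
        with pytest.raises(ValueError):
            rc.wpgma_cluster(np.zeros((3, 2)), ["a", "a", "b"])
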