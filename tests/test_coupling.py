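"""Consensus builders, MPC, row coupling and class comparisons."""

import numpy as np
import pytest
from scipy.stats import norm

import receptome as rc
from receptome.matrices import SimilarityMatrix

from .oracles import naive_spearman


def _fc(values):
    return SimilarityMatrix(values=np.asarray(values, dtype=float), kind="FC")


class TestConsensusFC:
    def test_two_subject_edge_is_mean_atanh(self):
        a = np.array([[0.0, 0.3], [0.3, 0.0]])
        b = np.array([[0.0, 0.5], [0.5, 0.0]])
        cons = rc.consensus_fc([_fc(a), _fc(b)])
        assert cons.values[0, 1] == pytest.approx(
            (np.arctanh(0.3) + np.arctanh(0.5)) / 2
        )

    def test_zero_matrices_give_zero_consensus(self):
        stack = [_fc(np.zeros((4, 4))) for _ in range(3)]
        assert np.allclose(rc.consensus_fc(stack).values, 0)

    def test_subject_order_invariance(self, geom60):
        stack = rc.simulate_subject_stack(geom60, 5, "FC", seed=1)
        a = rc.consensus_fc(stack)
        b = rc.consensus_fc(stack[::-1])
        assert np.allclose(a.values, b.values)

    def test_back_transform_flag(self):
        a = np.array([[0.0, 0.4], [0.4, 0.0]])
        cons = rc.consensus_fc([_fc(a)], back_transform=True)
        assert cons.values[0, 1] == pytest.approx(0.4)

    def test_perfect_correlation_rejected(self):
        bad = np.array([[0.0, 1.0], [1.0, 0.0]])
        with pytest.raises(ValueError, match="infinite"):
            rc.consensus_fc([_fc(bad)])


class TestConsensusSC:
    def test_single_subject_support_preserved(self, geom60):
        stack = rc.simulate_subject_stack(geom60, 1, "SC", seed=2)
        cons = rc.consensus_sc(stack, geom60.dist)
        iu = np.triu_indices(60, 1)
        assert set(np.where(cons.values[iu] > 0)[0]) <= set(
            np.where(stack[0].values[iu] > 0)[0]
        )

    def test_density_close_to_mean_subject_density(self, geom60):
        stack = rc.simulate_subject_stack(geom60, 10, "SC", seed=3)
        cons = rc.consensus_sc(stack, geom60.dist, n_bins=10)
        iu = np.triu_indices(60, 1)
        mean_edges = np.mean([(m.values[iu] > 0).sum() for m in stack])
        cons_edges = (cons.values[iu] > 0).sum()
        assert abs(cons_edges - mean_edges) / mean_edges < 0.05
        assert abs(cons_edges - mean_edges) <= 10  # <= n_bins rounding bound

    def test_edge_length_distribution_better_than_naive(self, geom60):
        from scipy.stats import ks_2samp

        stack = rc.simulate_subject_stack(geom60, 10, "SC", seed=4)
        iu = np.triu_indices(60, 1)
        d = geom60.dist[iu]
        pooled = np.concatenate([d[m.values[iu] > 0] for m in stack])
        cons = rc.consensus_sc(stack, geom60.dist, n_bins=10)
        log_mean = np.mean([np.log1p(m.values) for m in stack], axis=0)
        k = int(round(np.mean([(m.values[iu] > 0).sum() for m in stack])))
        naive = np.zeros(d.size, dtype=bool)
        naive[np.argsort(log_mean[iu])[::-1][:k]] = True
        ks_cons = ks_2samp(d[cons.values[iu] > 0], pooled).statistic
        ks_naive = ks_2samp(d[naive], pooled).statistic
        assert ks_cons < ks_naive

    def test_shape_mismatch(self, geom60):
        stack = rc.simulate_subject_stack(geom60, 2, "SC", seed=5)
        with pytest.raises(ValueError):
            rc.consensus_sc(stack, np.zeros((10, 10)))


class TestComputeMPC:
    def test_matches_residualise_then_correlate_oracle(self):
        rng = np.random.default_rng(6)
        profiles = rng.standard_normal((10, 14))
        mpc = rc.compute_mpc(profiles, transform="fisherz")
        r_impl = np.tanh(mpc.values)
        mean_prof = profiles.mean(axis=0)
        X = np.column_stack([np.ones(14), mean_prof])
        resid = profiles - (X @ np.linalg.lstsq(X, profiles.T, rcond=None)[0]).T
        r_oracle = np.corrcoef(resid)
        off = ~np.eye(10, dtype=bool)
        assert np.allclose(r_impl[off], r_oracle[off], atol=1e-9)

    def test_identical_profiles_orthogonal_to_mean_are_maximal(self):
        rng = np.random.default_rng(7)
        base = rng.standard_normal(14)
        shared = np.sin(np.linspace(0, 3, 14))
        shared -= shared.mean()
        shared -= shared @ base / (base @ base) * base  # orthogonalise
        profiles = np.vstack([base + shared, base + shared, base - shared,
                              base + 2 * rng.standard_normal(14)])
        mpc = rc.compute_mpc(profiles)
        off = ~np.eye(4, dtype=bool)
        assert mpc.values[0, 1] == pytest.approx(mpc.values[off].max())

    def test_profiles_equal_to_mean_rejected(self):
        profiles = np.tile(np.linspace(0, 1, 14), (3, 1))
        with pytest.raises(ValueError, match="degenerate"):
            rc.compute_mpc(profiles)

    def test_too_few_depths(self):
        with pytest.raises(ValueError):
            rc.compute_mpc(np.zeros((4, 2)))


class TestRowCoupling:
    def test_self_coupling_is_one(self, geom60):
        panel, _ = rc.simulate_density_panel(geom60, 10, 2, 0.2, seed=1)
        m = rc.build_receptome(rc.zscore_panel(panel, "joint"))
        vals = rc.row_coupling(m, m)
        assert np.allclose(vals, 1.0)

    def test_rank_reversing_transform_gives_minus_one(self, geom60):
        panel, _ = rc.simulate_density_panel(geom60, 10, 2, 0.2, seed=2)
        m = rc.build_receptome(rc.zscore_panel(panel, "joint"))
        neg = SimilarityMatrix(values=-m.values, row_ids=list(m.row_ids))
        assert np.allclose(rc.row_coupling(m, neg), -1.0)

    def test_matches_per_row_oracle(self):
        rng = np.random.default_rng(8)
        a = rng.standard_normal((20, 20))
        b = rng.standard_normal((20, 20))
        vals = rc.row_coupling(SimilarityMatrix(values=a), SimilarityMatrix(values=b))
        for i in range(20):
            mask = np.ones(20, dtype=bool)
            mask[i] = False
            assert vals[i] == pytest.approx(naive_spearman(a[i, mask], b[i, mask]),
                                            abs=1e-12)

    def test_sparse_row_yields_nan_with_warning(self):
        a = np.ones((5, 5)) - np.eye(5)
        b = np.zeros((5, 5))
        b[0, 1] = 1.0
        with pytest.warns(UserWarning, match="shared"):
            vals = rc.row_coupling(SimilarityMatrix(values=a),
                                   SimilarityMatrix(values=b, symmetric=False))
        assert np.isnan(vals[2])


class TestClassComparison:
    def test_disjoint_groups_match_hand_formula(self):
        values = np.array([1.0, 2.0, 3.0, 10.0, 11.0, 12.0])
        atlas = rc.ClassAtlas(labels=np.array(["a"] * 3 + ["b"] * 3))
        res = rc.class_comparison(values, atlas)
        # ranks 1-3 vs 4-6: h = 12/(N(N+1)) * sum n_i (Rbar_i - (N+1)/2)^2
        h_hand = 12 / (6 * 7) * (3 * (2 - 3.5) ** 2 + 3 * (5 - 3.5) ** 2)
        assert res.h == pytest.approx(h_hand)
        z_hand = (2 - 5) / np.sqrt((6 * 7 / 12) * (1 / 3 + 1 / 3))
        pair = res.pairwise[("a", "b")]
        assert pair["z"] == pytest.approx(z_hand)
        assert pair["p_adj"] == pytest.approx(2 * norm.sf(abs(z_hand)))

    def test_identical_groups_calibrated(self):
        rng = np.random.default_rng(9)
        n_sig = 0
        for rep in range(200):
            values = rng.standard_normal(40)
            atlas = rc.ClassAtlas(labels=np.repeat(["a", "b", "c", "d"], 10))
            res = rc.class_comparison(values, atlas)
            n_sig += res.p_global < 0.05
        assert 0.01 < n_sig / 200 < 0.11

    def test_vanishing_shift_limit(self):
        base = np.arange(10.0)
        for shift, expect_small in [(5.0, False), (1e-9, True)]:
            values = np.concatenate([base, base + shift])
            atlas = rc.ClassAtlas(labels=np.repeat(["a", "b"], 10))
            res = rc.class_comparison(values, atlas)
            assert (res.h < 1.0) == expect_small

    def test_small_class_excluded_with_warning(self):
        values = np.arange(7.0)
        atlas = rc.ClassAtlas(labels=np.array(["a", "a", "a", "b", "b", "b", "c"]))
        with pytest.warns(UserWarning, match="excluded"):
            res = rc.class_comparison(values, atlas)
        assert set(res.class_means) == {"a", "b"}

    def test_planted_class_difference_power(self, geom100):
        # idiotypic regions planted with stronger receptome coupling: the
        # class test should reject at alpha = 0.001 in >= 90% of seeds
        panel, _ = rc.simulate_density_panel(geom100, 19, 3, 0.1, seed=0)
        m = rc.build_receptome(rc.zscore_panel(panel, "joint"))
        names = np.array(["idiotypic", "unimodal", "heteromodal", "paralimbic"])
        labels = names[np.arange(100) % 4]
        targets = {"idiotypic": 0.7, "unimodal": 0.45,
                   "heteromodal": 0.3, "paralimbic": 0.3}
        atlas = rc.ClassAtlas(labels=labels)
        hits = 0
        for seed in range(100):
            other, _ = rc.simulate_coupled_matrix(m, labels, targets, seed=seed)
            vals = rc.row_coupling(m, other)
            hits += rc.class_comparison(vals, atlas).p_global < 0.001
        assert hits >= 90
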