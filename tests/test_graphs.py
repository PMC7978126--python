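"""Density thresholding, graph metrics (against networkx and brute-force
oracles), signed Louvain, participation, curves, the area test, and
block-level FC means."""

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from netphen import (
    CurveComparison,
    DensityGrid,
    block_means,
    clustering,
    degree,
    density_upper_bound,
    global_efficiency,
    metric_curves,
    participation,
    signed_louvain,
    strength,
    threshold_graph,
)
from netphen._utils import vec_to_sym


def random_sym(n_nodes, rng, loc=0.0, scale=1.0):
    m = n_nodes * (n_nodes - 1) // 2
    return vec_to_sym(rng.normal(loc, scale, m), n_nodes)


class TestDensityBounds:
    def test_capped_at_max(self):
        rng = np.random.default_rng(0)
        mats = [random_sym(20, rng, loc=1.0, scale=0.3) for _ in range(5)]
        assert density_upper_bound(mats, "positive") == 40

    def test_minimum_subject_sets_bound(self):
        # subject with exactly 13.7% negative edges limits the negative bound
        n = 50
        m = n * (n - 1) // 2
        k_neg = int(round(0.137 * m))
        v = np.ones(m)
        v[:k_neg] = -1.0
        mats = [vec_to_sym(v, n), vec_to_sym(np.sign(np.linspace(-1, 1, m)), n)]
        assert density_upper_bound(mats, "negative") == 13

    def test_no_same_sign_edges_is_error(self):
        mats = [vec_to_sym(np.ones(10), 5)]
        with pytest.raises(ValueError, match="no negative edges"):
            density_upper_bound(mats, "negative")


class TestThresholdGraph:
    def test_retains_top_k(self):
        v = np.arange(1.0, 11.0)  # 5 nodes, 10 edges
        g = threshold_graph(vec_to_sym(v, 5), 20, "positive")
        assert len(g.edge_idx) == 2
        assert sorted(v[g.edge_idx]) == [9.0, 10.0]

    def test_tie_broken_by_edge_index(self):
        v = np.array([0.5, 0.9, 0.5, 0.5, 0.1, 0.2, 0.3, 0.05, 0.15, 0.25])
        g1 = threshold_graph(vec_to_sym(v, 5), 20, "positive")
        g2 = threshold_graph(vec_to_sym(v, 5), 20, "positive")
        np.testing.assert_array_equal(g1.edge_idx, g2.edge_idx)
        assert list(g1.edge_idx) == [0, 1]  # tie at 0.5: lowest index wins

    def test_union_doubles_edges(self):
        rng = np.random.default_rng(1)
        z = random_sym(20, rng)
        pos = threshold_graph(z, 10, "positive")
        uni = threshold_graph(z, 10, "union")
        assert len(uni.edge_idx) == 2 * len(pos.edge_idx)

    def test_zero_k_rejected(self):
        rng = np.random.default_rng(2)
        with pytest.raises(ValueError, match="zero edges"):
            threshold_graph(random_sym(5, rng), 1, "positive")

    def test_insufficient_same_sign_edges_rejected(self):
        v = np.ones(45)
        v[0] = -0.5
        with pytest.raises(ValueError, match="negative"):
            threshold_graph(vec_to_sym(v, 10), 20, "negative")


class TestMetrics:
    def test_complete_graph(self):
        A = np.ones((6, 6)) - np.eye(6)
        assert global_efficiency(A) == pytest.approx(1.0)
        np.testing.assert_allclose(clustering(A), 1.0)
        np.testing.assert_allclose(degree(A), 5.0)

    def test_three_node_path_efficiency(self):
        A = np.zeros((3, 3))
        A[0, 1] = A[1, 0] = A[1, 2] = A[2, 1] = 1
        assert global_efficiency(A) == pytest.approx(5 / 6)

    def test_strength_sums_magnitudes(self):
        W = np.zeros((3, 3))
        W[0, 1] = W[1, 0] = 0.5
        W[0, 2] = W[2, 0] = -0.3
        np.testing.assert_allclose(strength(W), [0.8, 0.5, 0.3])

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_networkx_reference(self, seed):
        rng = np.random.default_rng(seed)
        A = (random_sym(12, rng) > 0.4).astype(float)
        A = np.triu(A, 1)
        A = A + A.T
        G = nx.from_numpy_array(A)
        assert global_efficiency(A) == pytest.approx(nx.global_efficiency(G))
        np.testing.assert_allclose(
            clustering(A), [nx.clustering(G, i) for i in range(12)], atol=1e-12
        )
        np.testing.assert_allclose(
            degree(A), [G.degree(i) for i in range(12)], atol=1e-12
        )


class TestSignedLouvain:
    def test_disconnected_cliques_recovered(self):
        W = np.zeros((8, 8))
        for block in (range(4), range(4, 8)):
            for i in block:
                for j in block:
                    if i != j:
                        W[i, j] = 1.0
        q, part = signed_louvain(W, seed=0, n_restarts=5)
        assert len(set(part[:4])) == 1 and len(set(part[4:])) == 1
        assert part[0] != part[4]
        np.testing.assert_allclose(participation(W, part), 0.0)

    def test_quality_matches_direct_evaluation(self):
        # evaluate Q* of the returned partition with an independent formula
        rng = np.random.default_rng(3)
        W = random_sym(15, rng)
        q, part = signed_louvain(W, seed=1, n_restarts=5)
        Wp, Wn = np.maximum(W, 0), np.maximum(-W, 0)
        vp, vn = Wp.sum(), Wn.sum()
        same = part[:, None] == part[None, :]
        kp, kn = Wp.sum(1), Wn.sum(1)
        qp = ((Wp - np.outer(kp, kp) / vp) * same).sum() / vp
        qn = ((Wn - np.outer(kn, kn) / vn) * same).sum() / vn
        expected = qp - vn / (vp + vn) * qn
        assert q == pytest.approx(expected, abs=1e-10)

    def test_planted_three_block_recovery(self):
        from sklearn.metrics import adjusted_rand_score

        truth = np.repeat([0, 1, 2], 10)
        scores = []
        for seed in range(20):
            rng = np.random.default_rng(seed)
            W = rng.normal(-0.1, 0.1, size=(30, 30))
            W[truth[:, None] == truth[None, :]] = rng.normal(
                0.8, 0.1, size=(W[truth[:, None] == truth[None, :]]).shape
            )
            W = np.triu(W, 1)
            W = W + W.T
            _, part = signed_louvain(W, seed=seed, n_restarts=10)
            scores.append(adjusted_rand_score(truth, part))
        assert np.mean(scores) > 0.9

    def test_negative_only_graph_valid(self):
        W = np.zeros((4, 4))
        W[0, 1] = W[1, 0] = -1.0
        W[2, 3] = W[3, 2] = -1.0
        q, part = signed_louvain(W, seed=0)
        # negative edges should separate their endpoints
        assert part[0] != part[1] and part[2] != part[3]

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError, match="all-zero"):
            signed_louvain(np.zeros((4, 4)))

    def test_seed_determinism(self):
        rng = np.random.default_rng(4)
        W = random_sym(20, rng)
        q1, p1 = signed_louvain(W, seed=5, n_restarts=5)
        q2, p2 = signed_louvain(W, seed=5, n_restarts=5)
        assert q1 == q2
        np.testing.assert_array_equal(p1, p2)


class TestParticipation:
    def test_even_split_across_two_modules(self):
        W = np.zeros((5, 5))
        # node 0 connects equally into module {1,2} and module {3,4}
        W[0, 1] = W[1, 0] = 1.0
        W[0, 3] = W[3, 0] = 1.0
        part = np.array([0, 1, 1, 2, 2])
        assert participation(W, part)[0] == pytest.approx(0.5)

    def test_isolated_node_zero(self):
        W = np.zeros((3, 3))
        W[1, 2] = W[2, 1] = 1.0
        assert participation(W, np.array([0, 0, 1]))[0] == 0.0


class TestCurves:
    def test_constant_matrices_identical_curves(self):
        rng = np.random.default_rng(5)
        z = random_sym(15, rng)
        grid = DensityGrid(percents=tuple(range(1, 11)))
        curves = metric_curves([z, z, z], grid, "clustering")
        np.testing.assert_array_equal(curves[0], curves[1])
        np.testing.assert_array_equal(curves[1], curves[2])

    def test_degree_curves_nondecreasing_in_density(self):
        rng = np.random.default_rng(6)
        mats = [random_sym(15, rng) for _ in range(4)]
        grid = DensityGrid(percents=tuple(range(1, 21)))
        curves = metric_curves(mats, grid, "degree")
        assert (np.diff(curves, axis=-1) >= 0).all()

    def test_combined_partition_curves_match_individual_paths(self):
        from netphen.graphs import modularity_participation_curves

        rng = np.random.default_rng(13)
        mats = [random_sym(12, rng) for _ in range(3)]
        grid = DensityGrid(percents=(5, 10, 15), sign="union")
        mod, part = modularity_participation_curves(mats, grid, seed=2, n_restarts=3)
        mod_ref = metric_curves(mats, grid, "modularity", seed=2, n_restarts=3)
        part_ref = metric_curves(mats, grid, "participation", seed=2, n_restarts=3)
        np.testing.assert_array_equal(mod, mod_ref)
        np.testing.assert_array_equal(part, part_ref)

    def test_edge_counts_matched_across_subjects(self):
        rng = np.random.default_rng(7)
        mats = [random_sym(15, rng, loc=0.2) for _ in range(6)]
        for d in (5, 10, 20):
            ks = {len(threshold_graph(z, d, "positive").edge_idx) for z in mats}
            assert len(ks) == 1


class TestCurveComparison:
    def test_constant_curve_area(self):
        case = np.full((10, 40), 0.5)
        ctrl = np.full((12, 40), 0.3)
        res = CurveComparison(case, ctrl).fit(n_perm=100, seed=0)
        assert res.results[0].area == pytest.approx(8.0)

    def test_identical_compositions_zero_area(self):
        rng = np.random.default_rng(8)
        curves = rng.normal(size=(10, 20))
        res = CurveComparison(curves, curves.copy()).fit(n_perm=100, seed=0)
        assert res.results[0].area == pytest.approx(0.0, abs=1e-12)
        assert res.results[0].p_perm == pytest.approx(1.0)

    def test_area_bound(self):
        rng = np.random.default_rng(9)
        case, ctrl = rng.normal(size=(8, 15)), rng.normal(size=(9, 15))
        res = CurveComparison(case, ctrl).fit(n_perm=100, seed=0)
        max_diff = np.abs(case.mean(0) - ctrl.mean(0)).max()
        assert abs(res.results[0].area) <= 15 * max_diff + 1e-12

    def test_regional_fdr_attached(self):
        rng = np.random.default_rng(10)
        case, ctrl = rng.normal(size=(8, 5, 12)), rng.normal(size=(9, 5, 12))
        res = CurveComparison(case, ctrl).fit(n_perm=100, seed=0)
        assert res.regional and len(res.results) == 5
        for r in res.results:
            assert r.q is not None and r.q >= r.p_perm - 1e-12

    def test_strong_effect_detected(self):
        rng = np.random.default_rng(11)
        case = rng.normal(1.0, 0.2, size=(20, 10))
        ctrl = rng.normal(0.0, 0.2, size=(20, 10))
        res = CurveComparison(case, ctrl).fit(n_perm=500, seed=1)
        assert res.results[0].p_perm == pytest.approx(1 / 501)
        assert res.results[0].cohens_d > 2

    def test_min_perm_enforced(self):
        with pytest.raises(ValueError, match="n_perm"):
            CurveComparison(np.ones((4, 5)), np.ones((4, 5))).fit(n_perm=10)


class TestBlockMeans:
    def test_uniform_edges(self):
        z = np.full((6, 6), 0.25)
        np.fill_diagonal(z, 0)
        bm = block_means(z, np.array([0, 0, 0, 1, 1, 1]))
        assert bm.whole == pytest.approx(0.25)
        np.testing.assert_allclose(bm.pair.to_numpy(), 0.25)

    def test_hand_enumerated_toy(self):
        # 4 nodes, modules {0,1} and {2,3}; explicit edge values
        z = np.zeros((4, 4))
        vals = {(0, 1): 0.6, (0, 2): 0.1, (0, 3): 0.2, (1, 2): 0.3,
                (1, 3): 0.4, (2, 3): -0.5}
        for (i, j), v in vals.items():
            z[i, j] = z[j, i] = v
        bm = block_means(z, np.array([0, 0, 1, 1]))
        assert bm.pair.loc[0, 0] == pytest.approx(0.6)
        assert bm.pair.loc[1, 1] == pytest.approx(-0.5)
        assert bm.pair.loc[0, 1] == pytest.approx((0.1 + 0.2 + 0.3 + 0.4) / 4)
        assert bm.within[0] == pytest.approx(0.6)
        assert bm.to_rest[0] == pytest.approx(0.25)
        assert bm.whole == pytest.approx(np.mean(list(vals.values())))

    def test_invariant_to_relabeling_within_modules(self):
        rng = np.random.default_rng(12)
        z = random_sym(8, rng)
        mods = np.array([0, 0, 0, 0, 1, 1, 1, 1])
        bm1 = block_means(z, mods)
        perm = np.array([2, 0, 3, 1, 6, 4, 7, 5])  # permutes within modules
        bm2 = block_means(z[np.ix_(perm, perm)], mods)
        assert np.allclose(bm1.pair.to_numpy(), bm2.pair.to_numpy())

    def test_empty_module_rejected(self):
        z = np.zeros((3, 3))
        with pytest.raises(ValueError):
            block_means(z, np.array([0, 0, 0, 1]))
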