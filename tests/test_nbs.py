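"""Edge-wise F maps, suprathreshold components, and the max-component
permutation test, checked against independent oracles (scipy t-tests,
networkx components, exhaustive label enumeration)."""

from itertools import combinations

import networkx as nx
import numpy as np
import pytest
from scipy import stats

from netphen import NetworkBasedStatistic, suprathreshold_components
from netphen._utils import vec_to_sym
from netphen.nbs import EdgeStatMap


def nx_components(F, threshold):
    """Independent component oracle on the suprathreshold graph."""
    n = F.shape[0]
    G = nx.Graph()
    for i in range(n):
        for j in range(i + 1, n):
            if F[i, j] >= threshold:
                G.add_edge(i, j, f=F[i, j])
    out = []
    for nodes in nx.connected_components(G):
        sub = G.subgraph(nodes)
        out.append(
            {
                "edges": {tuple(sorted(e)) for e in sub.edges()},
                "extent": sub.number_of_edges(),
                "intensity": sum(d["f"] for *_, d in sub.edges(data=True)),
            }
        )
    return out


def random_stack(n_subj, n_nodes, rng, delta=0.0, planted=()):
    m = n_nodes * (n_nodes - 1) // 2
    stack = rng.normal(0, 1, size=(n_subj, m))
    mats = np.stack([vec_to_sym(v, n_nodes) for v in stack])
    for i, j in planted:
        mats[: n_subj // 2, i, j] += delta
        mats[: n_subj // 2, j, i] += delta
    return mats


class TestEdgeStats:
    def test_single_edge_matches_scipy_t(self):
        rng = np.random.default_rng(0)
        mats = random_stack(12, 4, rng)
        groups = np.array(["case"] * 6 + ["control"] * 6)
        model = NetworkBasedStatistic(mats, groups)
        F = model.edge_stats()
        t01, _ = stats.ttest_ind(mats[:6, 0, 1], mats[6:, 0, 1])
        assert F.stat[0, 1] == pytest.approx(t01**2, abs=1e-10)
        assert (F.df_num, F.df_den) == (1, 10)

    def test_identical_groups_zero_f(self):
        rng = np.random.default_rng(1)
        half = random_stack(5, 6, rng)
        mats = np.concatenate([half, half])
        groups = np.array(["case"] * 5 + ["control"] * 5)
        F = NetworkBasedStatistic(mats, groups).edge_stats()
        i, j = np.triu_indices(6, 1)
        assert np.abs(F.stat[i, j]).max() < 1e-18

    def test_planted_edges_carry_largest_f(self):
        rng = np.random.default_rng(2)
        planted = [(0, 1), (1, 2), (2, 3)]
        mats = random_stack(80, 10, rng, delta=0.0, planted=planted)
        # strong planted effect against sd 1 noise
        for i, j in planted:
            mats[:40, i, j] += 10
            mats[:40, j, i] += 10
        groups = np.array(["case"] * 40 + ["control"] * 40)
        F = NetworkBasedStatistic(mats, groups).edge_stats().stat
        i, j = np.triu_indices(10, 1)
        order = np.argsort(-F[i, j])[:3]
        top = {tuple(sorted((i[k], j[k]))) for k in order}
        assert top == set(planted)

    def test_f_symmetric_nonnegative(self):
        rng = np.random.default_rng(3)
        mats = random_stack(20, 8, rng)
        groups = np.array(["case"] * 10 + ["control"] * 10)
        F = NetworkBasedStatistic(mats, groups).edge_stats().stat
        assert (F >= 0).all()
        np.testing.assert_array_equal(F, F.T)


class TestComponents:
    def test_hand_checkable_two_components(self):
        F = np.zeros((5, 5))
        for i, j in [(0, 1), (1, 2)]:
            F[i, j] = F[j, i] = 5.0
        F[3, 4] = F[4, 3] = 7.0
        comps = suprathreshold_components(EdgeStatMap(F, 1, 10), threshold=4.0)
        assert [c.extent for c in comps] == [2, 1]
        assert comps[0].edges == ((0, 1), (1, 2))
        assert comps[0].intensity == pytest.approx(10.0)

    def test_no_suprathreshold_edges_empty(self):
        F = np.ones((4, 4)) * 0.5
        np.fill_diagonal(F, 0)
        assert suprathreshold_components(EdgeStatMap(F, 1, 10), 2.0) == []

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_networkx_oracle(self, seed):
        rng = np.random.default_rng(seed)
        F = vec_to_sym(rng.exponential(2.0, size=190), 20)
        comps = suprathreshold_components(EdgeStatMap(F, 1, 30), threshold=4.0)
        oracle = nx_components(F, 4.0)
        assert len(comps) == len(oracle)
        got = {frozenset(c.edges) for c in comps}
        want = {frozenset(o["edges"]) for o in oracle}
        assert got == want
        by_edges = {frozenset(o["edges"]): o for o in oracle}
        for c in comps:
            o = by_edges[frozenset(c.edges)]
            assert c.extent == o["extent"]
            assert c.intensity == pytest.approx(o["intensity"])

    def test_intensity_bound(self):
        rng = np.random.default_rng(42)
        F = vec_to_sym(rng.exponential(3.0, size=190), 20)
        for thr in (2.0, 4.0, 8.0):
            for c in suprathreshold_components(EdgeStatMap(F, 1, 30), thr):
                assert c.intensity >= c.extent * thr - 1e-12

    def test_raising_threshold_never_grows_extent(self):
        rng = np.random.default_rng(7)
        F = vec_to_sym(rng.exponential(3.0, size=435), 30)
        prev = None
        for thr in (2.0, 3.0, 4.0, 6.0):
            comps = suprathreshold_components(EdgeStatMap(F, 1, 30), thr)
            total = sum(c.extent for c in comps)
            if prev is not None:
                assert total <= prev
            prev = total


class TestPermutationTest:
    def test_exhaustive_small_n_matches_enumeration_oracle(self):
        rng = np.random.default_rng(5)
        n_nodes = 6
        mats = random_stack(8, n_nodes, rng, delta=2.0, planted=[(0, 1), (1, 2)])
        groups = np.array(["case"] * 4 + ["control"] * 4)
        model = NetworkBasedStatistic(mats, groups)
        thr = 6.0
        fit = model.fit(thr, n_perm=1000, seed=0)
        assert fit.exhaustive and fit.n_perm == 70

        # oracle: enumerate all 70 label splits with scipy t-tests
        i, j = np.triu_indices(n_nodes, 1)
        E = mats[:, i, j]
        E = E - E.mean(axis=0)
        null_ext, null_int = [], []
        for case_idx in combinations(range(8), 4):
            mask = np.zeros(8, bool)
            mask[list(case_idx)] = True
            t, _ = stats.ttest_ind(E[mask], E[~mask], axis=0)
            comps = nx_components(vec_to_sym(t**2, n_nodes), thr)
            null_ext.append(max((c["extent"] for c in comps), default=0))
            null_int.append(max((c["intensity"] for c in comps), default=0.0))
        null_ext, null_int = np.array(null_ext), np.array(null_int)
        for c in fit.components:
            assert c.p_extent == pytest.approx((null_ext >= c.extent).mean())
            assert c.p_intensity == pytest.approx(
                (null_int >= c.intensity - 1e-9).mean()
            )

    def test_p_value_range(self):
        rng = np.random.default_rng(6)
        mats = random_stack(30, 10, rng, delta=3.0, planted=[(0, 1)])
        groups = np.array(["case"] * 15 + ["control"] * 15)
        fit = NetworkBasedStatistic(mats, groups).fit(8.0, n_perm=200, seed=1)
        for c in fit.components:
            assert 1 / 201 <= c.p_extent <= 1
            assert 1 / 201 <= c.p_intensity <= 1

    def test_observed_components_invariant_under_subject_reorder(self):
        rng = np.random.default_rng(8)
        mats = random_stack(24, 8, rng, delta=1.5, planted=[(0, 1), (1, 2)])
        groups = np.array(["case"] * 12 + ["control"] * 12)
        fit1 = NetworkBasedStatistic(mats, groups).fit(5.0, n_perm=150, seed=2)
        perm = rng.permutation(24)
        fit2 = NetworkBasedStatistic(mats[perm], groups[perm]).fit(
            5.0, n_perm=150, seed=2
        )
        assert {frozenset(c.edges) for c in fit1.components} == {
            frozenset(c.edges) for c in fit2.components
        }

    def test_seed_determinism(self):
        rng = np.random.default_rng(9)
        mats = random_stack(30, 8, rng, delta=1.0, planted=[(0, 1)])
        groups = np.array(["case"] * 15 + ["control"] * 15)
        m = NetworkBasedStatistic(mats, groups)
        f1 = m.fit(5.0, n_perm=200, seed=3)
        f2 = m.fit(5.0, n_perm=200, seed=3)
        np.testing.assert_array_equal(f1.null_max_intensity, f2.null_max_intensity)

    def test_design_residualization_removes_covariate_effect(self):
        rng = np.random.default_rng(10)
        n = 40
        mats = random_stack(n, 6, rng)
        age = rng.uniform(18, 70, n)
        mats += 0.05 * (age - age.mean())[:, None, None]  # additive covariate signal
        for k in range(n):
            np.fill_diagonal(mats[k], 0)
        groups = np.array(["case"] * 20 + ["control"] * 20)
        design = np.column_stack([np.ones(n), age])
        F_adj = NetworkBasedStatistic(mats, groups, design=design).edge_stats().stat
        # after residualization the age signal is gone; F stays modest
        crit = stats.f.isf(0.0005, 1, 38)
        assert np.median(F_adj) < crit

    def test_validation_errors(self):
        rng = np.random.default_rng(11)
        mats = random_stack(10, 5, rng)
        groups = np.array(["case"] * 5 + ["control"] * 5)
        model = NetworkBasedStatistic(mats, groups)
        with pytest.raises(ValueError, match="n_perm"):
            model.fit(4.0, n_perm=10)
        with pytest.raises(ValueError, match="statistic"):
            model.fit(4.0, statistic="volume")
        with pytest.raises(ValueError, match="threshold"):
            suprathreshold_components(model.edge_stats(), -1.0)
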