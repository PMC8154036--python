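import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from faaverse.cluster import (
    AdjacencyGraph,
    Cluster,
    build_channel_adjacency,
    cluster_asymmetry_test,
    cluster_permutation_test,
    find_clusters,
    grid_adjacency,
    node_sides_product,
    pair_graph,
    product_adjacency,
)
from faaverse.layouts import make_standard_layout


class TestAdjacency:
    def test_grid_recovers_four_neighbourhood(self):
        g = grid_adjacency(3, 3)
        assert g.n_nodes == 9
        assert (0, 1) in g.edges and (0, 3) in g.edges
        assert (0, 4) not in g.edges  # no diagonals
        assert len(g.edges) == 12

    def test_channel_adjacency_symmetric_and_local(self, layout):
        g = build_channel_adjacency(layout)
        names = g.node_ids
        nbr_names = {names[i]: {names[j] for j in g.neighbors[i]}
                     for i in range(g.n_nodes)}
        # symmetry
        for a, nbrs in nbr_names.items():
            for b in nbrs:
                assert a in nbr_names[b]
        # locality: frontal and occipital poles are never neighbours
        assert "O1" not in nbr_names["Fp1"]
        assert "O2" not in nbr_names["F4"]
        # homologous frontal neighbours exist through the midline row
        assert nbr_names["F3"], "F3 should have neighbours"

    def test_far_apart_channels_not_linked_in_larger_montage(self, layout):
        g = build_channel_adjacency(layout, subset=["F7", "F3", "Fz", "F4", "F8",
                                                    "O1", "O2"])
        names = g.node_ids
        idx = {n: i for i, n in enumerate(names)}
        assert idx["O1"] not in g.neighbors[idx["F7"]]

    def test_self_edges_rejected(self):
        with pytest.raises(ValueError):
            AdjacencyGraph(3, ((0, 0),))

    def test_product_graph_structure(self):
        chan = AdjacencyGraph(3, ((0, 1),))  # node 2 isolated
        prod = product_adjacency(chan, 5)
        assert prod.n_nodes == 15
        # isolated channel x 5 bins forms a path graph
        path_nodes = [2 * 5 + f for f in range(5)]
        for a, b in zip(path_nodes, path_nodes[1:]):
            assert b in prod.neighbors[a]
        assert len(prod.neighbors[path_nodes[0]]) == 1
        # 1 bin is isomorphic to the channel graph
        one = product_adjacency(chan, 1)
        assert one.n_nodes == 3 and one.edges == ((0, 1),)

    def test_pair_graph_uses_left_member_geometry(self, layout):
        pairs = list(layout.frontal_pairs())
        g = pair_graph(layout, pairs)
        assert g.n_nodes == len(pairs)
        assert g.node_ids == tuple(f"{l}-{r}" for l, r in pairs)


class TestFindClusters:
    def test_zero_map_has_no_clusters(self):
        g = grid_adjacency(2, 3)
        assert find_clusters(np.zeros(6), 2.0, g) == []

    def test_single_suprathreshold_node(self):
        g = grid_adjacency(2, 3)
        stat = np.zeros(6)
        stat[4] = 3.5
        (cl,) = find_clusters(stat, 2.0, g)
        assert cl.nodes == (4,) and cl.mass == pytest.approx(3.5) and cl.sign == 1

    def test_hand_drawn_mixed_sign_graph(self):
        # path 0-1-2-3-4-5 with stats +3 +2.5 -3 -4 +0.1 +2.2
        g = AdjacencyGraph(6, ((0, 1), (1, 2), (2, 3), (3, 4), (4, 5)))
        stat = np.array([3.0, 2.5, -3.0, -4.0, 0.1, 2.2])
        clusters = sorted(find_clusters(stat, 2.0, g), key=lambda c: c.nodes)
        assert [(c.nodes, c.sign) for c in clusters] == [
            ((0, 1), 1), ((2, 3), -1), ((5,), 1)]
        assert clusters[0].mass == pytest.approx(5.5)
        assert clusters[1].mass == pytest.approx(-7.0)


def _group_data(rng, n1=8, n0=8, nodes=6, effect=0.0, where=slice(0, 2)):
    X = rng.normal(size=(n1 + n0, nodes))
    X[:n1, where] += effect
    labels = np.concatenate([np.ones(n1), np.zeros(n0)])
    return X, labels


class TestClusterPermutation:
    def test_exact_enumeration_matches_brute_force(self, rng):
        """4 vs 4 subjects: the exact path must reproduce the full 70-way
        relabeling null exactly (independent re-implementation here)."""
        g = grid_adjacency(2, 3)
        X, labels = _group_data(rng, 4, 4, effect=2.5)
        res = cluster_permutation_test(X, labels, g, kind="group", n_perm=100)
        assert res.method == "exact" and res.n_perm_used == 70

        def welch_map(lab):
            return sps.ttest_ind(X[lab == 1], X[lab == 0],
                                 equal_var=False).statistic

        def masses(stat, sign):
            out = []
            seen = set()
            mask = stat > res.threshold if sign > 0 else stat < -res.threshold
            for start in np.nonzero(mask)[0]:
                if start in seen:
                    continue
                comp, stack = set(), [start]
                while stack:
                    n = stack.pop()
                    if n in comp:
                        continue
                    comp.add(n)
                    stack.extend(m for m in g.neighbors[n] if mask[m])
                seen |= comp
                out.append(stat[list(comp)].sum())
            return out

        null_pos, null_neg = [], []
        for members in itertools.combinations(range(8), 4):
            lab = np.zeros(8)
            lab[list(members)] = 1
            stat = welch_map(lab)
            null_pos.append(max(masses(stat, +1), default=0.0))
            null_neg.append(min(masses(stat, -1), default=0.0))
        for cl in res.clusters:
            if cl.sign == 1:
                expected = np.mean([m >= cl.mass - 1e-12 for m in null_pos])
            else:
                expected = np.mean([m <= cl.mass + 1e-12 for m in null_neg])
            assert cl.p == pytest.approx(expected, abs=0)

    def test_sign_equivariance(self, rng):
        g = grid_adjacency(2, 4)
        X, labels = _group_data(rng, 6, 7, nodes=8, effect=1.8)
        a = cluster_permutation_test(X, labels, g, kind="group", n_perm=300,
                                     seed=3)
        b = cluster_permutation_test(-X, labels, g, kind="group", n_perm=300,
                                     seed=3)
        assert np.allclose(a.stat_map, -b.stat_map)
        pa = sorted((c.nodes, c.sign, c.p) for c in a.clusters)
        pb = sorted((c.nodes, -c.sign, c.p) for c in b.clusters)
        assert pa == pb
        assert a.min_t == pytest.approx(-b.max_t)

    def test_raising_threshold_never_adds_significant_points(self, rng):
        g = grid_adjacency(3, 4)
        X, labels = _group_data(rng, 10, 10, nodes=12, effect=1.0,
                                where=slice(0, 5))
        counts = []
        for alpha in (0.2, 0.05, 0.01):
            res = cluster_permutation_test(X, labels, g, kind="group",
                                           n_perm=50, seed=0, alpha=alpha)
            counts.append(res.n_significant_points)
        assert counts[0] >= counts[1] >= counts[2]

    def test_p_floor_monte_carlo(self, rng):
        g = grid_adjacency(2, 3)
        X, labels = _group_data(rng, 12, 12, effect=4.0)
        res = cluster_permutation_test(X, labels, g, kind="group",
                                       n_perm=199, seed=1)
        assert res.method == "montecarlo"
        for cl in res.clusters:
            assert cl.p >= 1.0 / 200.0

    def test_deterministic_given_seed(self, rng):
        g = grid_adjacency(2, 3)
        X, labels = _group_data(rng, 12, 12, effect=1.0)
        r1 = cluster_permutation_test(X, labels, g, n_perm=200, seed=5)
        r2 = cluster_permutation_test(X, labels, g, n_perm=200, seed=5)
        assert [(c.nodes, c.p) for c in r1.clusters] == \
               [(c.nodes, c.p) for c in r2.clusters]

    def test_matches_mne_observed_clusters(self, rng):
        mne = pytest.importorskip("mne")
        import scipy.sparse as sp

        g = grid_adjacency(3, 4)
        X, labels = _group_data(rng, 15, 15, nodes=12, effect=1.0,
                                where=[0, 1, 4])
        res = cluster_permutation_test(X, labels, g, kind="group", n_perm=50,
                                       seed=0)
        adj = sp.lil_matrix((12, 12))
        for i, j in g.edges:
            adj[i, j] = adj[j, i] = 1

        def statfun(a, b):
            return sps.ttest_ind(a, b, equal_var=False).statistic

        T_obs, clusters, _, _ = mne.stats.permutation_cluster_test(
            [X[labels == 1], X[labels == 0]], threshold=res.threshold,
            n_permutations=50, adjacency=sp.csr_matrix(adj), stat_fun=statfun,
            tail=0, verbose=False)
        assert np.allclose(T_obs, res.stat_map)
        mine = sorted(c.nodes for c in res.clusters)
        theirs = sorted(tuple(sorted(int(i) for i in c[0])) for c in clusters)
        assert mine == theirs

    def test_linear_stat_map_matches_statsmodels(self, rng):
        import statsmodels.api as sm

        g = grid_adjacency(2, 3)
        X = rng.normal(size=(20, 6))
        score = rng.normal(size=20)
        conf = rng.normal(size=(20, 2))
        res = cluster_permutation_test(X, score, g, kind="linear",
                                       confounds=conf, n_perm=10, seed=0)
        for node in range(6):
            D = np.column_stack([np.ones(20), score, conf])
            fit = sm.OLS(X[:, node], D).fit()
            assert res.stat_map[node] == pytest.approx(fit.tvalues[1])
        # entry threshold uses the residual df of the pointwise regression
        assert res.threshold == pytest.approx(sps.t.ppf(0.975, 20 - 2 - 2))

    def test_group_with_confounds_uses_regression_t(self, rng):
        import statsmodels.api as sm

        g = grid_adjacency(2, 3)
        X, labels = _group_data(rng, 10, 10, effect=1.0)
        conf = rng.normal(size=20)
        res = cluster_permutation_test(X, labels, g, kind="group",
                                       confounds=conf, n_perm=10, seed=0)
        D = np.column_stack([np.ones(20), labels, conf])
        fit = sm.OLS(X[:, 0], D).fit()
        assert res.stat_map[0] == pytest.approx(fit.tvalues[1])

    def test_injected_frontal_effect_is_localized(self, rng):
        g = grid_adjacency(4, 4)
        target = [0, 1, 4, 5]
        X = rng.normal(size=(40, 16))
        X[:20, target] -= 2.0
        labels = np.concatenate([np.ones(20), np.zeros(20)])
        res = cluster_permutation_test(X, labels, g, kind="group",
                                       n_perm=500, seed=2)
        largest = res.largest_cluster("size")
        assert largest.sign == -1 and largest.p < 0.01
        assert set(target) <= set(largest.nodes)

    def test_input_validation(self, rng):
        g = grid_adjacency(2, 3)
        X = rng.normal(size=(6, 6))
        with pytest.raises(ValueError, match="2 subjects"):
            cluster_permutation_test(X, np.array([1, 0, 0, 0, 0, 0.0]), g)
        conf = rng.normal(size=6)
        conf[2] = np.nan
        with pytest.raises(ValueError, match="missing"):
            cluster_permutation_test(X, np.array([1, 1, 1, 0, 0, 0.0]), g,
                                     confounds=conf)


class TestClusterAsymmetry:
    def test_mirror_symmetric_cluster_chi2_zero(self):
        sides = ["left", "right", "midline", "left", "right"]
        cl = Cluster(nodes=(0, 1), mass=5.0, sign=1)
        res = cluster_asymmetry_test(cl, sides)
        assert res.statistic == 0.0 and res.p == pytest.approx(1.0)

    def test_fully_lateralized_cluster_detected(self):
        sides = ["left"] * 6 + ["right"] * 6
        cl = Cluster(nodes=tuple(range(6)), mass=12.0, sign=1)
        res = cluster_asymmetry_test(cl, sides)
        assert res.statistic > 3.84 and res.p < 0.05

    def test_counts_match_hand_2x2(self):
        from faaverse.stats import chi2_two_proportions

        sides = ["left"] * 5 + ["right"] * 7 + ["midline"] * 3
        cl = Cluster(nodes=(0, 1, 2, 5, 12, 13), mass=1.0, sign=1)
        res = cluster_asymmetry_test(cl, sides)
        # 3 of 5 left nodes vs 1 of 7 right nodes; midline excluded entirely
        oracle = chi2_two_proportions(3, 5, 1, 7)
        assert res.statistic == pytest.approx(oracle.statistic)
        assert res.p == pytest.approx(oracle.p)

    def test_one_sided_search_space_errors(self):
        with pytest.raises(ValueError):
            cluster_asymmetry_test(Cluster((0,), 1.0, 1), ["left", "left"])

    def test_node_sides_product_ordering(self):
        sides = node_sides_product(["F3", "Fz", "F4"], 2)
        assert sides == ["left", "left", "midline", "midline", "right", "right"]
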