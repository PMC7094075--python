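import networkx as nx
import numpy as np
import pytest

from paramicro import (
    bootstrap_centrality_ks,
    gaussian_graph_data,
    mb_stars_network,
    network_stats,
    simulate_correlated_pair_counts,
    simulate_null_counts,
    sparcc_correlations,
    sparcc_pvalues,
    threshold_edges,
)
from paramicro.networks import CoAssociationNetwork, _basis_variances, _rho_from_basis
from tests._oracles import brute_betweenness, brute_ks, f1_edges


class TestSparccBasis:
    def test_three_variable_closed_form(self):
        # T with all off-diagonal log-ratio variances 2: the 3x3 system
        # (I + J) w = t has the exact solution w = t - sum(t)/4 = (1,1,1),
        # giving rho_12 = (1 + 1 - 2)/2 = 0
        T = np.array([[0.0, 2, 2], [2, 0, 2], [2, 2, 0]])
        omega = _basis_variances(T, np.zeros((3, 3), dtype=bool))
        np.testing.assert_allclose(omega, [1.0, 1.0, 1.0], atol=1e-12)
        rho = _rho_from_basis(T, omega)
        assert rho[0, 1] == pytest.approx(0.0, abs=1e-12)
        np.testing.assert_allclose(np.diag(rho), 1.0)

    def test_correlated_pair_closed_form(self):
        # w = (1,1,1) with cov_12 = 0.5: T_12 = 1+1-2*0.5 = 1, others 2
        T = np.array([[0.0, 1, 2], [1, 0, 2], [2, 2, 0]])
        omega = _basis_variances(T, np.zeros((3, 3), dtype=bool))
        rho = _rho_from_basis(T, omega)
        # sparsity approximation distributes the shared covariance; the
        # planted pair must still be the largest off-diagonal entry
        assert rho[0, 1] == np.nanmax(rho[~np.eye(3, dtype=bool)])


class TestSparccCorrelations:
    def test_symmetric_unit_diagonal(self):
        ft = simulate_null_counts(12, 30, seed=0)
        rho = sparcc_correlations(ft, seed=1).correlations
        np.testing.assert_allclose(rho, rho.T, atol=1e-12)
        np.testing.assert_allclose(np.diag(rho), 1.0)

    def test_null_off_diagonal_small(self):
        ft = simulate_null_counts(50, 200, seed=2)
        rho = sparcc_correlations(ft, seed=3).correlations
        off = rho[~np.eye(50, dtype=bool)]
        assert np.nanmax(np.abs(off)) < 0.3

    def test_recovers_planted_pair(self):
        ft = simulate_correlated_pair_counts(32, 200, rho=0.9, seed=4)
        rho = sparcc_correlations(ft, seed=5).correlations
        assert 0.6 <= rho[0, 1] <= 1.0

    def test_compositional_scale_invariance(self):
        # multiplying every sample's counts by a constant leaves the
        # correlations essentially unchanged at high depth
        ft = simulate_correlated_pair_counts(20, 100, rho=0.8, seed=6)
        r1 = sparcc_correlations(ft.counts, seed=7).correlations
        r2 = sparcc_correlations(ft.counts * 5, seed=7).correlations
        assert np.nanmax(np.abs(r1 - r2)) < 0.1

    def test_deterministic(self):
        ft = simulate_null_counts(10, 20, seed=8)
        a = sparcc_correlations(ft, seed=9).correlations
        b = sparcc_correlations(ft, seed=9).correlations
        np.testing.assert_array_equal(a, b)

    def test_too_few_features(self):
        with pytest.raises(ValueError):
            sparcc_correlations(np.ones((2, 10)))


class TestSparccPvalues:
    def test_deterministic(self):
        ft = simulate_null_counts(8, 20, seed=10)
        a = sparcc_pvalues(ft, n_bootstrap=30, seed=11)
        b = sparcc_pvalues(ft, n_bootstrap=30, seed=11)
        np.testing.assert_array_equal(a, b)

    def test_strong_edge_hits_floor(self):
        ft = simulate_correlated_pair_counts(10, 150, rho=0.95, seed=12)
        p = sparcc_pvalues(ft, n_bootstrap=40, seed=13)
        assert p[0, 1] == pytest.approx(1 / 40)

    def test_null_edges_have_large_p(self):
        ft = simulate_null_counts(10, 100, seed=14)
        p = sparcc_pvalues(ft, n_bootstrap=40, seed=15)
        off = p[np.triu_indices(10, 1)]
        assert np.nanmedian(off) > 0.2


class TestThresholdEdges:
    def test_exact_threshold_excluded(self):
        rho = np.array([[1.0, 0.6], [0.6, 1.0]])
        p = np.full((2, 2), 0.001)
        net = threshold_edges(rho, p, ("a", "b"))
        assert net.n_edges == 0

    def test_qualifying_edge_included_with_sign(self):
        rho = np.array([[1.0, 0.95], [0.95, 1.0]])
        p = np.array([[np.nan, 0.01], [0.01, np.nan]])
        net = threshold_edges(rho, p, ("a", "b"))
        assert net.n_edges == 1
        assert net.edges[0][2] > 0

    def test_toy_enumeration(self):
        rho = np.eye(4)
        p = np.ones((4, 4))
        for i, j, r, pv in [(0, 1, 0.9, 0.01), (2, 3, -0.8, 0.02), (0, 2, 0.9, 0.2), (1, 3, 0.3, 0.01)]:
            rho[i, j] = rho[j, i] = r
            p[i, j] = p[j, i] = pv
        net = threshold_edges(rho, p, tuple("abcd"))
        got = {(u, v) for u, v, _ in net.edges}
        assert got == {("a", "b"), ("c", "d")}
        assert net.node_ids == tuple("abcd")  # isolated nodes retained

    def test_edge_count_monotone_in_thresholds(self):
        rng = np.random.default_rng(16)
        a = rng.uniform(-1, 1, (12, 12))
        rho = (a + a.T) / 2
        np.fill_diagonal(rho, 1.0)
        b = rng.uniform(0, 1, (12, 12))
        p = (b + b.T) / 2
        ids = tuple(f"n{i}" for i in range(12))
        prev = None
        for thr in (0.0, 0.2, 0.4, 0.6, 0.8):
            n = threshold_edges(rho, p, ids, min_abs_corr=thr).n_edges
            if prev is not None:
                assert n <= prev
            prev = n
        prev = None
        for alpha in (1.0, 0.5, 0.2, 0.05):
            n = threshold_edges(rho, p, ids, min_abs_corr=0.0, alpha=alpha).n_edges
            if prev is not None:
                assert n <= prev
            prev = n


class TestMbStars:
    def test_recovers_chain_graph(self):
        truth = [(i, i + 1) for i in range(9)]
        x = gaussian_graph_data(truth, 10, 200, strength=0.5, seed=17)
        net = mb_stars_network(x, seed=18)
        found = [(int(u[1:]), int(v[1:])) for u, v, _ in net.edges]
        assert f1_edges(found, truth) >= 0.8

    def test_null_graph_is_sparse(self):
        x = np.random.default_rng(19).standard_normal((100, 15))
        net = mb_stars_network(x, seed=20)
        assert net.n_edges / (15 * 14 / 2) < 0.05

    def test_deterministic(self):
        x = gaussian_graph_data([(0, 1)], 6, 80, seed=21)
        a = mb_stars_network(x, seed=22)
        b = mb_stars_network(x, seed=22)
        assert a.edges == b.edges

    def test_constant_feature_dropped(self):
        x = np.random.default_rng(23).standard_normal((50, 5))
        x[:, 2] = 1.0
        net = mb_stars_network(x, feature_ids=tuple("abcde"), seed=24)
        assert "c" not in net.node_ids


class TestNetworkStats:
    def test_path_graph(self):
        net = CoAssociationNetwork(("a", "b", "c"), (("a", "b", 1.0), ("b", "c", 1.0)))
        st = network_stats(net)
        assert list(st.betweenness) == [0.0, 1.0, 0.0]
        assert st.edge_density == pytest.approx(2 / 3)
        assert st.degree.sum() == 2 * net.n_edges

    def test_star_graph_is_maximally_centralized(self):
        edges = tuple(("hub", leaf, 1.0) for leaf in "abcd")
        net = CoAssociationNetwork(("hub", "a", "b", "c", "d"), edges)
        st = network_stats(net)
        assert st.betweenness["hub"] == pytest.approx(6.0)  # C(4,2) pairs
        assert st.betweenness_centralization == pytest.approx(1.0)

    def test_cycle_graph_is_uncentralized(self):
        ids = tuple(f"n{i}" for i in range(5))
        edges = tuple((ids[i], ids[(i + 1) % 5], 1.0) for i in range(5))
        st = network_stats(CoAssociationNetwork(ids, edges))
        assert st.betweenness.nunique() == 1
        assert st.betweenness_centralization == pytest.approx(0.0)

    def test_matches_bruteforce_betweenness_on_random_graphs(self):
        rng = np.random.default_rng(25)
        for _ in range(20):
            n = int(rng.integers(4, 9))
            g = nx.gnp_random_graph(n, 0.45, seed=int(rng.integers(2**31)))
            ids = tuple(str(v) for v in g.nodes)
            edges = tuple((str(u), str(v), 1.0) for u, v in g.edges)
            st = network_stats(CoAssociationNetwork(ids, edges))
            want = brute_betweenness(nx.relabel_nodes(g, str))
            for v in ids:
                assert st.betweenness[v] == pytest.approx(want[v], abs=1e-9)

    def test_betweenness_conservation(self):
        # sum of betweenness = sum over pairs of expected interior vertices
        rng = np.random.default_rng(26)
        for _ in range(5):
            g = nx.gnp_random_graph(7, 0.5, seed=int(rng.integers(2**31)))
            ids = tuple(str(v) for v in g.nodes)
            edges = tuple((str(u), str(v), 1.0) for u, v in g.edges)
            st = network_stats(CoAssociationNetwork(ids, edges))
            want = brute_betweenness(nx.relabel_nodes(g, str))
            assert st.betweenness.sum() == pytest.approx(sum(want.values()), abs=1e-9)


class TestBootstrapKS:
    def test_identical_populations_small_d(self):
        vals = np.arange(30.0)
        res = bootstrap_centrality_ks(vals, vals.copy(), k=50, n_reps=4000, seed=27)
        assert res.statistic < 0.05

    def test_disjoint_supports_give_d_one(self):
        res = bootstrap_centrality_ks(np.zeros(20), np.ones(20), k=50, n_reps=1000, seed=28)
        assert res.statistic == 1.0
        assert res.pvalue < 1e-6

    def test_d_matches_ecdf_scan_oracle(self):
        rng = np.random.default_rng(29)
        from scipy import stats

        for _ in range(10):
            a = rng.standard_normal(40)
            b = rng.standard_normal(35) + rng.uniform(-1, 1)
            d = stats.ks_2samp(a, b, method="asymp").statistic
            assert d == pytest.approx(brute_ks(a, b), abs=1e-12)

    def test_empty_input_errors(self):
        with pytest.raises(ValueError):
            bootstrap_centrality_ks(np.array([]), np.ones(3))


class TestCoAssociationNetworkInvariants:
    def test_rejects_self_edge(self):
        with pytest.raises(ValueError, match="self edge"):
            CoAssociationNetwork(("a",), (("a", "a", 1.0),))

    def test_rejects_duplicate_pair(self):
        with pytest.raises(ValueError, match="duplicate"):
            CoAssociationNetwork(("a", "b"), (("a", "b", 1.0), ("b", "a", 0.5),))
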