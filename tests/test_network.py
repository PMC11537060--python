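"""Co-occurrence networks: correlations, RMT threshold, topology, nulls."""

import networkx as nx
import numpy as np
import pandas as pd
import pytest
import scipy.stats

from spongenet.network import (
    RmtThresholdError,
    build_network,
    keystone_species,
    maslov_sneppen_rewire,
    null_ensemble,
    rmt_threshold,
    spearman_matrix,
    topology,
)
from spongenet.table import AsvTable


def two_block_matrix(n_block=50, within=0.9, between=0.1, jitter=0.02, seed=7):
    """Directly constructed block correlation matrix with entry jitter."""
    rng = np.random.default_rng(seed)
    p = 2 * n_block
    m = between + rng.normal(0, jitter, (p, p))
    m[:n_block, :n_block] = within + rng.normal(0, jitter, (n_block, n_block))
    m[n_block:, n_block:] = within + rng.normal(0, jitter, (n_block, n_block))
    m = (m + m.T) / 2
    np.fill_diagonal(m, 1.0)
    ids = [f"A{i:03d}" for i in range(p)]
    return pd.DataFrame(m, index=ids, columns=ids)


class TestSpearman:
    def test_monotone_and_antimonotone(self):
        t = AsvTable(
            pd.DataFrame(
                {"s1": [1, 9, 2], "s2": [3, 7, 3], "s3": [5, 5, 8], "s4": [9, 1, 9]},
                index=["up", "down", "up2"],
            )
        )
        corr, dropped = spearman_matrix(t)
        assert dropped == []
        assert corr.loc["up", "up2"] == pytest.approx(1.0)
        assert corr.loc["up", "down"] == pytest.approx(-1.0)

    def test_matches_scipy(self, random_table):
        corr, _ = spearman_matrix(random_table)
        ref = scipy.stats.spearmanr(random_table.counts.T).statistic
        sub = ref[: corr.shape[0], : corr.shape[0]]
        np.testing.assert_allclose(corr.to_numpy(), sub, atol=1e-12)

    def test_too_few_samples(self):
        t = AsvTable(pd.DataFrame(np.eye(3, dtype=int) + 1))
        with pytest.raises(ValueError, match="4 samples"):
            spearman_matrix(t)

    def test_zero_variance_flagged(self):
        t = AsvTable(
            pd.DataFrame(
                {"s1": [1, 5, 3], "s2": [2, 5, 1], "s3": [3, 5, 4], "s4": [4, 5, 2]},
                index=["ok", "flat", "ok2"],
            )
        )
        corr, dropped = spearman_matrix(t)
        assert dropped == ["flat"]
        assert list(corr.index) == ["ok", "ok2"]


class TestRmtThreshold:
    def test_two_block_matrix_components_equal_blocks(self):
        c = two_block_matrix()
        s_t, diag = rmt_threshold(c)
        assert s_t < 0.9
        net = build_network(c, s_t)
        comps = sorted(
            (set(cc) for cc in nx.connected_components(net.graph)), key=min
        )
        blocks = [
            {f"A{i:03d}" for i in range(50)},
            {f"A{i:03d}" for i in range(50, 100)},
        ]
        assert comps == blocks

    def test_degenerate_matrix_errors(self):
        ids = [str(i) for i in range(60)]
        c = pd.DataFrame(np.eye(60), index=ids, columns=ids)
        with pytest.raises(RmtThresholdError):
            rmt_threshold(c)

    def test_small_matrix_warns(self):
        c = two_block_matrix(n_block=10)
        with pytest.warns(UserWarning, match="nodes"):
            try:
                rmt_threshold(c)
            except RmtThresholdError:
                pass

    def test_diagnostics_cover_scan(self):
        c = two_block_matrix()
        _, diag = rmt_threshold(c)
        assert {"threshold", "poisson_gof_p"} <= set(diag.columns)
        assert diag["threshold"].iloc[0] == pytest.approx(0.30)


class TestBuildNetwork:
    def test_high_threshold_empty(self):
        c = two_block_matrix()
        assert build_network(c, 1.0).n_edges == 0

    def test_triangle(self):
        ids = list("xyz")
        m = np.full((3, 3), 0.95)
        m[0, 1] = m[1, 0] = -0.95  # one negative edge
        np.fill_diagonal(m, 1.0)
        net = build_network(pd.DataFrame(m, index=ids, columns=ids), 0.9)
        assert net.n_edges == 3
        assert net.graph["x"]["y"]["sign"] == -1
        assert net.graph["x"]["z"]["sign"] == 1

    def test_edges_monotone_in_threshold(self, rng):
        m = rng.uniform(-1, 1, (20, 20))
        m = (m + m.T) / 2
        np.fill_diagonal(m, 1.0)
        c = pd.DataFrame(m, index=[str(i) for i in range(20)],
                         columns=[str(i) for i in range(20)])
        edges = [
            set(map(frozenset, build_network(c, s).graph.edges()))
            for s in (0.3, 0.5, 0.7, 0.9)
        ]
        for lower, higher in zip(edges, edges[1:]):
            assert higher <= lower


class TestTopology:
    def test_k4(self):
        topo = topology(nx.complete_graph(4))
        assert topo.n_nodes == 4 and topo.n_links == 6
        assert topo.avg_connectivity == pytest.approx(3.0)
        assert topo.connectedness == 1.0
        assert topo.modularity == pytest.approx(0.0)

    def test_two_disjoint_triangles(self):
        g = nx.Graph(
            [("a", "b"), ("b", "c"), ("a", "c"), ("x", "y"), ("y", "z"), ("x", "z")]
        )
        topo = topology(g)
        assert topo.avg_connectivity == pytest.approx(2.0)
        assert topo.connectedness == pytest.approx(6 / 15)
        # Q = 2 x (1/2 - 1/4) with the two triangles as modules
        assert topo.modularity == pytest.approx(0.5)

    def test_star_hub(self):
        topo = topology(nx.star_graph(5))
        assert topo.degree[0] == 5
        assert topo.betweenness.idxmax() == 0
        assert topo.betweenness[0] == pytest.approx(1.0)

    def test_degree_sum_is_2l(self, rng):
        g = nx.gnm_random_graph(30, 60, seed=3)
        topo = topology(g)
        assert topo.degree.sum() == 2 * topo.n_links

    def test_empty_graph_errors(self):
        with pytest.raises(ValueError):
            topology(nx.Graph())


class TestMaslovSneppen:
    def test_invariants_preserved(self):
        g = nx.gnm_random_graph(40, 90, seed=0)
        h = maslov_sneppen_rewire(g, seed=1)
        assert set(h.nodes()) == set(g.nodes())
        assert h.number_of_edges() == g.number_of_edges()
        assert sorted(d for _, d in h.degree()) == sorted(d for _, d in g.degree())
        assert not any(u == v for u, v in h.edges())

    def test_triangle_unchanged(self):
        g = nx.complete_graph(3)
        h = maslov_sneppen_rewire(g, seed=0)
        assert set(map(frozenset, h.edges())) == set(map(frozenset, g.edges()))

    def test_seeded_reproducibility(self):
        g = nx.gnm_random_graph(25, 50, seed=2)
        h1 = maslov_sneppen_rewire(g, seed=9)
        h2 = maslov_sneppen_rewire(g, seed=9)
        assert set(h1.edges()) == set(h2.edges())

    def test_p4_reaches_exactly_its_two_configurations(self):
        """Degrees (1,2,2,1) on 4 labeled nodes admit exactly two simple
        graphs (the two paths with the same end nodes); rewiring visits
        both and nothing else."""
        g = nx.path_graph(4)  # 0-1-2-3
        seen = set()
        for seed in range(40):
            h = maslov_sneppen_rewire(g, n_swaps=1, seed=seed)
            seen.add(frozenset(map(frozenset, h.edges())))
        expected = {
            frozenset(map(frozenset, [(0, 1), (1, 2), (2, 3)])),
            frozenset(map(frozenset, [(0, 2), (2, 1), (1, 3)])),
        }
        assert seen == expected


class TestNullEnsemble:
    def test_avgk_degenerate(self):
        g = nx.gnm_random_graph(20, 40, seed=1)
        out = null_ensemble(g, metrics=("avgK",), n=10, seed=0)
        assert out.degenerate == ["avgK"]
        assert np.isnan(out.table.loc["avgK", "z"])

    def test_modular_graph_has_positive_z(self):
        g = nx.connected_caveman_graph(4, 6)
        out = null_ensemble(g, metrics=("modularity",), n=50, seed=0)
        assert out.table.loc["modularity", "z"] > 3

    def test_seeded_summary_identical(self):
        g = nx.gnm_random_graph(20, 45, seed=5)
        a = null_ensemble(g, n=10, seed=11).table
        b = null_ensemble(g, n=10, seed=11).table
        pd.testing.assert_frame_equal(a, b)


class TestKeystones:
    def test_hub_ranked_first(self):
        g = nx.star_graph(8)
        g.add_edges_from([(1, 2), (3, 4)])
        topo = topology(g)
        ks = keystone_species(topo, k=3)
        assert ks.index[0] == 0

    def test_cycle_ties_broken_by_id(self):
        g = nx.cycle_graph(["d", "b", "a", "c"])
        ks = keystone_species(topology(g), k=2)
        assert list(ks.index) == ["a", "b"]

    def test_two_hubs_top_two(self):
        g = nx.Graph()
        for leaf in range(10):
            g.add_edge("hub1", f"l{leaf}")
            g.add_edge("hub2", f"m{leaf}")
        g.add_edge("hub1", "hub2")
        ks = keystone_species(topology(g), k=2)
        assert set(ks.index) == {"hub1", "hub2"}

    def test_fewer_nodes_than_k_warns(self):
        g = nx.path_graph(3)
        with pytest.warns(UserWarning, match="top-10"):
            ks = keystone_species(topology(g), k=10)
        assert len(ks) == 3
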