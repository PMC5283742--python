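"""Passing-network construction and geodesic centralities vs oracles."""

import numpy as np
import pandas as pd
import pytest

from conftest import brute_force_census
from pitchnet.containers import PassLog
from pitchnet.network import (PassingNetwork, betweenness, build_adjacency,
                              centrality_scores, closeness, edge_distances,
                              export_network, import_network,
                              shortest_path_census)

ROSTER = [f"p{i}" for i in range(10)]


def _log(rows):
    df = pd.DataFrame(rows, columns=["time_s", "team", "passer_id",
                                     "receiver_id", "success"])
    return PassLog(df)


def test_empty_log_zero_matrix():
    log = _log([])
    net = build_adjacency(log, ROSTER, "A")
    assert net.A.sum() == 0 and net.A.shape == (10, 10)


def test_adjacency_counts_directed_events():
    log = _log([(1, "A", "p0", "p1", True)] * 3 + [(2, "A", "p1", "p0", True)])
    net = build_adjacency(log, ROSTER, "A")
    assert net.A[0, 1] == 3 and net.A[1, 0] == 1 and net.A.sum() == 4


def test_dyad_combinatorics_ten_players():
    # 10 outfield players: 45 unordered dyads, 90 possible directed entries
    n = len(ROSTER)
    assert n * (n - 1) // 2 == 45
    assert n * (n - 1) == 90


def test_sum_conservation(fixture_match):
    cfg = fixture_match.config
    for team in cfg.teams:
        net = build_adjacency(fixture_match.passes, cfg.roster(team), team)
        assert net.A.sum() == fixture_match.passes.n_successful(team)


@pytest.mark.parametrize("count,conv,expected", [
    (1, "reciprocal", 1.0), (1, "hop", 1.0),
    (4, "reciprocal", 0.25), (4, "hop", 1.0),
    (0, "reciprocal", np.inf), (0, "hop", np.inf),
])
def test_edge_distance_conventions(count, conv, expected):
    A = np.zeros((10, 10), dtype=int)
    A[0, 1] = count
    L = edge_distances(PassingNetwork(ROSTER, A), conv)
    assert L[0, 1] == expected


def test_unknown_convention_rejected():
    net = PassingNetwork(ROSTER, np.zeros((10, 10), int))
    with pytest.raises(ValueError):
        edge_distances(net, "euclid")


def _lengths(n, edges):
    L = np.full((n, n), np.inf)
    np.fill_diagonal(L, 0.0)
    for i, j, w in edges:
        L[i, j] = w
    return L


def test_census_chain():
    L = _lengths(3, [(0, 1, 1.0), (1, 2, 1.0)])
    c = shortest_path_census(L)
    assert c.dist[0, 2] == 2.0
    assert c.sigma[0, 2] == 1
    assert c.sigma_through[1, 0, 2] == 1


def test_census_diamond_tie():
    L = _lengths(4, [(0, 1, 1.0), (0, 2, 1.0), (1, 3, 1.0), (2, 3, 1.0)])
    c = shortest_path_census(L)
    assert c.sigma[0, 3] == 2
    assert c.sigma_through[1, 0, 3] == 1
    assert c.sigma_through[2, 0, 3] == 1
    assert betweenness(c)[1] == pytest.approx(0.5)


def test_negative_length_rejected():
    with pytest.raises(ValueError):
        shortest_path_census(_lengths(2, [(0, 1, -1.0)]))


def test_census_matches_brute_force_on_random_digraphs():
    """Census, closeness and betweenness agree with exhaustive enumeration.

    200 random weighted digraphs with <= 5 nodes, both count->length
    conventions via integer pass counts.
    """
    rng = np.random.default_rng(42)
    for trial in range(200):
        n = int(rng.integers(2, 6))
        A = rng.integers(0, 4, size=(n, n))
        np.fill_diagonal(A, 0)
        net = PassingNetwork([f"v{i}" for i in range(n)], A)
        for conv in ("reciprocal", "hop"):
            L = edge_distances(net, conv)
            c = shortest_path_census(L, conv)
            dist_o, sigma_o, through_o = brute_force_census(L)
            np.testing.assert_allclose(c.dist, dist_o, rtol=1e-9, atol=1e-12)
            np.testing.assert_array_equal(c.sigma, sigma_o)
            np.testing.assert_array_equal(c.sigma_through, through_o)
            # closeness against the oracle's distance matrix
            close, reach = closeness(c)
            for v in range(n):
                d = np.delete(dist_o[v], v)
                finite = d[np.isfinite(d)]
                expected = 1.0 / finite.sum() if finite.sum() > 0 else 0.0
                assert close[v] == pytest.approx(expected)
                assert reach[v] == len(finite)
            # betweenness against oracle path counts
            bet = betweenness(c)
            for v in range(n):
                exp = sum(through_o[v, s, t] / sigma_o[s, t]
                          for s in range(n) for t in range(n)
                          if s != v and t != v and s != t and sigma_o[s, t] > 0)
                assert bet[v] == pytest.approx(exp)


def test_betweenness_matches_networkx():
    """Cross-check against networkx Brandes betweenness on weighted digraphs."""
    import networkx as nx

    rng = np.random.default_rng(7)
    for _ in range(25):
        n = 8
        A = rng.integers(0, 3, size=(n, n))
        np.fill_diagonal(A, 0)
        net = PassingNetwork([str(i) for i in range(n)], A)
        c = shortest_path_census(edge_distances(net, "reciprocal"))
        mine = betweenness(c)
        G = nx.DiGraph()
        G.add_nodes_from(range(n))
        for i in range(n):
            for j in range(n):
                if A[i, j] > 0:
                    G.add_edge(i, j, w=1.0 / A[i, j])
        ref = nx.betweenness_centrality(G, weight="w", normalized=False)
        np.testing.assert_allclose(mine, [ref[i] for i in range(n)], atol=1e-9)


def test_out_star_closeness():
    A = np.zeros((10, 10), int)
    A[0, 1:] = 1
    c = shortest_path_census(edge_distances(PassingNetwork(ROSTER, A)))
    close, reach = closeness(c)
    assert close[0] == pytest.approx(1.0 / 9.0)
    assert reach[0] == 9
    assert close[1] == 0.0 and reach[1] == 0  # no outgoing edges


def test_complete_digraph_zero_betweenness():
    A = np.ones((6, 6), int)
    np.fill_diagonal(A, 0)
    net = PassingNetwork([str(i) for i in range(6)], A)
    c = shortest_path_census(edge_distances(net))
    assert np.allclose(betweenness(c), 0.0)


def test_chain_betweenness_one():
    A = np.zeros((3, 3), int)
    A[0, 1] = A[1, 2] = 1
    c = shortest_path_census(edge_distances(PassingNetwork(list("abc"), A)))
    assert betweenness(c)[1] == pytest.approx(1.0)


def test_scaling_counts_scales_closeness_only():
    """Reciprocal convention: A -> k*A multiplies closeness by k, leaves
    betweenness unchanged."""
    rng = np.random.default_rng(3)
    A = rng.integers(0, 4, size=(7, 7))
    np.fill_diagonal(A, 0)
    nodes = [str(i) for i in range(7)]
    s1 = centrality_scores(PassingNetwork(nodes, A))
    s3 = centrality_scores(PassingNetwork(nodes, 3 * A))
    np.testing.assert_allclose(s3.closeness, 3.0 * s1.closeness, rtol=1e-9)
    np.testing.assert_allclose(s3.betweenness, s1.betweenness, atol=1e-9)


def test_adding_passes_never_lengthens_geodesics():
    rng = np.random.default_rng(4)
    for _ in range(20):
        A = rng.integers(0, 4, size=(6, 6))
        np.fill_diagonal(A, 0)
        nodes = [str(i) for i in range(6)]
        c1 = shortest_path_census(edge_distances(PassingNetwork(nodes, A)))
        # add a pass along an existing edge
        nz = np.argwhere(A > 0)
        if len(nz) == 0:
            continue
        i, j = nz[rng.integers(len(nz))]
        A2 = A.copy()
        A2[i, j] += 1
        c2 = shortest_path_census(edge_distances(PassingNetwork(nodes, A2)))
        assert np.all(c2.dist <= c1.dist + 1e-12)


def test_graphml_round_trip(tmp_path, fixture_match):
    cfg = fixture_match.config
    net = build_adjacency(fixture_match.passes, cfg.roster("A"), "A")
    scores = centrality_scores(net)
    path = tmp_path / "net.graphml"
    export_network(net, scores, path, roles=cfg.roles)
    back = import_network(path)
    order = [back.nodes.index(n) for n in net.nodes]
    np.testing.assert_array_equal(back.A[np.ix_(order, order)], net.A)


def test_graphml_empty_network(tmp_path):
    net = PassingNetwork(ROSTER, np.zeros((10, 10), int))
    path = tmp_path / "empty.graphml"
    export_network(net, None, path)
    back = import_network(path)
    assert len(back.nodes) == 10 and back.A.sum() == 0
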