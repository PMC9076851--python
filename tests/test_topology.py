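"""Topology metrics against brute-force oracles; median-degree hub rule."""

import itertools

import networkx as nx
import pytest

from netpharm import topology
from netpharm.errors import ValidationError
from conftest import HUB_TARGETS, random_graph


# -- independent oracles ----------------------------------------------------

def floyd_warshall_distances(g):
    """Dense all-pairs shortest paths, O(n^3), independent of networkx BFS."""
    nodes = sorted(g.nodes())
    idx = {n: i for i, n in enumerate(nodes)}
    n = len(nodes)
    INF = float("inf")
    d = [[0 if i == j else INF for j in range(n)] for i in range(n)]
    for u, v in g.edges():
        d[idx[u]][idx[v]] = d[idx[v]][idx[u]] = 1
    for k in range(n):
        for i in range(n):
            dik = d[i][k]
            if dik == INF:
                continue
            for j in range(n):
                if dik + d[k][j] < d[i][j]:
                    d[i][j] = dik + d[k][j]
    return nodes, d


def brute_clustering(g):
    """Mean local clustering by explicit neighbor-pair enumeration."""
    total = 0.0
    for v in g.nodes():
        nbrs = list(g.neighbors(v))
        k = len(nbrs)
        if k < 2:
            continue
        links = sum(1 for a, b in itertools.combinations(nbrs, 2) if g.has_edge(a, b))
        total += 2.0 * links / (k * (k - 1))
    return total / g.number_of_nodes()


# -- simplify ---------------------------------------------------------------

def test_simplify_collapses_duplicates_and_self_loops():
    g = topology.simplify_graph([("A", "B"), ("B", "A"), ("C", "C")])
    assert set(g.nodes()) == {"A", "B"}
    assert g.number_of_edges() == 1


def test_simplify_drops_isolated_declared_nodes():
    nodes = [f"N{i}" for i in range(97)]
    edges = [(nodes[i], nodes[i + 1]) for i in range(92)]  # last 4 untouched
    g = topology.simplify_graph(edges, drop_isolated=True, nodes=nodes)
    assert g.number_of_nodes() == 93
    g_keep = topology.simplify_graph(edges, drop_isolated=False, nodes=nodes)
    assert g_keep.number_of_nodes() == 97


def test_simplify_idempotent_on_simple_graph():
    edges = [("A", "B"), ("B", "C"), ("A", "C")]
    g1 = topology.simplify_graph(edges)
    g2 = topology.simplify_graph(list(g1.edges()))
    assert set(g1.edges()) == set(g2.edges())


# -- degrees and median -----------------------------------------------------

def test_degree_table_triangle_and_star():
    tri = topology.degree_table(nx.complete_graph(["A", "B", "C"]))
    assert set(tri) == {2}
    star = topology.degree_table(nx.star_graph(5))
    assert star.max() == 5 and (star == 1).sum() == 5


@pytest.mark.parametrize("degrees,expected", [
    ({"A": 1, "B": 2, "C": 3}, 2.0),
    ({"A": 1, "B": 2, "C": 3, "D": 10}, 2.5),
])
def test_median_degree_conventions(degrees, expected):
    assert topology.median_degree(degrees) == expected


def test_median_degree_empty_raises():
    with pytest.raises(ValidationError):
        topology.median_degree({})


def test_handshake_identity_random_graphs():
    for seed in range(30):
        g = random_graph(seed)
        assert topology.degree_table(g).sum() == 2 * g.number_of_edges()


# -- hub selection ----------------------------------------------------------

def test_select_hubs_star_and_regular():
    star = nx.star_graph(5)  # median degree 1, threshold 2
    assert topology.select_hubs(star) == {0}
    ring = nx.cycle_graph(8)  # 2-regular: 2 > 4 is false
    assert topology.select_hubs(ring) == set()


def test_select_hubs_monotone_in_multiplier():
    for seed in range(20):
        g = random_graph(seed)
        if g.number_of_nodes() == 0:
            continue
        prev = topology.select_hubs(g, multiplier=0.5)
        for mult in (1.0, 1.5, 2.0, 3.0):
            cur = topology.select_hubs(g, multiplier=mult)
            assert cur <= prev
            prev = cur


def test_select_hubs_strict_vs_nonstrict():
    # path P3: degrees 1,2,1; median 1; threshold 2
    g = nx.path_graph(["A", "B", "C"])
    assert topology.select_hubs(g, strict=True) == set()
    assert topology.select_hubs(g, strict=False) == {"B"}


def test_hub_rule_on_bundled_degree_sequence(degree_series):
    """The 93-node degree table yields median 15 and exactly 25 hubs."""
    from netpharm.synthetic_data import graph_from_degree_sequence
    g = graph_from_degree_sequence(degree_series.to_dict())
    assert topology.median_degree(topology.degree_table(g)) == 15
    hubs = topology.select_hubs(g, multiplier=2, strict=True)
    assert hubs == set(HUB_TARGETS)
    # strict and non-strict agree here (min hub degree 31 > threshold 30)
    assert topology.select_hubs(g, multiplier=2, strict=False) == hubs


# -- clustering and path length ---------------------------------------------

def test_clustering_closed_forms():
    assert topology.network_clustering(nx.complete_graph(4)) == 1.0
    assert topology.network_clustering(nx.path_graph(4)) == 0.0


def test_clustering_matches_enumeration_oracle():
    for seed in range(200):
        g = random_graph(seed, n_max=12)
        assert topology.network_clustering(g) == pytest.approx(
            brute_clustering(g), abs=1e-12)


def test_path_length_closed_forms():
    assert topology.characteristic_path_length(nx.complete_graph(25)) == 1.0
    # P4 distances: 1,2,3,1,2,1 -> mean 10/6
    assert topology.characteristic_path_length(nx.path_graph(4)) == pytest.approx(10 / 6)


def test_path_length_matches_floyd_warshall():
    checked = 0
    for seed in range(200):
        g = random_graph(seed, n_max=15)
        if g.number_of_edges() == 0:
            continue
        nodes, d = floyd_warshall_distances(g)
        finite = [d[i][j] for i in range(len(nodes)) for j in range(i + 1, len(nodes))
                  if d[i][j] != float("inf")]
        assert topology.characteristic_path_length(g) == pytest.approx(
            sum(finite) / len(finite))
        checked += 1
    assert checked > 150


def test_path_length_requires_an_edge():
    g = nx.empty_graph(3)
    with pytest.raises(ValidationError):
        topology.characteristic_path_length(g)


# -- topology report --------------------------------------------------------

def test_report_complete_graph():
    rep = topology.topology_report(nx.complete_graph(25))
    assert rep.n_nodes == 25 and rep.network_density == 1.0
    assert rep.network_diameter == 1 and rep.network_radius == 1
    assert rep.characteristic_path_length == 1.0
    assert rep.connected_components == 1 and not rep.largest_component_only


def test_report_path_graph_eccentricities():
    rep = topology.topology_report(nx.path_graph(4))
    assert rep.network_density == 0.5
    assert rep.network_diameter == 3 and rep.network_radius == 2


def test_report_disconnected_flag():
    g = nx.union(nx.complete_graph(["A", "B", "C"]),
                 nx.complete_graph(["D", "E", "F"]))
    rep = topology.topology_report(g)
    assert rep.connected_components == 2
    assert rep.network_diameter == 1
    assert rep.largest_component_only


def test_report_diameter_radius_vs_oracle():
    for seed in range(100):
        g = random_graph(seed, n_max=15)
        if g.number_of_nodes() == 0:
            continue
        rep = topology.topology_report(g)
        largest = max(nx.connected_components(g), key=lambda c: (len(c), sorted(c)))
        sub = g.subgraph(largest)
        if sub.number_of_nodes() == 1:
            assert rep.network_diameter == 0
            continue
        nodes, d = floyd_warshall_distances(sub)
        ecc = [max(row) for row in d]
        assert rep.network_diameter == max(ecc)
        assert rep.network_radius == min(ecc)


# -- induced subgraph -------------------------------------------------------

def test_induced_subgraph_cases():
    tri = nx.complete_graph(["A", "B", "C"])
    sub = topology.induced_subgraph(tri, {"A", "B"})
    assert set(sub.edges()) == {("A", "B")} or set(sub.edges()) == {("B", "A")}
    same = topology.induced_subgraph(tri, {"A", "B", "C"})
    assert set(map(frozenset, same.edges())) == set(map(frozenset, tri.edges()))
    with pytest.warns(UserWarning):
        topology.induced_subgraph(tri, {"A", "Z"})


def test_induced_subgraph_matches_edge_filter():
    import numpy as np
    for seed in range(50):
        g = random_graph(seed)
        rng = np.random.default_rng(seed)
        keep = {n for n in g.nodes() if rng.random() < 0.5}
        sub = topology.induced_subgraph(g, keep)
        expected = {frozenset((u, v)) for u, v in g.edges()
                    if u in keep and v in keep}
        assert set(map(frozenset, sub.edges())) == expected
        assert set(sub.nodes()) == keep & set(g.nodes())
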