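"""PPI-graph simplification, topology metrics, and median-degree hub selection.

The protein-protein interaction (PPI) network is an undirected simple graph
over gene symbols.  The analysis convention follows the Cytoscape
"Analyze Network" tool: the *edgecount* (degree) of a node is the number of
distinct other nodes it interacts with, local clustering of a node with
degree < 2 is 0 and included in the network mean, and on disconnected
graphs the eccentricity-based statistics (diameter, radius, characteristic
path length) are computed on the largest connected component and flagged.

*Hub targets* are selected by the median rule: a node is a hub when its
degree strictly exceeds ``multiplier`` x the median degree of all nodes
(default multiplier 2).  The strictness and multiplier are exposed because
the rule sits at the heart of downstream target prioritization.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable

import networkx as nx
import pandas as pd

from .errors import ValidationError
from .target_sets import GeneSymbol

__all__ = [
    "PPIGraph",
    "TopologyReport",
    "simplify_graph",
    "degree_table",
    "median_degree",
    "select_hubs",
    "network_clustering",
    "characteristic_path_length",
    "topology_report",
    "induced_subgraph",
]

#: A PPI graph is a plain :class:`networkx.Graph` whose nodes are normalized
#: gene symbols.  Simplicity (no self-loops, no parallel edges) is
#: guaranteed by :func:`simplify_graph` and preserved by every operation here.
PPIGraph = nx.Graph


def simplify_graph(
    raw_edges: Iterable[tuple[GeneSymbol, GeneSymbol]],
    drop_isolated: bool = True,
    nodes: Iterable[GeneSymbol] | None = None,
) -> PPIGraph:
    """Build a simple undirected graph from a raw edge list.

    Duplicate edges (in either orientation) are collapsed and self-loops
    removed.  ``nodes``, when given, declares the full node set so that
    nodes untouched by any edge are known; with ``drop_isolated=True``
    (the default, mirroring the "hide disconnected nodes" convention of
    STRING exports) degree-0 nodes are removed.  Idempotent on an
    already-simple graph's edge list.
    """
    g = nx.Graph()
    if nodes is not None:
        g.add_nodes_from(nodes)
    for u, v in raw_edges:
        if u == v:
            continue
        g.add_edge(u, v)
    if drop_isolated:
        g.remove_nodes_from(list(nx.isolates(g)))
    return g


def degree_table(g: PPIGraph) -> pd.Series:
    """Per-node edgecount as a Series (index: symbol), sorted by degree desc.

    Satisfies the handshake identity: the degrees sum to twice the number
    of edges.
    """
    deg = dict(g.degree())
    s = pd.Series(deg, dtype=int, name="edgecount")
    return s.sort_values(ascending=False, kind="stable")


def median_degree(dt: pd.Series | dict) -> float:
    """Sample median of a degree table (mean of middle two for even n)."""
    s = pd.Series(dt, dtype=float)
    if s.empty:
        raise ValidationError("degree table is empty")
    return float(s.median())


def select_hubs(
    g: PPIGraph, multiplier: float = 2.0, strict: bool = True
) -> set[GeneSymbol]:
    """Nodes whose degree exceeds ``multiplier`` x the median degree.

    With ``strict`` (default) the comparison is ``>``; otherwise ``>=``.
    Invariant under node relabeling; the result is a subset of the nodes,
    and raising the multiplier never enlarges it.
    """
    if g.number_of_nodes() == 0:
        raise ValidationError("cannot select hubs from an empty graph")
    dt = degree_table(g)
    threshold = multiplier * median_degree(dt)
    if strict:
        return {v for v, d in dt.items() if d > threshold}
    return {v for v, d in dt.items() if d >= threshold}


def network_clustering(g: PPIGraph) -> float:
    """Mean local clustering coefficient over all nodes.

    Nodes with degree < 2 contribute 0 and are included in the mean
    (NetworkAnalyzer convention).  Always in [0, 1].
    """
    if g.number_of_nodes() == 0:
        raise ValidationError("clustering of an empty graph is undefined")
    return float(nx.average_clustering(g, count_zeros=True))


def _connected_pair_distances(g: PPIGraph):
    """Yield shortest-path lengths for all connected unordered node pairs."""
    for comp in nx.connected_components(g):
        sub = g.subgraph(comp)
        lengths = dict(nx.all_pairs_shortest_path_length(sub))
        nodes = sorted(comp)
        for i, u in enumerate(nodes):
            for v in nodes[i + 1:]:
                yield lengths[u][v]


def characteristic_path_length(g: PPIGraph) -> float:
    """Mean shortest-path length over all connected unordered node pairs.

    Pairs in different components are excluded; a complete graph gives
    exactly 1.0.  Raises if the graph has no edges (no connected pair
    exists).
    """
    if g.number_of_edges() == 0:
        raise ValidationError("characteristic path length needs at least one edge")
    total = 0
    npairs = 0
    for d in _connected_pair_distances(g):
        total += d
        npairs += 1
    return total / npairs


@dataclass(frozen=True)
class TopologyReport:
    """Summary topology statistics of a PPI network.

    When the graph is disconnected, ``network_diameter``, ``network_radius``
    and ``characteristic_path_length`` refer to the largest connected
    component and ``largest_component_only`` is set.
    """

    n_nodes: int
    n_edges: int
    clustering_coefficient: float
    network_diameter: int
    network_radius: int
    network_density: float
    characteristic_path_length: float
    avg_neighbors: float
    connected_components: int
    largest_component_only: bool = False

    def to_series(self) -> pd.Series:
        return pd.Series(
            {
                "n_nodes": self.n_nodes,
                "n_edges": self.n_edges,
                "clustering_coefficient": self.clustering_coefficient,
                "network_diameter": self.network_diameter,
                "network_radius": self.network_radius,
                "network_density": self.network_density,
                "characteristic_path_length": self.characteristic_path_length,
                "avg_neighbors": self.avg_neighbors,
                "connected_components": self.connected_components,
                "largest_component_only": self.largest_component_only,
            }
        )


def topology_report(g: PPIGraph) -> TopologyReport:
    """Compute the full panel of topology statistics for a PPI network."""
    n = g.number_of_nodes()
    if n == 0:
        raise ValidationError("topology report of an empty graph is undefined")
    m = g.number_of_edges()
    ncomp = nx.number_connected_components(g)
    density = 0.0 if n < 2 else 2.0 * m / (n * (n - 1))
    avg_neighbors = 0.0 if n == 0 else 2.0 * m / n
    largest = max(nx.connected_components(g), key=lambda c: (len(c), sorted(c)))
    sub = g.subgraph(largest)
    if sub.number_of_nodes() > 1:
        ecc = nx.eccentricity(sub)
        diameter = max(ecc.values())
        radius = min(ecc.values())
        cpl = characteristic_path_length(sub)
    else:
        diameter = radius = 0
        cpl = 0.0
    return TopologyReport(
        n_nodes=n,
        n_edges=m,
        clustering_coefficient=network_clustering(g),
        network_diameter=int(diameter),
        network_radius=int(radius),
        network_density=density,
        characteristic_path_length=cpl,
        avg_neighbors=avg_neighbors,
        connected_components=ncomp,
        largest_component_only=ncomp > 1,
    )


def induced_subgraph(g: PPIGraph, keep: set[GeneSymbol]) -> PPIGraph:
    """Subgraph induced by ``keep``; symbols absent from g warn and are ignored."""
    missing = set(keep) - set(g.nodes())
    if missing:
        warnings.warn(
            f"{len(missing)} symbol(s) not in the graph were ignored "
            f"(e.g. {sorted(missing)[:3]})",
            stacklevel=2,
        )
    return nx.Graph(g.subgraph(set(keep) & set(g.nodes())))
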