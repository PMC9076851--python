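"""Layered (multipartite) networks: compound-target, compound-target-disease,
and compound-hubtarget-pathway constructions, plus core-compound selection.

Nodes carry a *layer* label (herb / compound / target / disease / pathway)
and edges a *relation* determined by the layer pair of their endpoints.
Intra-layer edges are never produced: protein-protein interactions live in
:mod:`netpharm.topology`, not here.  The constructions mirror the standard
figures of a network-pharmacology study: the bipartite compound-target map,
the herb-compound-target-disease network, and the compound-hubtarget-pathway
network from which *core compounds* are selected by the same
median-edgecount rule used for hub targets.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import networkx as nx
import pandas as pd

from .enrichment import AnnotationCollection
from .errors import ValidationError
from .target_sets import GeneSymbol, TargetSet
from .topology import median_degree

__all__ = [
    "LAYERS",
    "RELATIONS",
    "LayeredNetwork",
    "CompoundTargetMap",
    "build_compound_target",
    "build_compound_target_disease",
    "build_compound_hub_pathway",
    "layer_degree",
    "select_core_compounds",
]

LAYERS = ("herb", "compound", "target", "disease", "pathway")

#: Admissible layer pairs and the relation label each carries.
RELATIONS: dict[frozenset, str] = {
    frozenset({"compound", "target"}): "compound-target",
    frozenset({"target", "disease"}): "target-disease",
    frozenset({"herb", "compound"}): "herb-compound",
    frozenset({"target", "pathway"}): "target-pathway",
}


class LayeredNetwork:
    """A typed multi-layer network backed by a :class:`networkx.Graph`.

    Every node has a ``layer`` attribute from :data:`LAYERS`; every edge a
    ``relation`` attribute determined by its endpoints' layer pair.  Adding
    an intra-layer edge, an edge over an unsupported layer pair, or reusing
    a node name across layers raises :class:`ValidationError`.
    """

    def __init__(self):
        self.graph = nx.Graph()

    # -- construction -----------------------------------------------------
    def add_node(self, name: str, layer: str) -> None:
        if layer not in LAYERS:
            raise ValidationError(f"unknown layer {layer!r}; expected one of {LAYERS}")
        existing = self.graph.nodes.get(name)
        if existing is not None and existing.get("layer") != layer:
            raise ValidationError(
                f"node {name!r} already present in layer {existing.get('layer')!r}"
            )
        self.graph.add_node(name, layer=layer)

    def add_edge(self, u: str, v: str) -> None:
        for name in (u, v):
            if name not in self.graph:
                raise ValidationError(f"add_edge: unknown node {name!r}; add it first")
        lu = self.graph.nodes[u]["layer"]
        lv = self.graph.nodes[v]["layer"]
        if lu == lv:
            raise ValidationError(f"intra-layer edge {u!r}-{v!r} in layer {lu!r}")
        relation = RELATIONS.get(frozenset({lu, lv}))
        if relation is None:
            raise ValidationError(f"no relation defined for layer pair ({lu}, {lv})")
        self.graph.add_edge(u, v, relation=relation)

    # -- queries ----------------------------------------------------------
    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def layers(self) -> set[str]:
        return {d["layer"] for _, d in self.graph.nodes(data=True)}

    def nodes_in_layer(self, layer: str) -> set[str]:
        return {n for n, d in self.graph.nodes(data=True) if d["layer"] == layer}

    def layer_of(self, name: str) -> str:
        return self.graph.nodes[name]["layer"]

    def edges(self):
        """Iterate (u, v, relation) triples."""
        for u, v, d in self.graph.edges(data=True):
            yield u, v, d["relation"]


@dataclass(frozen=True)
class CompoundTargetMap:
    """Mapping compound id -> set of predicted target gene symbols."""

    entries: dict[str, frozenset[GeneSymbol]]

    @property
    def compounds(self) -> list[str]:
        return sorted(self.entries)

    def target_union(self) -> frozenset[GeneSymbol]:
        if not self.entries:
            return frozenset()
        return frozenset().union(*self.entries.values())

    def n_links(self) -> int:
        return sum(len(ts) for ts in self.entries.values())


def build_compound_target(cmap: CompoundTargetMap) -> LayeredNetwork:
    """Bipartite compound-target network.

    Node count = #compounds + #distinct targets; edge count = total number
    of (compound, target) links.
    """
    if not cmap.entries:
        raise ValidationError("compound-target map is empty")
    net = LayeredNetwork()
    for compound in cmap.compounds:
        net.add_node(compound, "compound")
    for target in sorted(cmap.target_union()):
        net.add_node(target, "target")
    for compound in cmap.compounds:
        for target in sorted(cmap.entries[compound]):
            net.add_edge(compound, target)
    return net


def build_compound_target_disease(
    cmap: CompoundTargetMap,
    common: TargetSet | frozenset[GeneSymbol],
    herb_label: str = "herb",
    disease_label: str = "disease",
) -> LayeredNetwork:
    """Herb-compound-target-disease network restricted to the common targets.

    The target layer is the compound/disease common target set; a single
    herb node links to every compound and a single disease node to every
    common target.  Compounds with no common target are retained, connected
    only through the herb node.  Node count = #compounds + #common + 2.
    """
    symbols = frozenset(common.symbols if isinstance(common, TargetSet) else common)
    if not cmap.entries:
        raise ValidationError("compound-target map is empty")
    if not symbols:
        raise ValidationError("common target set is empty")
    stray = symbols - cmap.target_union()
    if stray:
        warnings.warn(
            f"{len(stray)} common target(s) absent from the compound-target map "
            f"were dropped (e.g. {sorted(stray)[:3]})",
            stacklevel=2,
        )
        symbols = symbols - stray
        if not symbols:
            raise ValidationError("no common target remains after dropping strays")
    net = LayeredNetwork()
    net.add_node(herb_label, "herb")
    net.add_node(disease_label, "disease")
    for compound in cmap.compounds:
        net.add_node(compound, "compound")
        net.add_edge(herb_label, compound)
    for target in sorted(symbols):
        net.add_node(target, "target")
        net.add_edge(target, disease_label)
    for compound in cmap.compounds:
        for target in sorted(cmap.entries[compound] & symbols):
            net.add_edge(compound, target)
    return net


def build_compound_hub_pathway(
    cmap: CompoundTargetMap,
    hubs: set[GeneSymbol],
    pathways: AnnotationCollection,
) -> LayeredNetwork:
    """Compound-hubtarget-pathway network.

    The target layer keeps only hubs annotated to at least one pathway;
    the pathway layer holds every term of the collection; compound-target
    edges come from the map (restricted to retained hubs) and
    target-pathway edges from term membership.  Node count =
    #compounds + #retained hubs + #pathways.
    """
    if not cmap.entries:
        raise ValidationError("compound-target map is empty")
    if not len(pathways):
        raise ValidationError("pathway collection is empty")
    annotated = pathways.gene_union()
    retained = sorted(set(hubs) & annotated)
    if not retained:
        raise ValidationError("no hub target appears in any pathway gene set")
    net = LayeredNetwork()
    for compound in cmap.compounds:
        net.add_node(compound, "compound")
    for target in retained:
        net.add_node(target, "target")
    for term in pathways:
        net.add_node(term.term_id, "pathway")
    retained_set = frozenset(retained)
    for compound in cmap.compounds:
        for target in sorted(cmap.entries[compound] & retained_set):
            net.add_edge(compound, target)
    for term in pathways:
        for target in sorted(term.genes & retained_set):
            net.add_edge(target, term.term_id)
    return net


def layer_degree(net: LayeredNetwork, layer: str) -> pd.Series:
    """Edgecount (across all relations) of every node in one layer."""
    if layer not in net.layers():
        raise ValidationError(f"layer {layer!r} not present; have {sorted(net.layers())}")
    nodes = sorted(net.nodes_in_layer(layer))
    s = pd.Series({n: net.graph.degree(n) for n in nodes}, dtype=int, name="edgecount")
    return s.sort_values(ascending=False, kind="stable")


def select_core_compounds(
    net: LayeredNetwork,
    multiplier: float = 2.0,
    strict: bool = True,
    median_scope: str = "all_nodes",
) -> set[str]:
    """Compounds whose edgecount exceeds ``multiplier`` x a median edgecount.

    ``median_scope`` chooses the population whose median sets the
    threshold: ``'all_nodes'`` (every node of the network) or
    ``'compound_layer'`` (compound nodes only).  ``strict`` toggles > vs >=.
    Both switches are exposed because the median rule is commonly stated
    without fixing either convention.
    """
    if median_scope not in ("all_nodes", "compound_layer"):
        raise ValidationError(
            f"median_scope must be 'all_nodes' or 'compound_layer', got {median_scope!r}"
        )
    compounds = layer_degree(net, "compound")  # raises if layer missing/empty
    if median_scope == "all_nodes":
        degrees = pd.Series(dict(net.graph.degree()), dtype=int)
    else:
        degrees = compounds
    threshold = multiplier * median_degree(degrees)
    if strict:
        return {c for c, d in compounds.items() if d > threshold}
    return {c for c, d in compounds.items() if d >= threshold}
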