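"""Shared fixtures: bundled reference tables and small random-graph helpers."""

import networkx as nx
import numpy as np
import pytest

from netpharm import datasets

#: the 25 hub targets of the bundled PPI degree table (degree > 2 x median 15)
HUB_TARGETS = frozenset({
    "AKT1", "TNF", "VEGFA", "IL6", "MAPK3", "CASP3", "IL1B", "TP53", "JUN",
    "EGFR", "PTGS2", "HSP90AA1", "ESR1", "MMP9", "HRAS", "NOS3", "SIRT1",
    "BCL2L1", "RELA", "MAPK1", "MAPK14", "MMP2", "GSK3B", "CASP9", "MCL1",
})


@pytest.fixture(scope="session")
def degree_series():
    return datasets.ppi_degree_series()


@pytest.fixture(scope="session")
def pathway_collection():
    return datasets.load_pathway_collection()


@pytest.fixture(scope="session")
def energy_rows():
    return datasets.load_energy_components()


def random_graph(seed: int, n_max: int = 20) -> nx.Graph:
    """Small Erdos-Renyi graph with letter-number node labels."""
    rng = np.random.default_rng(seed)
    n = int(rng.integers(2, n_max + 1))
    p = float(rng.uniform(0.1, 0.7))
    g = nx.gnp_random_graph(n, p, seed=int(rng.integers(2**31)))
    return nx.relabel_nodes(g, {i: f"N{i:02d}" for i in g.nodes()})
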