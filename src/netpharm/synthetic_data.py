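"""Seeded generators of synthetic inputs with planted ground truth.

Network-pharmacology inputs normally come from web servers (target
prediction, disease-gene databases, STRING, annotation servers).  This
module generates statistically analogous inputs offline, with *planted*
structure so that every pipeline stage has a known right answer:

* a compound-target map whose target union has a prescribed size, with
  both shared and compound-unique targets;
* a disease gene set with an exactly planted intersection against the
  compound-target union;
* a PPI graph with a near-regular background and planted high-degree hubs
  that the median-degree rule must recover;
* annotation collections with one planted over-represented term;
* MM-PBSA-like energy tables whose totals are exact component sums and
  whose residue profiles plant known critical residues.

Defaults reproduce the scale of the motivating study: 12 compounds,
a 161-target union, 4124 disease genes with a planted overlap of 97.

Every generator draws from its own named pseudo-random stream derived from
``(seed, crc32(generator name))``, so adding a generator never perturbs
the output of existing ones.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, replace
from math import ceil
from typing import Sequence

import networkx as nx
import numpy as np

from .binding_analysis import DockScore, EnergyComponents, ResidueEnergyProfile
from .enrichment import AnnotationCollection, AnnotationTerm, Category
from .errors import ValidationError
from .networks import CompoundTargetMap
from .target_sets import TargetSet
from .topology import PPIGraph, degree_table

__all__ = [
    "SynthConfig",
    "PLANTED_TERM_ID",
    "gen_compound_target_map",
    "gen_disease_set",
    "gen_ppi_with_planted_hubs",
    "planted_hubs",
    "graph_from_degree_sequence",
    "gen_annotations",
    "gen_dock_scores",
    "gen_energy_tables",
]

#: term id of the planted over-represented term in generated collections
PLANTED_TERM_ID = "SYNT_PLANTED"


@dataclass(frozen=True)
class SynthConfig:
    """Configuration of all synthetic generators.

    The compound/disease scale defaults mirror the motivating study
    (12 compounds, 161-target union, 4124 disease genes, 97 planted
    common targets).  The PPI defaults (100 background nodes of mean
    degree 6 with 5 planted hubs) define the standard hub-recovery
    experiment; the enrichment defaults (50 terms over a 2000-gene
    background, planted term covering 80% of the query) define the
    standard planted-term recovery experiment.
    """

    seed: int = 0
    # compound / disease target sets
    n_compounds: int = 12
    n_targets: int = 161
    n_disease: int = 4124
    planted_overlap: int = 97
    links_per_target_mean: float = 3.4  # mean compounds hitting one target
    # PPI with planted hubs
    n_background_nodes: int = 100
    n_planted_hubs: int = 5
    background_degree: int = 6
    # annotation collections
    n_terms: int = 50
    term_size_range: tuple[int, int] = (10, 60)
    planted_effect: float = 0.8
    background_size: int = 2000
    # energy tables
    n_complexes: int = 4
    n_residues: int = 200
    n_critical: int = 3

    def rng(self, stream: str) -> np.random.Generator:
        """Named pseudo-random stream: seeded by (seed, crc32(stream))."""
        return np.random.default_rng(
            [int(self.seed) & 0x7FFFFFFF, zlib.crc32(stream.encode())]
        )

    def with_seed(self, seed: int) -> "SynthConfig":
        return replace(self, seed=seed)


# ---------------------------------------------------------------------------
# compound-target map and disease set
# ---------------------------------------------------------------------------

def gen_compound_target_map(cfg: SynthConfig) -> CompoundTargetMap:
    """Compound-target map with exactly ``n_targets`` distinct targets.

    Each target is linked to 1 + Poisson(links_per_target_mean - 1)
    compounds (capped at n_compounds), giving the heavy overlap structure
    of multi-compound target prediction.  When n_compounds >= 2 the first
    two targets are forced unique/shared so both kinds always occur.
    """
    if cfg.n_compounds < 1:
        raise ValidationError("need at least one compound")
    if cfg.n_targets < 2 and cfg.n_compounds >= 2:
        raise ValidationError("need at least two targets to plant shared+unique")
    rng = cfg.rng("compound_target_map")
    compounds = [f"compound{i + 1:02d}" for i in range(cfg.n_compounds)]
    targets = [f"TG{i + 1:04d}" for i in range(cfg.n_targets)]
    lam = max(cfg.links_per_target_mean - 1.0, 0.0)
    entries: dict[str, set[str]] = {c: set() for c in compounds}
    for j, t in enumerate(targets):
        if cfg.n_compounds >= 2 and j == 0:
            chosen = [0]            # forced compound-unique target
        elif cfg.n_compounds >= 2 and j == 1:
            chosen = [0, 1]         # forced shared target
        else:
            k = min(1 + int(rng.poisson(lam)), cfg.n_compounds)
            chosen = rng.choice(cfg.n_compounds, size=k, replace=False)
        for i in chosen:
            entries[compounds[int(i)]].add(t)
    return CompoundTargetMap({c: frozenset(ts) for c, ts in entries.items()})


def gen_disease_set(cfg: SynthConfig, compound_union: TargetSet | frozenset) -> TargetSet:
    """Disease gene set of size ``n_disease`` with an exactly planted overlap.

    Exactly ``planted_overlap`` symbols are drawn from the compound-target
    union; the remainder are fresh disease-only symbols.
    """
    union = sorted(compound_union.symbols if isinstance(compound_union, TargetSet)
                   else compound_union)
    if cfg.planted_overlap > min(len(union), cfg.n_disease):
        raise ValidationError(
            f"planted_overlap={cfg.planted_overlap} exceeds "
            f"min(|union|={len(union)}, n_disease={cfg.n_disease})"
        )
    rng = cfg.rng("disease_set")
    overlap = rng.choice(len(union), size=cfg.planted_overlap, replace=False)
    symbols = {union[int(i)] for i in overlap}
    n_rest = cfg.n_disease - cfg.planted_overlap
    symbols.update(f"DZ{i + 1:05d}" for i in range(n_rest))
    return TargetSet(frozenset(symbols), frozenset({"synthetic-disease"}))


# ---------------------------------------------------------------------------
# PPI graphs
# ---------------------------------------------------------------------------

def gen_ppi_with_planted_hubs(
    cfg: SynthConfig, labels: Sequence[str] | None = None
) -> PPIGraph:
    """PPI graph with a near-regular background and planted high-degree hubs.

    The background is a random ``background_degree``-regular graph (degrees
    exactly d, mimicking the tight degree concentration of non-hub
    proteins).  Planted hubs form a clique among themselves — dense hub
    cores are characteristic of real PPI networks — and each additionally
    attaches to 4d + 1 uniformly chosen background nodes, so every hub's
    degree (k - 1 + 4d + 1) strictly exceeds four times the background
    median degree d, well clear of the 2x-median selection threshold.

    ``labels``, when given, must supply ``n_background_nodes +
    n_planted_hubs`` node names; hub identities are then drawn uniformly
    from the labels.  Nodes carry a boolean ``planted`` attribute
    (see :func:`planted_hubs`).
    """
    n_b, k, d = cfg.n_background_nodes, cfg.n_planted_hubs, cfg.background_degree
    if k < 0 or n_b < 1:
        raise ValidationError("need n_planted_hubs >= 0 and n_background_nodes >= 1")
    if k and k >= n_b:
        raise ValidationError("n_planted_hubs must be smaller than n_background_nodes")
    if d >= n_b:
        raise ValidationError(f"background_degree={d} needs > {d} background nodes")
    if (n_b * d) % 2:
        raise ValidationError("n_background_nodes * background_degree must be even")
    attach = 4 * d + 1
    if attach > n_b:
        raise ValidationError(
            f"hub attachment degree {attach} exceeds background size {n_b}"
        )
    rng = cfg.rng("ppi_planted_hubs")
    if labels is None:
        background = [f"BG{i + 1:03d}" for i in range(n_b)]
        hubs = [f"HUB{i + 1:02d}" for i in range(k)]
    else:
        labels = list(labels)
        if len(labels) != n_b + k:
            raise ValidationError(
                f"labels must have {n_b + k} entries, got {len(labels)}"
            )
        if len(set(labels)) != len(labels):
            raise ValidationError("labels must be unique")
        order = rng.permutation(len(labels))
        hubs = [labels[int(i)] for i in order[:k]]
        background = [labels[int(i)] for i in order[k:]]
    reg_seed = int(rng.integers(2**31))
    reg = nx.random_regular_graph(d, n_b, seed=reg_seed)
    g: PPIGraph = nx.Graph()
    g.add_nodes_from(background, planted=False)
    g.add_nodes_from(hubs, planted=True)
    for u, v in reg.edges():
        g.add_edge(background[u], background[v])
    for i, h in enumerate(hubs):
        for other in hubs[i + 1:]:
            g.add_edge(h, other)
        chosen = rng.choice(n_b, size=attach, replace=False)
        for j in chosen:
            g.add_edge(h, background[int(j)])
    return g


def planted_hubs(g: PPIGraph) -> set[str]:
    """The planted hub ids recorded on a generated PPI graph."""
    return {n for n, d in g.nodes(data=True) if d.get("planted")}


def graph_from_degree_sequence(degrees: dict[str, int]) -> PPIGraph:
    """Deterministic Havel-Hakimi realization of a labeled degree sequence.

    Ties are broken by symbol order, so the construction is reproducible.
    Only degree-derived statistics of the result are meaningful (the true
    edge set of a network with this degree sequence is not unique).

    Raises
    ------
    ValidationError
        If the sequence is not graphical (Erdős–Gallai condition fails).
    """
    if not degrees:
        raise ValidationError("degree sequence is empty")
    if any(d < 0 for d in degrees.values()):
        raise ValidationError("degrees must be non-negative")
    if not nx.is_graphical(list(degrees.values())):
        raise ValidationError(
            "degree sequence is not graphical (fails the Erdős–Gallai condition)"
        )
    remaining = dict(degrees)
    g: PPIGraph = nx.Graph()
    g.add_nodes_from(degrees)
    while True:
        order = sorted(remaining, key=lambda s: (-remaining[s], s))
        pivot = order[0]
        d = remaining[pivot]
        if d == 0:
            break
        partners = order[1:d + 1]
        if len(partners) < d or remaining[partners[-1]] == 0:
            raise ValidationError("degree sequence exhausted mid-construction")
        for p in partners:
            g.add_edge(pivot, p)
            remaining[p] -= 1
        remaining[pivot] = 0
    got = degree_table(g).to_dict()
    if got != {s: int(d) for s, d in degrees.items()}:
        raise ValidationError("Havel-Hakimi construction failed to realize sequence")
    return g


# ---------------------------------------------------------------------------
# annotation collections
# ---------------------------------------------------------------------------

def gen_annotations(cfg: SynthConfig, query: TargetSet | frozenset) -> AnnotationCollection:
    """Annotation collection with one planted over-represented term.

    ``n_terms`` decoy terms draw their genes uniformly from a background
    of ``background_size`` genes containing the query; the planted term
    (id :data:`PLANTED_TERM_ID`) contains ``ceil(planted_effect * |query|)``
    query genes plus background filler.  The collection's background is
    the full pool, so decoy overlaps stay at chance level.
    """
    if not (0.0 < cfg.planted_effect <= 1.0):
        raise ValidationError("planted_effect must lie in (0, 1]")
    lo, hi = cfg.term_size_range
    if not (1 <= lo <= hi):
        raise ValidationError(f"invalid term_size_range {cfg.term_size_range}")
    qset = sorted(query.symbols if isinstance(query, TargetSet) else query)
    if not qset:
        raise ValidationError("query is empty")
    pool = list(qset)
    i = 0
    while len(pool) < max(cfg.background_size, len(qset)):
        i += 1
        sym = f"BGG{i:05d}"
        if sym not in query:
            pool.append(sym)
    pool = sorted(pool)
    non_query = sorted(set(pool) - set(qset))
    if hi > len(pool):
        raise ValidationError(
            f"term_size_range max {hi} exceeds background size {len(pool)}"
        )
    rng = cfg.rng("annotations")
    terms: list[AnnotationTerm] = []
    k_planted = ceil(cfg.planted_effect * len(qset))
    size_planted = max(int(rng.integers(lo, hi + 1)), k_planted)
    planted_query = [qset[int(i)] for i in
                     rng.choice(len(qset), size=k_planted, replace=False)]
    filler_n = size_planted - k_planted
    if filler_n > len(non_query):
        raise ValidationError("background too small for the planted term filler")
    filler = [non_query[int(i)] for i in
              rng.choice(len(non_query), size=filler_n, replace=False)]
    terms.append(
        AnnotationTerm(
            term_id=PLANTED_TERM_ID,
            description="synthetic planted enriched term",
            category=Category.pathway,
            genes=frozenset(planted_query) | frozenset(filler),
        )
    )
    for t in range(cfg.n_terms):
        size = int(rng.integers(lo, hi + 1))
        genes = [pool[int(i)] for i in rng.choice(len(pool), size=size, replace=False)]
        terms.append(
            AnnotationTerm(
                term_id=f"SYNT{t + 1:03d}",
                description=f"synthetic decoy term {t + 1}",
                category=Category.pathway,
                genes=frozenset(genes),
            )
        )
    return AnnotationCollection(terms, background=frozenset(pool))


# ---------------------------------------------------------------------------
# docking and energy tables
# ---------------------------------------------------------------------------

def gen_dock_scores(
    cfg: SynthConfig, compounds: Sequence[str], targets: Sequence[str]
) -> list[DockScore]:
    """Fully populated docking-score matrix with scores uniform in [2, 9]."""
    if not compounds or not targets:
        raise ValidationError("need at least one compound and one target")
    rng = cfg.rng("dock_scores")
    out = []
    for c in compounds:
        for t in targets:
            out.append(DockScore(c, t, round(float(rng.uniform(2.0, 9.0)), 2)))
    return out


def gen_energy_tables(
    cfg: SynthConfig,
) -> tuple[list[EnergyComponents], list[ResidueEnergyProfile]]:
    """MM-PBSA-like component tables and residue decompositions.

    Components are drawn in realistic ranges (vdW in [-160, -60], elec in
    [-120, -10], polar in [50, 190], SASA in [-20, -14] kJ/mol, each
    rounded to 3 decimals) and the total is set to the *exact* component
    sum.  Each residue profile has ``n_residues`` residues with
    contributions in [-3, 3] except ``n_critical`` planted critical
    residues (ids prefixed ``HOT``) with magnitudes in [5.5, 15].
    """
    if cfg.n_complexes < 1:
        raise ValidationError("need at least one complex")
    if cfg.n_critical > cfg.n_residues:
        raise ValidationError("n_critical cannot exceed n_residues")
    rng = cfg.rng("energy_tables")
    components: list[EnergyComponents] = []
    profiles: list[ResidueEnergyProfile] = []
    for i in range(cfg.n_complexes):
        cid = f"CPX{i + 1:02d}"
        vdw = round(float(rng.uniform(-160.0, -60.0)), 3)
        elec = round(float(rng.uniform(-120.0, -10.0)), 3)
        polar = round(float(rng.uniform(50.0, 190.0)), 3)
        sasa = round(float(rng.uniform(-20.0, -14.0)), 3)
        components.append(
            EnergyComponents(cid, e_vdw=vdw, e_elec=elec, g_polar=polar,
                             g_sasa=sasa, g_bind=vdw + elec + polar + sasa)
        )
        crit_idx = set(int(j) for j in
                       rng.choice(cfg.n_residues, size=cfg.n_critical, replace=False))
        contributions: dict[str, float] = {}
        for j in range(cfg.n_residues):
            if j in crit_idx:
                mag = float(rng.uniform(5.5, 15.0))
                sign = 1.0 if rng.random() < 0.5 else -1.0
                contributions[f"HOT{j + 1:03d}"] = round(sign * mag, 3)
            else:
                contributions[f"RES{j + 1:03d}"] = round(float(rng.uniform(-3.0, 3.0)), 3)
        profiles.append(ResidueEnergyProfile(cid, contributions))
    return components, profiles
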