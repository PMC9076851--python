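"""Hypergeometric/EASE tails vs enumeration, BH step-up, proportions."""

import itertools
from math import comb

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from netpharm.enrichment import (AnnotationCollection, AnnotationTerm,
                                 Category, EnrichmentRow, bh_adjust,
                                 category_proportions, ease_tail, enrich,
                                 filter_and_rank, hypergeom_tail)
from netpharm.errors import ValidationError
from conftest import HUB_TARGETS


# -- independent oracles ----------------------------------------------------

def tail_by_enumeration(k, K, n, N):
    """P(X >= k) by counting all C(N, n) draws explicitly."""
    marked = set(range(K))
    hits = sum(1 for draw in itertools.combinations(range(N), n)
               if len(marked & set(draw)) >= k)
    return hits / comb(N, n)


def bh_stepup(p):
    """Literal Benjamini-Hochberg step-up definition."""
    m = len(p)
    order = sorted(range(m), key=lambda i: p[i])
    adj = [0.0] * m
    running = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, p[i] * m / rank)
        adj[i] = min(running, 1.0)
    return adj


# -- hypergeometric tails ---------------------------------------------------

def test_tail_trivial_values():
    assert hypergeom_tail(0, 5, 4, 10) == 1.0
    assert hypergeom_tail(5, 5, 10, 10) == pytest.approx(1.0)  # n = N draws all


def test_tail_small_case_exact():
    # N=10, K=5, n=4, k=4: C(5,4)/C(10,4) = 5/210
    assert hypergeom_tail(4, 5, 4, 10) == pytest.approx(5 / 210)
    assert hypergeom_tail(4, 5, 4, 10) == pytest.approx(tail_by_enumeration(4, 5, 4, 10))


def test_tail_matches_enumeration_for_small_N():
    rng = np.random.default_rng(0)
    for _ in range(60):
        N = int(rng.integers(2, 13))
        K = int(rng.integers(0, N + 1))
        n = int(rng.integers(1, N + 1))
        k = int(rng.integers(0, min(K, n) + 1))
        assert hypergeom_tail(k, K, n, N) == pytest.approx(
            tail_by_enumeration(k, K, n, N), abs=1e-12)


def test_tail_nonincreasing_in_k():
    K, n, N = 30, 20, 100
    values = [hypergeom_tail(k, K, n, N) for k in range(0, min(K, n) + 1)]
    assert all(a >= b for a, b in zip(values, values[1:]))


def test_pmf_sums_to_one():
    from scipy.stats import hypergeom
    for (N, K, n) in [(10, 5, 4), (50, 20, 10), (2000, 40, 25)]:
        lo, hi = max(0, n + K - N), min(n, K)
        total = sum(hypergeom.pmf(k, N, K, n) for k in range(lo, hi + 1))
        assert total == pytest.approx(1.0, abs=1e-12)


def test_tail_argument_validation():
    with pytest.raises(ValidationError):
        hypergeom_tail(5, 4, 4, 10)  # k > K
    with pytest.raises(ValidationError):
        hypergeom_tail(1, 11, 4, 10)  # K > N


def test_ease_is_tail_with_one_gene_removed():
    # enumeration: tail at k=3 for (K=5, n=4, N=10) = 55/210
    assert ease_tail(4, 5, 4, 10) == pytest.approx(55 / 210)
    assert ease_tail(1, 5, 4, 10) == 1.0  # reduces to k=0
    assert ease_tail(0, 5, 4, 10) == 1.0
    for k in range(5):
        assert ease_tail(k, 5, 4, 10) >= hypergeom_tail(k, 5, 4, 10)


# -- BH adjustment ----------------------------------------------------------

def test_bh_hand_example():
    assert bh_adjust([0.01, 0.02, 0.03]) == pytest.approx([0.03, 0.03, 0.03])
    assert bh_adjust([0.5]) == [0.5]
    assert bh_adjust([0.2, 0.2, 0.2]) == pytest.approx([0.2, 0.2, 0.2])


@settings(max_examples=100, deadline=None)
@given(st.lists(st.floats(0, 1, allow_nan=False), min_size=1, max_size=30))
def test_bh_matches_stepup_definition(p):
    adj = bh_adjust(p)
    assert adj == pytest.approx(bh_stepup(p), abs=1e-12)
    assert all(a >= r for a, r in zip(adj, p))
    # order-preserving with respect to raw ranks
    pairs = sorted(zip(p, adj))
    assert all(a1 <= a2 + 1e-12 for (_, a1), (_, a2) in zip(pairs, pairs[1:]))


def test_bh_rejects_out_of_range():
    with pytest.raises(ValidationError):
        bh_adjust([0.5, 1.2])


# -- enrich -----------------------------------------------------------------

def test_enrich_saturated_query_gives_p_one():
    term = AnnotationTerm("T1", "d", Category.pathway, frozenset({"A", "B", "C"}))
    col = AnnotationCollection([term])
    rows = enrich(frozenset({"A", "B", "C"}), col)
    assert len(rows) == 1
    r = rows[0]
    assert r.k == r.K == r.n == r.N == 3
    assert r.p_raw == pytest.approx(1.0)


def test_enrich_planted_term_ranks_first():
    """A 40-gene term holding 20 of a 25-gene query in a 2000-gene background
    must dominate the decoys' p-values."""
    rng = np.random.default_rng(1)
    background = [f"B{i:04d}" for i in range(1975)] + [f"Q{i:02d}" for i in range(25)]
    query = frozenset(f"Q{i:02d}" for i in range(25))
    planted = frozenset(list(query)[:20]) | frozenset(f"B{i:04d}" for i in range(20))
    terms = [AnnotationTerm("PL", "planted", Category.pathway, planted)]
    for t in range(30):
        genes = rng.choice(background, size=40, replace=False)
        terms.append(AnnotationTerm(f"D{t}", "decoy", Category.pathway,
                                    frozenset(genes)))
    col = AnnotationCollection(terms, background=frozenset(background))
    rows = enrich(query, col)
    best = min(rows, key=lambda r: r.p_raw)
    assert best.term_id == "PL"
    assert best.p_raw < 1e-20


def test_enrich_hub_overlaps_match_pathway_counts(pathway_collection):
    """Querying the 25 hub targets against the bundled pathway collection
    recovers each pathway's printed overlap count."""
    with pytest.warns(UserWarning, match="SIRT1"):  # SIRT1 is unannotated
        rows = enrich(HUB_TARGETS, pathway_collection)
    counts = {r.term_id: r.k for r in rows}
    assert counts == {
        "hsa05200": 18, "hsa04151": 15, "hsa05205": 13, "hsa04010": 12,
        "hsa04668": 12, "hsa05161": 12, "hsa04915": 11, "hsa05164": 11,
        "hsa05215": 10, "hsa05160": 10,
    }


def test_enrich_drops_out_of_background_genes():
    term = AnnotationTerm("T1", "d", Category.pathway, frozenset({"A", "B"}))
    col = AnnotationCollection([term])
    with pytest.warns(UserWarning, match="dropped"):
        rows = enrich(frozenset({"A", "ZZZ"}), col)
    assert rows[0].n == 1
    with pytest.raises(ValidationError), pytest.warns(UserWarning):
        enrich(frozenset({"ZZZ"}), col)


def test_enrich_adjusts_within_category():
    terms = [
        AnnotationTerm("b1", "d", Category.BP, frozenset({"A", "B"})),
        AnnotationTerm("b2", "d", Category.BP, frozenset({"A", "C"})),
        AnnotationTerm("m1", "d", Category.MF, frozenset({"A", "D"})),
    ]
    col = AnnotationCollection(terms, background=frozenset("ABCDEFGH"))
    rows = enrich(frozenset({"A", "B"}), col)
    by_id = {r.term_id: r for r in rows}
    # MF has a single tested term: adjusted equals raw
    assert by_id["m1"].p_adj == pytest.approx(by_id["m1"].p_raw)
    # BP adjusts over its two terms only
    bp_raw = [by_id["b1"].p_raw, by_id["b2"].p_raw]
    bp_adj = bh_adjust(bp_raw)
    assert [by_id["b1"].p_adj, by_id["b2"].p_adj] == pytest.approx(bp_adj)


# -- filter and rank --------------------------------------------------------

def _row(term_id, k, p_raw, p_adj):
    return EnrichmentRow(
        term_id=term_id, description="", category=Category.pathway,
        overlap_genes=frozenset(f"G{i}" for i in range(k)), k=k, K=k + 5,
        n=25, N=2000, p_raw=p_raw, p_adj=p_adj)


def test_filter_keeps_only_significant():
    rows = [_row("a", 5, 0.001, 0.01), _row("b", 3, 0.1, 0.2)]
    assert [r.term_id for r in filter_and_rank(rows, alpha=0.05)] == ["a"]
    assert filter_and_rank([]) == []


def test_rank_by_gene_count(pathway_collection):
    with pytest.warns(UserWarning, match="SIRT1"):
        rows = enrich(HUB_TARGETS, pathway_collection)
    ranked = filter_and_rank(rows, alpha=1.1, rank_by="k")
    assert ranked[0].term_id == "hsa05200"  # 18 genes first
    assert {r.term_id for r in ranked[-2:]} == {"hsa05215", "hsa05160"}  # 10s last


# -- category proportions ---------------------------------------------------

def test_category_proportions_study_counts():
    """253 BP / 35 MF / 25 CC terms give 80.83 / 11.18 / 7.99 percent."""
    props = category_proportions({"BP": 253, "MF": 35, "CC": 25})
    assert props.rounded == {"BP": 80.83, "MF": 11.18, "CC": 7.99}
    assert sum(props.raw.values()) == pytest.approx(100.0)


@pytest.mark.parametrize("counts,expected", [
    ({"BP": 1, "MF": 1}, {"BP": 50.00, "MF": 50.00}),
    ({"BP": 2, "MF": 1}, {"BP": 66.67, "MF": 33.33}),
])
def test_category_proportions_rounding(counts, expected):
    assert category_proportions(counts).rounded == expected


def test_category_proportions_zero_total_raises():
    with pytest.raises(ValidationError):
        category_proportions({"BP": 0})
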