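"""Over-representation analysis of gene sets with BH-FDR control.

Given a query gene set (here: hub targets of a compound panel) and a
collection of annotation terms (GO categories, KEGG-style pathways) over a
background universe of N genes, each term of size K is tested for
over-representation among the n query genes that lie in the background.
With k genes overlapping, the raw p-value is the hypergeometric upper tail

    p = P(X >= k),   X ~ Hypergeometric(N, K, n),

optionally replaced by the more conservative EASE variant that removes one
overlapping gene before taking the tail (the convention popularized by the
DAVID annotation server).  Raw p-values are then Benjamini-Hochberg adjusted
within each annotation category (BP / MF / CC / pathway) and filtered at a
significance level alpha.

The background universe defaults to the union of all term gene sets, the
only self-consistent choice when no genome-wide annotation is supplied; it
can be overridden with any larger universe.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from enum import Enum
from typing import Iterable, NamedTuple

import numpy as np
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .errors import ValidationError
from .target_sets import GeneSymbol, TargetSet

__all__ = [
    "Category",
    "AnnotationTerm",
    "AnnotationCollection",
    "EnrichmentRow",
    "hypergeom_tail",
    "ease_tail",
    "bh_adjust",
    "enrich",
    "filter_and_rank",
    "CategoryProportions",
    "category_proportions",
]


class Category(str, Enum):
    """Annotation category: the three GO namespaces plus pathway collections."""

    BP = "BP"
    MF = "MF"
    CC = "CC"
    pathway = "pathway"


@dataclass(frozen=True)
class AnnotationTerm:
    """One annotation term (GO term or pathway) and its member genes."""

    term_id: str
    description: str
    category: Category
    genes: frozenset[GeneSymbol]

    def __post_init__(self):
        if not self.genes:
            raise ValidationError(f"term {self.term_id!r} has an empty gene set")


@dataclass
class AnnotationCollection:
    """A list of annotation terms plus the background gene universe.

    If no background is given, the union of all term gene sets is used.
    Every term's genes must lie inside the background.
    """

    terms: list[AnnotationTerm]
    background: frozenset[GeneSymbol] = field(default_factory=frozenset)

    def __post_init__(self):
        ids = [t.term_id for t in self.terms]
        if len(ids) != len(set(ids)):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValidationError(f"duplicate term ids in collection: {dupes}")
        union = frozenset().union(*(t.genes for t in self.terms)) if self.terms else frozenset()
        if not self.background:
            self.background = union
        elif not union <= self.background:
            stray = sorted(union - self.background)[:5]
            raise ValidationError(
                f"term genes outside the background universe, e.g. {stray}"
            )

    def __len__(self) -> int:
        return len(self.terms)

    def __iter__(self):
        return iter(self.terms)

    def gene_union(self) -> frozenset[GeneSymbol]:
        if not self.terms:
            return frozenset()
        return frozenset().union(*(t.genes for t in self.terms))


@dataclass(frozen=True)
class EnrichmentRow:
    """Result of testing one term: overlap, counts, raw and adjusted p."""

    term_id: str
    description: str
    category: Category
    overlap_genes: frozenset[GeneSymbol]
    k: int  # overlap size
    K: int  # term size within background
    n: int  # effective query size (query ∩ background)
    N: int  # background size
    p_raw: float
    p_adj: float


def _check_counts(k: int, K: int, n: int, N: int) -> None:
    if not (0 <= k <= min(K, n)):
        raise ValidationError(f"need 0 <= k <= min(K, n); got k={k}, K={K}, n={n}")
    if not (K <= N and n <= N):
        raise ValidationError(f"need K <= N and n <= N; got K={K}, n={n}, N={N}")
    if K < 0 or n < 0 or N <= 0:
        raise ValidationError(f"counts must be non-negative with N > 0; got K={K}, n={n}, N={N}")


def hypergeom_tail(k: int, K: int, n: int, N: int) -> float:
    """Upper-tail P(X >= k) for X ~ Hypergeometric(N, K, n).

    N is the background size, K the term size, n the query size and k the
    observed overlap.  Returns exactly 1.0 when k == 0.  Evaluated through
    the survival function of :data:`scipy.stats.hypergeom`, which works in
    log space and is stable for the extreme tails that enrichment analysis
    routinely produces.
    """
    _check_counts(k, K, n, N)
    if k == 0:
        return 1.0
    return float(hypergeom.sf(k - 1, N, K, n))


def ease_tail(k: int, K: int, n: int, N: int) -> float:
    """EASE score: hypergeometric tail with one overlap gene removed.

    ``ease_tail(k, ...) == hypergeom_tail(max(k - 1, 0), ...)``; always at
    least as large as the plain tail, hence more conservative.
    """
    _check_counts(k, K, n, N)
    return hypergeom_tail(max(k - 1, 0), K, n, N)


def bh_adjust(p_values: Iterable[float]) -> list[float]:
    """Benjamini-Hochberg step-up adjusted p-values, in input order.

    Equivalent to sorting ascending, setting p_adj(i) = min_{j>=i} p(j)*m/j,
    capping at 1, and undoing the sort.  Monotone in the raw ranks.
    """
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        return []
    if np.any((p < 0) | (p > 1)) or np.any(~np.isfinite(p)):
        raise ValidationError("p-values must lie in [0, 1]")
    _, adj, _, _ = multipletests(p, method="fdr_bh")
    return [float(x) for x in adj]


_METHODS = {"hypergeometric": hypergeom_tail, "ease": ease_tail}


def enrich(
    query: TargetSet | Iterable[GeneSymbol],
    collection: AnnotationCollection,
    method: str = "hypergeometric",
    adjust_within_category: bool = True,
) -> list[EnrichmentRow]:
    """Test every term of a collection for over-representation in a query.

    Query genes outside the background are dropped with a warning (reducing
    the effective query size n).  One row is returned per term with overlap
    k >= 1; adjusted p-values are BH across all tested terms, within each
    category separately by default (set ``adjust_within_category=False`` for
    a single global adjustment).
    """
    if method not in _METHODS:
        raise ValidationError(f"unknown method {method!r}; choose from {sorted(_METHODS)}")
    tail = _METHODS[method]
    qset = frozenset(query.symbols if isinstance(query, TargetSet) else query)
    effective = qset & collection.background
    dropped = qset - collection.background
    if dropped:
        warnings.warn(
            f"{len(dropped)} query gene(s) outside the background were dropped "
            f"(e.g. {sorted(dropped)[:3]})",
            stacklevel=2,
        )
    if not effective:
        raise ValidationError("no query gene lies in the annotation background")

    n, N = len(effective), len(collection.background)
    tested: list[tuple[AnnotationTerm, frozenset, int, int, float]] = []
    for term in collection.terms:
        overlap = term.genes & effective
        if not overlap:
            continue
        K = len(term.genes)
        p = tail(len(overlap), K, n, N)
        tested.append((term, overlap, len(overlap), K, p))

    # BH within category (or globally) across the tested terms
    rows: list[EnrichmentRow] = []
    if adjust_within_category:
        groups: dict[Category, list[int]] = {}
        for i, (term, *_rest) in enumerate(tested):
            groups.setdefault(term.category, []).append(i)
    else:
        groups = {None: list(range(len(tested)))}  # type: ignore[dict-item]
    p_adj = [1.0] * len(tested)
    for idx in groups.values():
        adj = bh_adjust([tested[i][4] for i in idx])
        for i, a in zip(idx, adj):
            p_adj[i] = a
    for i, (term, overlap, k, K, p) in enumerate(tested):
        rows.append(
            EnrichmentRow(
                term_id=term.term_id,
                description=term.description,
                category=term.category,
                overlap_genes=overlap,
                k=k,
                K=K,
                n=n,
                N=N,
                p_raw=p,
                p_adj=p_adj[i],
            )
        )
    return rows


def filter_and_rank(
    rows: list[EnrichmentRow],
    alpha: float = 0.05,
    rank_by: str = "p_raw",
    top: int | None = None,
) -> list[EnrichmentRow]:
    """Keep rows with p_adj < alpha and sort by p-value or overlap size.

    ``rank_by='p_raw'`` sorts ascending by raw p (ties: larger k first);
    ``rank_by='k'`` sorts descending by overlap count (ties: smaller p
    first).  Remaining ties break on term_id.  ``top`` truncates the list.
    """
    if rank_by not in ("p_raw", "k"):
        raise ValidationError(f"rank_by must be 'p_raw' or 'k', got {rank_by!r}")
    kept = [r for r in rows if r.p_adj < alpha]
    if rank_by == "p_raw":
        kept.sort(key=lambda r: (r.p_raw, -r.k, r.term_id))
    else:
        kept.sort(key=lambda r: (-r.k, r.p_raw, r.term_id))
    return kept[:top] if top is not None else kept


class CategoryProportions(NamedTuple):
    """Category percentages, both rounded (2 dp, half-up) and raw."""

    rounded: dict[str, float]
    raw: dict[str, float]


def category_proportions(counts: dict[str, int]) -> CategoryProportions:
    """Percentage of terms per category, rounded half-up to 2 decimals.

    The rounded values need not sum to exactly 100; the raw values do (up
    to floating point).
    """
    if any(c < 0 for c in counts.values()):
        raise ValidationError("term counts must be non-negative")
    total = sum(counts.values())
    if total <= 0:
        raise ValidationError("total term count must be positive")
    raw = {cat: 100.0 * c / total for cat, c in counts.items()}
    rounded = {
        cat: float(
            (Decimal(c) * 100 / Decimal(total)).quantize(
                Decimal("0.01"), rounding=ROUND_HALF_UP
            )
        )
        for cat, c in counts.items()
    }
    return CategoryProportions(rounded=rounded, raw=raw)
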