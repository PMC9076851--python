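"""Gene-symbol normalization, multi-source target sets, and Venn intersection.

A *target set* is the basic currency of a network-pharmacology analysis:
the predicted protein targets of a panel of compounds on one side, and the
genes associated with a disease on the other.  Symbols from heterogeneous
databases are normalized into a single official-gene-symbol-style namespace
(uppercase, whitespace-stripped) before any set algebra, and every set
remembers which source databases contributed to it.
"""

from __future__ import annotations

from collections.abc import Iterable, Mapping
from dataclasses import dataclass

import pandas as pd

from .errors import ValidationError

__all__ = [
    "GeneSymbol",
    "TargetSet",
    "VennResult",
    "normalize_symbol",
    "apply_alias_table",
    "merge_sources",
    "intersect_sets",
    "venn_summary",
]

#: A normalized gene symbol is a plain ``str``; the constraints (nonempty,
#: uppercase, no internal whitespace) are enforced by :func:`normalize_symbol`.
GeneSymbol = str


def normalize_symbol(raw: str) -> GeneSymbol:
    """Normalize a raw gene name into official-gene-symbol style.

    Strips surrounding whitespace and uppercases.  Hyphens and digits are
    preserved (official symbols such as ``HSP90AA1`` contain digits).
    Idempotent: ``normalize_symbol(normalize_symbol(x)) == normalize_symbol(x)``.

    Raises
    ------
    ValidationError
        If the input is empty/whitespace-only, or contains internal
        whitespace (which would indicate a free-text protein name rather
        than a gene symbol).
    """
    if raw is None:
        raise ValidationError("gene symbol is missing")
    sym = str(raw).strip().upper()
    if not sym:
        raise ValidationError(f"empty gene symbol: {raw!r}")
    if any(ch.isspace() for ch in sym):
        raise ValidationError(
            f"gene symbol contains internal whitespace: {raw!r}; "
            "supply an alias table to map free-text names to symbols"
        )
    return sym


@dataclass(frozen=True)
class TargetSet:
    """An immutable, provenance-tagged set of normalized gene symbols."""

    symbols: frozenset[GeneSymbol]
    sources: frozenset[str] = frozenset()

    @classmethod
    def from_iterable(cls, raw: Iterable[str], source: str | None = None) -> "TargetSet":
        """Build a set from raw gene names, normalizing and deduplicating."""
        symbols = frozenset(normalize_symbol(s) for s in raw)
        sources = frozenset([source]) if source else frozenset()
        return cls(symbols, sources)

    def __len__(self) -> int:
        return len(self.symbols)

    def __contains__(self, item: object) -> bool:
        return item in self.symbols

    def __iter__(self):
        return iter(sorted(self.symbols))

    def with_source(self, source: str) -> "TargetSet":
        return TargetSet(self.symbols, self.sources | {source})


@dataclass(frozen=True)
class VennResult:
    """Two-set Venn partition: left-only / common / right-only.

    The three parts are pairwise disjoint and partition each input:
    ``|left_only| + |common| == |left|`` and ``|right_only| + |common| == |right|``.
    """

    left_only: TargetSet
    common: TargetSet
    right_only: TargetSet

    @property
    def sizes(self) -> tuple[int, int, int]:
        return (len(self.left_only), len(self.common), len(self.right_only))


def apply_alias_table(raw: Iterable[str], aliases: Mapping[str, str]) -> list[str]:
    """Map raw names through a user-supplied alias table before normalization.

    Lookup is case-insensitive on the stripped raw name; names absent from
    the table pass through unchanged.
    """
    lut = {str(k).strip().upper(): v for k, v in aliases.items()}
    out = []
    for name in raw:
        key = str(name).strip().upper()
        out.append(lut.get(key, name))
    return out


def merge_sources(sets: list[TargetSet]) -> TargetSet:
    """Union a list of target sets, pooling symbols and source labels.

    The result size is at most the sum of the input sizes; merging is
    associative and commutative up to set equality.
    """
    if not sets:
        raise ValidationError("merge_sources requires at least one TargetSet")
    symbols: frozenset[GeneSymbol] = frozenset()
    sources: frozenset[str] = frozenset()
    for ts in sets:
        symbols |= ts.symbols
        sources |= ts.sources
    return TargetSet(symbols, sources)


def intersect_sets(left: TargetSet, right: TargetSet) -> VennResult:
    """Two-set Venn analysis of compound targets against disease genes.

    Symmetric in the common part: ``intersect_sets(a, b).common`` equals
    ``intersect_sets(b, a).common``.  Empty inputs are allowed and simply
    yield an empty common part.
    """
    common = left.symbols & right.symbols
    return VennResult(
        left_only=TargetSet(left.symbols - common, left.sources),
        common=TargetSet(common, left.sources | right.sources),
        right_only=TargetSet(right.symbols - common, right.sources),
    )


def venn_summary(venn: VennResult) -> pd.DataFrame:
    """Tabulate a Venn partition as (part, size, comma-joined symbols)."""
    rows = []
    for part, ts in [("left_only", venn.left_only), ("common", venn.common),
                     ("right_only", venn.right_only)]:
        rows.append({"part": part, "size": len(ts), "symbols": ",".join(sorted(ts.symbols))})
    return pd.DataFrame(rows, columns=["part", "size", "symbols"])
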