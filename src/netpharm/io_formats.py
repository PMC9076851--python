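"""Readers and writers for the on-disk formats the pipeline touches.

All tables are tab-separated UTF-8 with a header row; lines starting with
``#`` are comments.  Networks are exchanged as SIF (Cytoscape simple
interaction format) and GraphML; gene-set collections as GMT (GSEA
dialect); docking and MM-PBSA results as plain TSV tables.  Numeric
parsing accepts both the ASCII hyphen and the Unicode minus (U+2212),
including a space between sign and digits, because published energy tables
routinely contain the latter.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path
from typing import Union

import networkx as nx
import pandas as pd

from .binding_analysis import DockScore, EnergyComponents, ResidueEnergyProfile
from .enrichment import AnnotationCollection, AnnotationTerm, Category
from .errors import ParseError, SchemaError, ValidationError
from .networks import LayeredNetwork
from .target_sets import TargetSet, normalize_symbol

__all__ = [
    "TableDialect",
    "read_gene_table",
    "read_gmt",
    "write_gmt",
    "write_sif",
    "read_sif",
    "write_graphml",
    "read_graphml",
    "read_layered_graphml",
    "read_energy_table",
    "write_energy_table",
    "read_residue_profiles",
    "write_residue_profiles",
    "read_dock_scores",
    "write_dock_scores",
]

Network = Union[LayeredNetwork, nx.Graph]


@dataclass(frozen=True)
class TableDialect:
    """Dialect of the flat tables: TSV, header row, '#' comments, UTF-8."""

    delimiter: str = "\t"
    header: bool = True
    comment_prefix: str = "#"
    encoding: str = "utf-8"

    def __post_init__(self):
        if len(self.delimiter) != 1:
            raise ValidationError("delimiter must be a single character")


DIALECT = TableDialect()


def parse_number(text: str) -> float:
    """Parse a decimal number, accepting Unicode minus and spaced signs."""
    s = str(text).strip().replace("−", "-")
    s = re.sub(r"(?<=[+-])\s+", "", s)
    try:
        return float(s)
    except ValueError as exc:
        raise ParseError(f"not a number: {text!r}") from exc


def _read_table(path: str | Path, dialect: TableDialect = DIALECT) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    return pd.read_csv(
        path,
        sep=dialect.delimiter,
        comment=dialect.comment_prefix,
        encoding=dialect.encoding,
        dtype=str,
        skip_blank_lines=True,
    )


def _require_columns(df: pd.DataFrame, required: list[str], path: Path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(
            f"{path}: missing column(s) {missing}; available: {list(df.columns)}"
        )


# ---------------------------------------------------------------------------
# gene tables
# ---------------------------------------------------------------------------

def read_gene_table(
    path: str | Path,
    symbol_column: str = "gene",
    source: str | None = None,
    dialect: TableDialect = DIALECT,
) -> TargetSet:
    """Read a TSV gene table into a normalized, deduplicated TargetSet.

    ``source`` defaults to the file name.  An empty table (header only)
    yields an empty TargetSet.
    """
    path = Path(path)
    df = _read_table(path, dialect)
    _require_columns(df, [symbol_column], path)
    raw = [v for v in df[symbol_column].tolist() if pd.notna(v)]
    return TargetSet.from_iterable(raw, source=source or path.name)


# ---------------------------------------------------------------------------
# GMT gene-set collections
# ---------------------------------------------------------------------------

def read_gmt(
    path: str | Path,
    category: Category | str = Category.pathway,
    background: frozenset[str] | None = None,
    dialect: TableDialect = DIALECT,
) -> AnnotationCollection:
    """Read a GMT file (term-id <tab> description <tab> gene...).

    Every line needs at least three fields; duplicate genes within a line
    are collapsed; duplicate term ids raise.  All terms receive the given
    ``category`` (GMT itself does not record one).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    cat = Category(category)
    terms: list[AnnotationTerm] = []
    with open(path, encoding=dialect.encoding) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith(dialect.comment_prefix):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(
                    f"{path}: GMT line needs >= 3 tab-separated fields", line=lineno
                )
            term_id, description, *genes = fields
            genes = [g for g in genes if g.strip()]
            if not genes:
                raise ParseError(f"{path}: term {term_id!r} has no genes", line=lineno)
            terms.append(
                AnnotationTerm(
                    term_id=term_id,
                    description=description,
                    category=cat,
                    genes=frozenset(normalize_symbol(g) for g in genes),
                )
            )
    ids = [t.term_id for t in terms]
    if len(ids) != len(set(ids)):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise SchemaError(f"{path}: duplicate term id(s): {dupes}")
    return AnnotationCollection(terms, background=background or frozenset())


def write_gmt(collection: AnnotationCollection, path: str | Path) -> Path:
    path = Path(path)
    with open(path, "w", encoding="utf-8") as fh:
        for term in collection:
            genes = "\t".join(sorted(term.genes))
            fh.write(f"{term.term_id}\t{term.description}\t{genes}\n")
    return path


# ---------------------------------------------------------------------------
# SIF / GraphML networks
# ---------------------------------------------------------------------------

def _as_graph(net: Network) -> nx.Graph:
    return net.graph if isinstance(net, LayeredNetwork) else net


def write_sif(net: Network, path: str | Path, default_relation: str = "ppi") -> Path:
    """Write a network in Cytoscape SIF: 'source <tab> relation <tab> target'.

    Isolated nodes are emitted as single-field lines per SIF convention.
    Edges lacking a ``relation`` attribute use ``default_relation``.
    """
    g = _as_graph(net)
    if g.number_of_nodes() == 0:
        raise ValidationError("refusing to write an empty network")
    path = Path(path)
    with open(path, "w", encoding="utf-8") as fh:
        for u, v, d in sorted(g.edges(data=True)):
            rel = d.get("relation", default_relation)
            fh.write(f"{u}\t{rel}\t{v}\n")
        for n in sorted(nx.isolates(g)):
            fh.write(f"{n}\n")
    return path


def read_sif(path: str | Path, dialect: TableDialect = DIALECT) -> nx.Graph:
    """Read a SIF file back into a graph with ``relation`` edge attributes.

    Single-field lines become isolated nodes.  Together with
    :func:`write_sif` this is a node-set/edge-set round-trip identity.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    g = nx.Graph()
    with open(path, encoding=dialect.encoding) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith(dialect.comment_prefix):
                continue
            fields = line.split("\t")
            if len(fields) == 1:
                g.add_node(fields[0])
            elif len(fields) == 3:
                u, rel, v = fields
                g.add_edge(u, v, relation=rel)
            else:
                raise ParseError(
                    f"{path}: SIF line must have 1 or 3 tab-separated fields",
                    line=lineno,
                )
    return g


def write_graphml(net: Network, path: str | Path,
                  default_layer: str = "target",
                  default_relation: str = "ppi") -> Path:
    """Write GraphML with a 'layer' node attribute and 'relation' edge attribute.

    Node ids are the node names (no generated integer ids), keeping the
    output diff-friendly; XML escaping is handled by the serializer.
    """
    g = _as_graph(net)
    if g.number_of_nodes() == 0:
        raise ValidationError("refusing to write an empty network")
    out = nx.Graph()
    for n, d in g.nodes(data=True):
        out.add_node(n, layer=d.get("layer", default_layer))
    for u, v, d in g.edges(data=True):
        out.add_edge(u, v, relation=d.get("relation", default_relation))
    path = Path(path)
    nx.write_graphml(out, path, named_key_ids=True)
    return path


def read_graphml(path: str | Path) -> nx.Graph:
    """Read GraphML written by :func:`write_graphml` (node names as ids)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    return nx.read_graphml(path)


def read_layered_graphml(path: str | Path) -> LayeredNetwork:
    """Rebuild a LayeredNetwork from GraphML 'layer' node attributes."""
    g = read_graphml(path)
    net = LayeredNetwork()
    for n, d in g.nodes(data=True):
        if "layer" not in d:
            raise SchemaError(f"{path}: node {n!r} lacks a 'layer' attribute")
        net.add_node(n, d["layer"])
    for u, v, _ in g.edges(data=True):
        net.add_edge(u, v)
    return net


# ---------------------------------------------------------------------------
# energy / docking tables
# ---------------------------------------------------------------------------

_ENERGY_COLUMNS = ["complex", "vdw", "elec", "polar", "sasa"]


def read_energy_table(path: str | Path,
                      dialect: TableDialect = DIALECT) -> list[EnergyComponents]:
    """Read an MM-PBSA component table (complex, vdw, elec, polar, sasa, total).

    The four components are required per row; 'total' may be blank, in
    which case it is left absent (to be computed downstream).  Unicode
    minus is accepted.
    """
    path = Path(path)
    df = _read_table(path, dialect)
    _require_columns(df, _ENERGY_COLUMNS, path)
    has_total = "total" in df.columns
    records: list[EnergyComponents] = []
    for i, row in df.iterrows():
        def cell(col: str, required: bool = True) -> float | None:
            v = row.get(col)
            if v is None or (isinstance(v, float) and pd.isna(v)) or str(v).strip() == "":
                if required:
                    raise ParseError(f"{path}: missing value", line=i + 2, column=col)
                return None
            try:
                return parse_number(v)
            except ParseError as exc:
                raise ParseError(f"{path}: {exc}", line=i + 2, column=col) from exc

        records.append(
            EnergyComponents(
                complex_id=str(row["complex"]),
                e_vdw=cell("vdw"),
                e_elec=cell("elec"),
                g_polar=cell("polar"),
                g_sasa=cell("sasa"),
                g_bind=cell("total", required=False) if has_total else None,
            )
        )
    return records


def write_energy_table(records: list[EnergyComponents], path: str | Path) -> Path:
    path = Path(path)
    rows = [
        {
            "complex": r.complex_id, "vdw": r.e_vdw, "elec": r.e_elec,
            "polar": r.g_polar, "sasa": r.g_sasa,
            "total": "" if r.g_bind is None else r.g_bind,
        }
        for r in records
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
    return path


def read_residue_profiles(path: str | Path,
                          dialect: TableDialect = DIALECT) -> list[ResidueEnergyProfile]:
    """Read per-residue decompositions (complex, residue, energy), one profile
    per complex, preserving first-appearance order of complexes."""
    path = Path(path)
    df = _read_table(path, dialect)
    _require_columns(df, ["complex", "residue", "energy"], path)
    profiles: dict[str, dict[str, float]] = {}
    for i, row in df.iterrows():
        cid, res = str(row["complex"]), str(row["residue"])
        contributions = profiles.setdefault(cid, {})
        if res in contributions:
            raise SchemaError(f"{path}: duplicate residue {res!r} for complex {cid!r}")
        try:
            contributions[res] = parse_number(row["energy"])
        except ParseError as exc:
            raise ParseError(f"{path}: {exc}", line=i + 2, column="energy") from exc
    return [ResidueEnergyProfile(cid, contribs) for cid, contribs in profiles.items()]


def write_residue_profiles(profiles: list[ResidueEnergyProfile],
                           path: str | Path) -> Path:
    path = Path(path)
    rows = [
        {"complex": p.complex_id, "residue": res, "energy": e}
        for p in profiles for res, e in p.contributions.items()
    ]
    pd.DataFrame(rows, columns=["complex", "residue", "energy"]).to_csv(
        path, sep="\t", index=False
    )
    return path


def read_dock_scores(path: str | Path,
                     dialect: TableDialect = DIALECT) -> list[DockScore]:
    """Read a docking-score table (compound, target, total_score)."""
    path = Path(path)
    df = _read_table(path, dialect)
    _require_columns(df, ["compound", "target", "total_score"], path)
    out = []
    for i, row in df.iterrows():
        try:
            score = parse_number(row["total_score"])
        except ParseError as exc:
            raise ParseError(f"{path}: {exc}", line=i + 2, column="total_score") from exc
        out.append(DockScore(str(row["compound"]), str(row["target"]), score))
    return out


def write_dock_scores(scores: list[DockScore], path: str | Path) -> Path:
    path = Path(path)
    rows = [
        {"compound": s.compound, "target": s.target, "total_score": s.total_score}
        for s in scores
    ]
    pd.DataFrame(rows, columns=["compound", "target", "total_score"]).to_csv(
        path, sep="\t", index=False
    )
    return path
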