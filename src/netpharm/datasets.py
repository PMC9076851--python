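"""Bundled reference datasets.

Small curated tables from a published network-pharmacology study of the
iridoid glycosides of *Eucommia ulmoides* Oliver against osteoporosis:

* the edgecount (degree) table of the 93-node PPI network of common
  compound/disease targets,
* the top-10 KEGG pathway annotations of the 25 hub targets,
* the MM-PBSA energy decompositions of four protein-ligand complexes,
* metadata of the 12 active iridoid glycoside compounds.

These serve as worked examples and as ground truth for the degree-median
hub rule, the layered-network node accounting, and the energy additivity
check.  They are loaded lazily from TSV/GMT files shipped inside the
package.
"""

from __future__ import annotations

from importlib import resources
from pathlib import Path

import pandas as pd

from . import io_formats
from .binding_analysis import EnergyComponents
from .enrichment import AnnotationCollection

__all__ = [
    "data_path",
    "load_ppi_degree_table",
    "ppi_degree_series",
    "load_pathway_collection",
    "load_energy_components",
    "load_compound_table",
    "compound_names",
]


def data_path(name: str) -> Path:
    """Filesystem path of a bundled data file."""
    return Path(resources.files("netpharm") / "data" / name)


def load_ppi_degree_table() -> pd.DataFrame:
    """Degree table of the 93-node common-target PPI network.

    Columns: ``gene``, ``protein_name``, ``edgecount``.  Sorted by
    edgecount descending.
    """
    df = pd.read_csv(data_path("ppi_degree_table.tsv"), sep="\t", comment="#")
    df["edgecount"] = df["edgecount"].astype(int)
    return df


def ppi_degree_series() -> pd.Series:
    """The same degree table as a Series indexed by gene symbol."""
    df = load_ppi_degree_table()
    return pd.Series(df["edgecount"].values, index=df["gene"].values,
                     name="edgecount")


def load_pathway_collection() -> AnnotationCollection:
    """Top-10 KEGG pathway annotations of the hub targets, as a collection.

    The background defaults to the union of the ten gene lists (24 genes).
    """
    return io_formats.read_gmt(data_path("kegg_pathways_top10.gmt"),
                               category="pathway")


def load_energy_components(include_ambiguous: bool = False) -> list[EnergyComponents]:
    """MM-PBSA energy decompositions of the docked complexes.

    By default only the three rows whose published components are
    typographically unambiguous are returned; ``include_ambiguous=True``
    adds the MAPK1-geniposide row, whose polar term was reconstructed from
    the additivity constraint (see the data file header).
    """
    df = pd.read_csv(data_path("mmpbsa_energies.tsv"), sep="\t", comment="#")
    if not include_ambiguous:
        df = df[df["ambiguous"] == 0]
    return [
        EnergyComponents(
            complex_id=row["complex"],
            e_vdw=float(row["vdw"]),
            e_elec=float(row["elec"]),
            g_polar=float(row["polar"]),
            g_sasa=float(row["sasa"]),
            g_bind=float(row["total"]),
        )
        for _, row in df.iterrows()
    ]


def load_compound_table() -> pd.DataFrame:
    """Metadata of the 12 active iridoid glycosides (name, CAS, formula, MW)."""
    return pd.read_csv(data_path("iridoid_compounds.tsv"), sep="\t", comment="#")


def compound_names() -> list[str]:
    """The 12 compound names, in the bundled table's order."""
    return load_compound_table()["compound"].tolist()
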