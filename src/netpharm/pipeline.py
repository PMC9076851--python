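"""Config-driven orchestration of the full network-pharmacology flow.

Stages, in order: merge/normalize compound and disease targets → Venn
intersection → PPI simplification → degree table / median / hub selection
→ hub subnetwork + topology report → gene-set enrichment → significance
filter and ranking → layered networks (compound-target,
compound-target-disease, compound-hubtarget-pathway) → core-compound
selection → docking / MM-PBSA reports.  Every intermediate is written as
TSV/SIF/GraphML into the output directory, together with a JSON manifest
recording the configuration, input checksums, and per-stage counts.

Inputs may come from files or, in *synthetic mode*, from the seeded
generators of :mod:`netpharm.synthetic_data`; stages whose optional inputs
are missing (e.g. no docking scores) are skipped and noted in the manifest.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import pandas as pd
import yaml

from . import io_formats, synthetic_data, topology
from .binding_analysis import (critical_residues, score_matrix_report,
                               total_binding_energy)
from .enrichment import enrich, filter_and_rank
from .errors import ValidationError
from .networks import (CompoundTargetMap, build_compound_hub_pathway,
                       build_compound_target, build_compound_target_disease,
                       layer_degree, select_core_compounds)
from .synthetic_data import SynthConfig
from .target_sets import TargetSet, intersect_sets, merge_sources, venn_summary

__all__ = ["PipelineConfig", "run_pipeline", "load_config"]

log = logging.getLogger("netpharm.pipeline")


@dataclass
class PipelineConfig:
    """All knobs of one pipeline run; defaults carry the standard constants
    (hub/core multiplier 2, alpha 0.05, strict comparisons)."""

    outdir: str | Path = "netpharm_out"
    seed: int = 0
    # input files (all optional; synthetic mode fills the gaps)
    compound_target_path: str | None = None   # TSV: compound, target
    disease_paths: list[str] = field(default_factory=list)  # gene TSVs
    ppi_edges_path: str | None = None         # TSV: gene_a, gene_b
    gmt_paths: list[str] = field(default_factory=list)
    dock_scores_path: str | None = None
    energy_path: str | None = None
    residue_path: str | None = None
    # synthetic mode
    synthetic: bool = True
    synth: SynthConfig | None = None
    # analysis options
    hub_multiplier: float = 2.0
    hub_strict: bool = True
    alpha: float = 0.05
    enrichment_method: str = "hypergeometric"
    top_pathways: int = 10
    rank_by: str = "k"
    core_multiplier: float = 2.0
    core_strict: bool = True
    core_median_scope: str = "all_nodes"
    herb_label: str = "herb"
    disease_label: str = "disease"


def load_config(path: str | Path) -> PipelineConfig:
    """Load a YAML or JSON config file into a PipelineConfig."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    with open(path, encoding="utf-8") as fh:
        raw = yaml.safe_load(fh) or {}
    synth = raw.pop("synth", None)
    cfg = PipelineConfig(**raw)
    if synth is not None:
        cfg.synth = SynthConfig(**synth)
    return cfg


def _sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _read_pair_table(path: str, col_a: str, col_b: str) -> list[tuple[str, str]]:
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    for col in (col_a, col_b):
        if col not in df.columns:
            raise ValidationError(f"{path}: missing column {col!r}")
    return [(str(a), str(b)) for a, b in zip(df[col_a], df[col_b])]


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Execute every stage and return the run manifest (also written to disk).

    Identical config + inputs produce identical outputs; the manifest
    differs only in its timestamp.
    """
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    synth = (cfg.synth or SynthConfig()).with_seed(
        cfg.synth.seed if cfg.synth is not None else cfg.seed
    )
    manifest: dict = {
        "config": {
            **{k: v for k, v in dataclasses.asdict(cfg).items() if k != "synth"},
            "synth": dataclasses.asdict(synth) if cfg.synthetic else None,
        },
        "inputs": {},
        "stages": {},
        "skipped": [],
        "status": "running",
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
    }
    for name in ("compound_target_path", "ppi_edges_path", "dock_scores_path",
                 "energy_path", "residue_path"):
        p = getattr(cfg, name)
        if p:
            manifest["inputs"][name] = {"path": str(p), "sha256": _sha256(p)}
    for p in list(cfg.disease_paths) + list(cfg.gmt_paths):
        manifest["inputs"][str(p)] = {"path": str(p), "sha256": _sha256(p)}

    stage = "targets"
    try:
        # ------------------------------------------------------------------
        # 1. compound-target map and disease set
        # ------------------------------------------------------------------
        if cfg.compound_target_path:
            pairs = _read_pair_table(cfg.compound_target_path, "compound", "target")
            entries: dict[str, set[str]] = {}
            for c, t in pairs:
                entries.setdefault(c, set()).add(t)
            cmap = CompoundTargetMap(
                {c: frozenset(TargetSet.from_iterable(ts).symbols)
                 for c, ts in entries.items()}
            )
        elif cfg.synthetic:
            cmap = synthetic_data.gen_compound_target_map(synth)
        else:
            raise ValidationError("no compound-target input and synthetic mode off")
        compound_union = TargetSet(cmap.target_union(), frozenset({"compounds"}))

        if cfg.disease_paths:
            disease = merge_sources(
                [io_formats.read_gene_table(p, symbol_column="gene")
                 for p in cfg.disease_paths]
            )
        elif cfg.synthetic:
            disease = synthetic_data.gen_disease_set(synth, compound_union)
        else:
            raise ValidationError("no disease input and synthetic mode off")
        manifest["stages"]["targets"] = {
            "n_compounds": len(cmap.compounds),
            "n_compound_targets": len(compound_union),
            "n_disease_targets": len(disease),
        }

        # ------------------------------------------------------------------
        # 2. Venn intersection
        # ------------------------------------------------------------------
        stage = "venn"
        venn = intersect_sets(compound_union, disease)
        venn_summary(venn).to_csv(outdir / "venn.tsv", sep="\t", index=False)
        common = venn.common
        manifest["stages"]["venn"] = {"n_common": len(common)}
        if not len(common):
            raise ValidationError("no common targets between compounds and disease")

        # ------------------------------------------------------------------
        # 3. PPI network, degrees, hubs, hub subnetwork
        # ------------------------------------------------------------------
        stage = "ppi"
        if cfg.ppi_edges_path:
            raw_edges = _read_pair_table(cfg.ppi_edges_path, "gene_a", "gene_b")
            g = topology.simplify_graph(raw_edges, drop_isolated=True,
                                        nodes=sorted(common.symbols))
        elif cfg.synthetic:
            labels = sorted(common.symbols)
            n_hubs = min(synth.n_planted_hubs, max(len(labels) - 1, 0))
            ppi_cfg = dataclasses.replace(
                synth, n_planted_hubs=n_hubs,
                n_background_nodes=len(labels) - n_hubs,
            )
            if (ppi_cfg.n_background_nodes * ppi_cfg.background_degree) % 2:
                ppi_cfg = dataclasses.replace(
                    ppi_cfg, background_degree=ppi_cfg.background_degree + 1)
            g = synthetic_data.gen_ppi_with_planted_hubs(ppi_cfg, labels=labels)
        else:
            raise ValidationError("no PPI input and synthetic mode off")
        dt = topology.degree_table(g)
        dt.rename_axis("gene").reset_index().to_csv(
            outdir / "degree_table.tsv", sep="\t", index=False)
        med = topology.median_degree(dt)
        hubs = topology.select_hubs(g, multiplier=cfg.hub_multiplier,
                                    strict=cfg.hub_strict)
        (outdir / "hubs.txt").write_text("\n".join(sorted(hubs)) + "\n")
        hub_g = topology.induced_subgraph(g, hubs) if hubs else nx.Graph()
        io_formats.write_sif(g, outdir / "ppi.sif")
        report = None
        if hubs:
            report = topology.topology_report(hub_g)
            report.to_series().rename_axis("parameter").reset_index(name="value").to_csv(
                outdir / "hub_topology.tsv", sep="\t", index=False)
            io_formats.write_sif(hub_g, outdir / "hub_ppi.sif")
        manifest["stages"]["ppi"] = {
            "n_nodes": g.number_of_nodes(),
            "n_edges": g.number_of_edges(),
            "median_degree": med,
            "n_hubs": len(hubs),
            "hub_nodes": sorted(hubs),
        }

        # ------------------------------------------------------------------
        # 4. enrichment
        # ------------------------------------------------------------------
        stage = "enrichment"
        if cfg.gmt_paths:
            collections = [io_formats.read_gmt(p) for p in cfg.gmt_paths]
            terms = [t for c in collections for t in c.terms]
            from .enrichment import AnnotationCollection
            collection = AnnotationCollection(terms)
        elif cfg.synthetic:
            collection = synthetic_data.gen_annotations(
                synth, frozenset(hubs) if hubs else common.symbols)
        else:
            collection = None
        ranked = []
        if collection is not None and hubs:
            rows = enrich(frozenset(hubs), collection, method=cfg.enrichment_method)
            ranked = filter_and_rank(rows, alpha=cfg.alpha, rank_by=cfg.rank_by,
                                     top=cfg.top_pathways)
            pd.DataFrame(
                [{
                    "term_id": r.term_id, "description": r.description,
                    "category": r.category.value, "k": r.k, "K": r.K,
                    "n": r.n, "N": r.N, "p_raw": r.p_raw, "p_adj": r.p_adj,
                    "genes": ",".join(sorted(r.overlap_genes)),
                } for r in ranked]
            ).to_csv(outdir / "enrichment.tsv", sep="\t", index=False)
            manifest["stages"]["enrichment"] = {
                "n_tested": len(rows), "n_significant": len(ranked),
                "top_term": ranked[0].term_id if ranked else None,
            }
        else:
            manifest["skipped"].append("enrichment")

        # ------------------------------------------------------------------
        # 5. layered networks and core compounds
        # ------------------------------------------------------------------
        stage = "networks"
        ct_net = build_compound_target(cmap)
        io_formats.write_graphml(ct_net, outdir / "compound_target.graphml")
        ctd_net = build_compound_target_disease(
            cmap, common, herb_label=cfg.herb_label,
            disease_label=cfg.disease_label)
        io_formats.write_graphml(ctd_net, outdir / "compound_target_disease.graphml")
        manifest["stages"]["networks"] = {
            "compound_target_nodes": ct_net.n_nodes,
            "compound_target_edges": ct_net.n_edges,
            "compound_target_disease_nodes": ctd_net.n_nodes,
            "compound_target_disease_edges": ctd_net.n_edges,
        }
        if ranked and hubs:
            from .enrichment import AnnotationCollection
            top_terms = [t for t in collection.terms
                         if t.term_id in {r.term_id for r in ranked}]
            chp_net = build_compound_hub_pathway(
                cmap, hubs, AnnotationCollection(top_terms))
            io_formats.write_graphml(chp_net, outdir / "compound_hub_pathway.graphml")
            core = select_core_compounds(
                chp_net, multiplier=cfg.core_multiplier,
                strict=cfg.core_strict, median_scope=cfg.core_median_scope)
            layer_degree(chp_net, "compound").rename_axis("compound").reset_index(
            ).to_csv(outdir / "compound_degrees.tsv", sep="\t", index=False)
            manifest["stages"]["networks"]["compound_hub_pathway_nodes"] = chp_net.n_nodes
            manifest["stages"]["networks"]["compound_hub_pathway_edges"] = chp_net.n_edges
            manifest["stages"]["core_compounds"] = {"core": sorted(core)}
        else:
            manifest["skipped"].append("compound_hub_pathway")

        # ------------------------------------------------------------------
        # 6. binding reports
        # ------------------------------------------------------------------
        stage = "binding"
        if cfg.dock_scores_path:
            scores = io_formats.read_dock_scores(cfg.dock_scores_path)
        elif cfg.synthetic and hubs:
            scores = synthetic_data.gen_dock_scores(
                synth, cmap.compounds, sorted(hubs))
        else:
            scores = None
        if scores:
            rep = score_matrix_report(scores)
            rep.scores.rename_axis("compound").to_csv(
                outdir / "dock_matrix.tsv", sep="\t")
            manifest["stages"]["docking"] = {
                "n_pairs": int(rep.scores.notna().sum().sum()),
                "grade_counts": rep.grade_counts,
            }
        else:
            manifest["skipped"].append("docking")

        energies, profiles = None, None
        if cfg.energy_path:
            energies = io_formats.read_energy_table(cfg.energy_path)
        elif cfg.synthetic:
            energies, profiles = synthetic_data.gen_energy_tables(synth)
        if cfg.residue_path:
            profiles = io_formats.read_residue_profiles(cfg.residue_path)
        if energies:
            rows = [{"complex": e.complex_id,
                     "total_kj_mol": total_binding_energy(e)} for e in energies]
            pd.DataFrame(rows).to_csv(outdir / "binding_energy.tsv",
                                      sep="\t", index=False)
            manifest["stages"]["mmpbsa"] = {"n_complexes": len(energies)}
        else:
            manifest["skipped"].append("mmpbsa")
        if profiles:
            rows = [{"complex": p.complex_id,
                     "critical_residues": ",".join(sorted(critical_residues(p)))}
                    for p in profiles]
            pd.DataFrame(rows).to_csv(outdir / "critical_residues.tsv",
                                      sep="\t", index=False)
            manifest["stages"]["residues"] = {"n_profiles": len(profiles)}

        manifest["status"] = "ok"
    except Exception as exc:
        manifest["status"] = "failed"
        manifest["failed_stage"] = stage
        manifest["error"] = str(exc)
        with open(outdir / "manifest.json", "w", encoding="utf-8") as fh:
            json.dump(manifest, fh, indent=2, default=str)
        raise
    with open(outdir / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    log.info("pipeline finished: %s", outdir / "manifest.json")
    return manifest
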