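"""End-to-end orchestration: score -> extract -> anneal -> filter -> compare.

The library entry point is :func:`analyze_regions`, which takes in-memory
(expression, network) inputs; :func:`run_pipeline` is the file-based wrapper
used by the command line, reading a YAML config and writing GraphML/SIF
networks and TSV tables.  All randomness is fanned out deterministically from
one master seed (per-region substreams use seed + region index).
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import networkx as nx
import numpy as np
import yaml

from .anneal import AnnealConfig, sa_optimize, threshold_filter
from .heinz import Subnetwork, heinz_extract
from .io import (ExpressionMatrix, collapse_probes, match_network, read_expression,
                 read_idmap, read_ppi)
from .regions import (OverlapSummary, RegionResult, find_common_genes,
                      overlap_matrix, regulation_direction, specific_subnetwork)
from .scoring import ScoredNetwork, ScoringConfig, score_network

logger = logging.getLogger(__name__)

__all__ = [
    "PipelineConfig", "PipelineResult", "analyze_regions", "run_pipeline",
    "write_network", "read_network", "write_tables",
]


@dataclass
class RegionInput:
    expression: str
    condition: str | None = None
    fdr: float | str = "auto"
    format: str = "tsv"


@dataclass
class PipelineConfig:
    """File-based pipeline configuration (see ``PipelineConfig.from_yaml``)."""

    regions: dict[str, RegionInput]
    ppi: str
    idmap: str | None = None
    ppi_format: str = "tsv_edgelist"
    target_positive_fraction: float = 0.15
    anneal: AnnealConfig = field(default_factory=AnnealConfig)
    quantile: float = 0.9
    min_regions: int | None = None
    exclude_shared: bool = False
    outdir: str = "signet_out"
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        regions = {
            label: RegionInput(**spec) if isinstance(spec, dict)
            else RegionInput(expression=spec)
            for label, spec in raw.pop("regions").items()
        }
        anneal = AnnealConfig(**raw.pop("anneal", {}))
        return cls(regions=regions, anneal=anneal, **raw)

    def validate_paths(self) -> None:
        missing = [p for p in
                   [self.ppi, self.idmap,
                    *(r.expression for r in self.regions.values()),
                    *(r.condition for r in self.regions.values())]
                   if p is not None and not Path(p).exists()]
        if missing:
            raise FileNotFoundError(f"missing input path(s): {missing}")
        if not self.regions:
            raise ValueError("need at least one region")


@dataclass
class PipelineResult:
    """Everything the pipeline produces, per region and across regions."""

    regions: dict[str, RegionResult]
    scored: dict[str, ScoredNetwork]
    overlap: OverlapSummary | None
    common_genes: set[str]
    specific: dict[str, RegionResult]


def run_region(expr: ExpressionMatrix, ppi: nx.Graph,
               scoring: ScoringConfig, anneal: AnnealConfig,
               ) -> tuple[RegionResult, ScoredNetwork]:
    """One region's chain: match -> score -> heinz -> anneal -> filter."""
    matched_expr, matched_ppi = match_network(expr, ppi)
    sn = score_network(matched_expr, matched_ppi, scoring)
    module = heinz_extract(sn)
    logger.info("region %s: heinz module %d nodes (score %.3f)",
                expr.region or "-", len(module.nodes), module.node_score_total)
    module = sa_optimize(module, sn, anneal)
    module = threshold_filter(module, sn, anneal.threshold)
    logger.info("region %s: refined module %d nodes / %d edges",
                expr.region or "-", len(module.nodes), len(module.edges))
    regulation = {g: regulation_direction(matched_expr, g) for g in module.nodes}
    return RegionResult(expr.region, module, regulation), sn


def analyze_regions(exprs: dict[str, ExpressionMatrix], ppi: nx.Graph,
                    fdr: dict[str, float] | float | None = None,
                    target_positive_fraction: float = 0.15,
                    anneal: AnnealConfig | None = None,
                    quantile: float = 0.9, min_regions: int | None = None,
                    exclude_shared: bool = False, seed: int = 0,
                    ) -> PipelineResult:
    """Run the full multi-region analysis on in-memory inputs.

    ``fdr`` may be a single value, a per-region mapping, or None to calibrate
    each region to ``target_positive_fraction`` positive-score nodes.  The
    common/specific split removes the common genes (optionally, with
    ``exclude_shared``, every gene occurring in two or more region
    subnetworks) and re-runs extraction per region.
    """
    anneal = anneal or AnnealConfig()
    region_results: dict[str, RegionResult] = {}
    scored: dict[str, ScoredNetwork] = {}
    for i, (label, expr) in enumerate(sorted(exprs.items())):
        if expr.region != label:
            expr = ExpressionMatrix(expr.data, expr.condition, region=label)
        region_fdr = fdr.get(label) if isinstance(fdr, dict) else fdr
        scoring = ScoringConfig(fdr=region_fdr,
                                target_positive_fraction=target_positive_fraction,
                                edge_threshold=anneal.threshold)
        cfg_r = replace(anneal, seed=seed + i)
        result, sn = run_region(expr, ppi, scoring, cfg_r)
        region_results[label] = result
        scored[label] = sn

    overlap = None
    common: set[str] = set()
    results_list = [region_results[l] for l in sorted(region_results)]
    if len(results_list) >= 2:
        overlap = overlap_matrix(results_list)
        common = find_common_genes(results_list, quantile=quantile,
                                   min_regions=min_regions)
    logger.info("common genes: %d", len(common))

    shared: set[str] = set()
    if exclude_shared and len(results_list) >= 2:
        counts: dict[str, int] = {}
        for r in results_list:
            for g in r.subnetwork.nodes:
                counts[g] = counts.get(g, 0) + 1
        shared = {g for g, c in counts.items() if c >= 2}

    specific: dict[str, RegionResult] = {}
    for i, label in enumerate(sorted(region_results)):
        cfg_s = replace(anneal, seed=seed + 1000 + i)
        module = specific_subnetwork(scored[label], common, cfg_s,
                                     exclude=shared if exclude_shared else None)
        regulation = {}
        if not module.is_empty and scored[label].expr is not None:
            regulation = {g: regulation_direction(scored[label].expr, g)
                          for g in module.nodes}
        specific[label] = RegionResult(label, module, regulation)
        logger.info("region %s: specific module %d nodes%s", label,
                    len(module.nodes),
                    " (absent)" if module.is_empty else "")

    return PipelineResult(regions=region_results, scored=scored,
                          overlap=overlap, common_genes=common,
                          specific=specific)


def run_pipeline(cfg: PipelineConfig) -> PipelineResult:
    """File-based end-to-end run; writes all outputs under ``cfg.outdir``."""
    cfg.validate_paths()
    ppi = read_ppi(cfg.ppi, format=cfg.ppi_format)
    idmap = read_idmap(cfg.idmap) if cfg.idmap else None
    exprs: dict[str, ExpressionMatrix] = {}
    fdrs: dict[str, float | None] = {}
    for label, spec in cfg.regions.items():
        expr = read_expression(spec.expression, format=spec.format,
                               condition_path=spec.condition, region=label)
        if idmap is not None:
            expr = collapse_probes(expr, idmap)
        exprs[label] = expr
        fdrs[label] = None if spec.fdr in (None, "auto") else float(spec.fdr)

    result = analyze_regions(
        exprs, ppi, fdr=fdrs,
        target_positive_fraction=cfg.target_positive_fraction,
        anneal=cfg.anneal, quantile=cfg.quantile,
        min_regions=cfg.min_regions, exclude_shared=cfg.exclude_shared,
        seed=cfg.seed,
    )
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for label in sorted(result.regions):
        rr = result.regions[label]
        write_network(rr.subnetwork, result.scored[label],
                      outdir / f"module_{label}.graphml",
                      regulation=rr.regulation)
        sr = result.specific[label]
        if not sr.subnetwork.is_empty:
            write_network(sr.subnetwork, result.scored[label],
                          outdir / f"specific_{label}.graphml",
                          regulation=sr.regulation)
    write_tables(result, outdir)
    return result


def _subnet_graph(subnet: Subnetwork, sn: ScoredNetwork,
                  regulation: dict[str, str] | None) -> nx.Graph:
    g = nx.Graph()
    weak = set(subnet.flags.get("weak_bridges", ()))
    for n in subnet.nodes:
        g.add_node(n, score=float(sn.node_score[n]), p=float(sn.pvalue[n]),
                   regulation=(regulation or {}).get(n, ""))
    for u, v in subnet.edges:
        e = ScoredNetwork.edge_key(u, v)
        z = sn.z(u, v) if np.isfinite(sn.edge_sd) and sn.edge_sd > 0 else 0.0
        g.add_edge(u, v, edge_score=float(sn.edge_score[e]), z=float(z),
                   weak_bridge=bool(e in weak))
    return g


def write_network(subnet: Subnetwork, sn: ScoredNetwork, path,
                  format: str = "graphml",
                  regulation: dict[str, str] | None = None) -> None:
    """Serialize a subnetwork with node/edge attributes (GraphML or SIF)."""
    path = Path(path)
    g = _subnet_graph(subnet, sn, regulation)
    if format == "graphml":
        nx.write_graphml(g, path, named_key_ids=True)
    elif format == "sif":
        with open(path, "w") as fh:
            connected = {n for e in subnet.edges for n in e}
            for u, v in sorted(subnet.edges):
                fh.write(f"{u}\tpp\t{v}\n")
            for n in sorted(set(subnet.nodes) - connected):
                fh.write(f"{n}\n")
    else:
        raise ValueError(f"unknown network format {format!r}")


def read_network(path) -> nx.Graph:
    """Read back a GraphML file written by :func:`write_network`."""
    return nx.read_graphml(path)


def _fmt(x: float) -> str:
    return f"{x:.6g}"


def write_tables(result: PipelineResult, outdir) -> None:
    """Write score, Venn-cell, common-gene and regulation TSVs.

    Row order is deterministic (sorted by gene id / region label), so reruns
    with identical inputs are byte-identical.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for label in sorted(result.scored):
        sn = result.scored[label]
        with open(outdir / f"scores_{label}.tsv", "w") as fh:
            fh.write("gene\tp\tscore\n")
            for g in sorted(sn.node_score):
                fh.write(f"{g}\t{_fmt(sn.pvalue[g])}\t{_fmt(sn.node_score[g])}\n")
        with open(outdir / f"edge_scores_{label}.tsv", "w") as fh:
            fh.write("geneA\tgeneB\tedge_score\tz_score\n")
            for (u, v) in sorted(sn.edge_score):
                z = sn.z(u, v) if np.isfinite(sn.edge_sd) and sn.edge_sd > 0 else 0.0
                fh.write(f"{u}\t{v}\t{_fmt(sn.edge_score[(u, v)])}\t{_fmt(z)}\n")

    with open(outdir / "common_genes.tsv", "w") as fh:
        fh.write("gene\n")
        for g in sorted(result.common_genes):
            fh.write(f"{g}\n")

    if result.overlap is not None:
        with open(outdir / "venn_cells.tsv", "w") as fh:
            fh.write("regions\tintersection\texclusive\n")
            for combo in sorted(result.overlap.intersections,
                                key=lambda c: (len(c), sorted(c))):
                fh.write("|".join(sorted(combo)) + "\t"
                         f"{result.overlap.intersections[combo]}\t"
                         f"{result.overlap.venn_cells[combo]}\n")

    with open(outdir / "regulation.tsv", "w") as fh:
        fh.write("region\tkind\tgene\tregulation\n")
        for label in sorted(result.regions):
            for kind, rr in (("module", result.regions[label]),
                             ("specific", result.specific[label])):
                for g in sorted(rr.subnetwork.nodes):
                    fh.write(f"{label}\t{kind}\t{g}\t{rr.regulation.get(g, '')}\n")

    summary = {
        "regions": {
            label: {
                "module_nodes": len(result.regions[label].subnetwork.nodes),
                "module_edges": len(result.regions[label].subnetwork.edges),
                "module_score": result.regions[label].subnetwork.node_score_total,
                "specific_nodes": len(result.specific[label].subnetwork.nodes),
                "specific_absent": result.specific[label].subnetwork.is_empty,
                "fdr": result.scored[label].fdr,
                "tau": result.scored[label].tau,
                "bum_a": result.scored[label].fit.a,
                "bum_lambda": result.scored[label].fit.lam,
            } for label in sorted(result.regions)
        },
        "n_common_genes": len(result.common_genes),
    }
    with open(outdir / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
        fh.write("\n")


def output_digest(outdir) -> str:
    """SHA-256 over the sorted relative paths and contents of an output dir."""
    h = hashlib.sha256()
    for p in sorted(Path(outdir).rglob("*")):
        if p.is_file():
            h.update(p.relative_to(outdir).as_posix().encode())
            h.update(p.read_bytes())
    return h.hexdigest()
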