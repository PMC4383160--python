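"""Cross-region comparison of extracted subnetworks.

Given one refined subnetwork per region, this module tabulates overlaps
(Venn cells), extracts the "common" genes — genes recurring across regions
whose within-subnetwork connectivity exceeds the 90% degree quantile in every
region containing them — and re-runs the extraction pipeline per region with
the common genes removed to obtain region-specific modules.  Member genes are
also labelled up/down/unchanged from the case-vs-control means.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from itertools import combinations

from scipy import stats

from .anneal import AnnealConfig, sa_optimize, threshold_filter
from .heinz import Subnetwork, heinz_extract
from .io import CASE, CONTROL, ExpressionMatrix
from .scoring import ScoredNetwork

logger = logging.getLogger(__name__)

__all__ = [
    "RegionResult", "OverlapSummary", "overlap_matrix", "find_common_genes",
    "specific_subnetwork", "regulation_direction", "empirical_quantile",
]


@dataclass
class RegionResult:
    """One region's refined subnetwork with per-member regulation calls."""

    region: str
    subnetwork: Subnetwork
    regulation: dict[str, str] = field(default_factory=dict)


@dataclass
class OverlapSummary:
    """Per-region gene sets with intersection and exclusive Venn-cell counts.

    ``intersections`` maps every non-empty combination of region labels to
    the plain intersection size; ``venn_cells`` maps it to the exclusive cell
    size (in exactly these regions and no others).  The exclusive cells of
    the combinations containing a region sum to that region's set size.
    """

    sets: dict[str, frozenset[str]]
    intersections: dict[frozenset[str], int]
    venn_cells: dict[frozenset[str], int]


def overlap_matrix(results: list[RegionResult]) -> OverlapSummary:
    """Exact set-intersection counts for all non-empty region combinations."""
    if len(results) < 2:
        raise ValueError("need at least 2 regions")
    labels = [r.region for r in results]
    if len(set(labels)) != len(labels):
        raise ValueError(f"duplicate region labels: {labels}")
    sets = {r.region: frozenset(r.subnetwork.nodes) for r in results}
    inter: dict[frozenset[str], int] = {}
    venn: dict[frozenset[str], int] = {}
    for k in range(1, len(labels) + 1):
        for combo in combinations(labels, k):
            inside = frozenset.intersection(*(sets[c] for c in combo))
            outside = frozenset().union(
                *(sets[l] for l in labels if l not in combo)) if k < len(labels) \
                else frozenset()
            inter[frozenset(combo)] = len(inside)
            venn[frozenset(combo)] = len(inside - outside)
    return OverlapSummary(sets=sets, intersections=inter, venn_cells=venn)


def empirical_quantile(values, q: float) -> float:
    """Type-1 empirical quantile: the ceil(q*n)-th smallest value."""
    vals = sorted(values)
    if not vals:
        raise ValueError("empty value list")
    k = max(1, math.ceil(q * len(vals)))
    return vals[k - 1]


def find_common_genes(results: list[RegionResult], quantile: float = 0.9,
                      min_regions: int | None = None) -> set[str]:
    """Genes recurring across regions with top-quantile connectivity everywhere.

    A gene is a candidate when it appears in at least ``min_regions``
    subnetworks (default: all of them); it is common iff in EVERY region
    containing it its within-subnetwork degree strictly exceeds that region's
    empirical ``quantile`` of member degrees.
    """
    if not 0.0 < quantile < 1.0:
        raise ValueError("quantile must lie in (0,1)")
    if any(r.subnetwork.is_empty for r in results):
        raise ValueError("all region subnetworks must be non-empty")
    if min_regions is None:
        min_regions = len(results)

    degrees: dict[str, dict[str, int]] = {}
    cutoffs: dict[str, float] = {}
    for r in results:
        g = r.subnetwork.graph()
        deg = dict(g.degree())
        degrees[r.region] = deg
        cutoffs[r.region] = empirical_quantile(list(deg.values()), quantile)

    membership: dict[str, list[str]] = {}
    for r in results:
        for gene in r.subnetwork.nodes:
            membership.setdefault(gene, []).append(r.region)

    common = set()
    for gene, regs in membership.items():
        if len(regs) < min_regions:
            continue
        if all(degrees[reg][gene] > cutoffs[reg] for reg in regs):
            common.add(gene)
    return common


def specific_subnetwork(region_sn: ScoredNetwork, common: set[str],
                        cfg: AnnealConfig | None = None,
                        exclude: set[str] | None = None) -> Subnetwork:
    """Re-extract a region's module after deleting the common genes.

    ``exclude`` optionally removes further genes (e.g. everything shared with
    other regions' subnetworks).  If no positive-score node survives — the
    region has no specific signal left — an empty result flagged
    ``no_specific_module`` is returned rather than raising.
    """
    drop = set(common) | (set(exclude) if exclude else set())
    keep = [n for n in region_sn.graph.nodes if n not in drop]
    if not keep:
        logger.warning("region %s: no nodes left after common-gene removal",
                       region_sn.region)
        return Subnetwork.empty(no_specific_module=True)
    residual = region_sn.restrict(keep)
    if not residual.positive_nodes():
        logger.warning("region %s: no positive node after common-gene removal",
                       region_sn.region)
        return Subnetwork.empty(no_specific_module=True)
    cfg = cfg or AnnealConfig()
    module = heinz_extract(residual)
    module = sa_optimize(module, residual, cfg)
    return threshold_filter(module, residual, cfg.threshold)


def regulation_direction(expr: ExpressionMatrix, gene: str,
                         alpha: float = 0.05) -> str:
    """Call a gene up/down/unchanged in cases vs controls (Welch test)."""
    if gene not in expr.data.index:
        raise KeyError(f"gene {gene!r} not in expression matrix")
    case = expr.data.loc[gene, [s for s in expr.sample_ids
                                if expr.condition[s] == CASE]].to_numpy(float)
    ctrl = expr.data.loc[gene, [s for s in expr.sample_ids
                                if expr.condition[s] == CONTROL]].to_numpy(float)
    res = stats.ttest_ind(case, ctrl, equal_var=False)
    p = float(res.pvalue)
    if not math.isfinite(p):
        p = 1.0
    if p < alpha and case.mean() > ctrl.mean():
        return "up"
    if p < alpha and case.mean() < ctrl.mean():
        return "down"
    return "unchanged"
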