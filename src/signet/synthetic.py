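"""Synthetic multi-region datasets with planted common and specific modules.

The generator emulates the statistical structure the scoring model assumes:
background genes draw i.i.d. N(0, 1) expression in every sample, so their
case-vs-control p-values are Uniform(0, 1) (the uniform noise component of
the beta-uniform mixture); planted signal genes get their case means shifted
by ``effect_delta``, concentrating their p-values near zero (the beta-like
signal component); and each planted module shares a per-sample latent factor
with loading ``coexpr_rho``, inducing positive co-expression — hence strong
edge scores — along the module's interactions.

One connected "common" module is shared by all regions; each region
additionally carries one connected region-specific module, all pairwise
disjoint.  Everything is exactly regenerable from (parameters, seed).
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from typing import NamedTuple

import networkx as nx
import numpy as np
import pandas as pd

from .io import CASE, CONTROL, ExpressionMatrix

__all__ = [
    "SyntheticParams", "SyntheticTruth", "Recovery",
    "generate_ppi", "plant_modules", "densify_module", "generate_expression",
    "generate_dataset", "recovery_metrics",
]


@dataclass(frozen=True)
class SyntheticParams:
    """Default study conditions for the planted-module benchmark."""

    n_genes: int = 300
    mean_degree: float = 4.0
    n_regions: int = 3
    common_size: int = 10
    specific_size: int = 8
    common_min_degree: int = 5
    specific_min_degree: int = 3
    n_control: int = 10
    n_case: int = 10
    effect_delta: float = 2.0
    coexpr_rho: float = 0.7
    seed: int = 0


@dataclass
class SyntheticTruth:
    """Planted module membership plus the parameters that generated it."""

    common_module: frozenset[str]
    specific_modules: list[frozenset[str]]
    params: dict = field(default_factory=dict)

    def all_planted(self) -> frozenset[str]:
        return self.common_module.union(*self.specific_modules) \
            if self.specific_modules else self.common_module

    def to_json(self) -> str:
        return json.dumps({
            "common_module": sorted(self.common_module),
            "specific_modules": [sorted(m) for m in self.specific_modules],
            "params": self.params,
        }, indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "SyntheticTruth":
        obj = json.loads(text)
        return cls(frozenset(obj["common_module"]),
                   [frozenset(m) for m in obj["specific_modules"]],
                   obj.get("params", {}))


def _gene_name(i: int, width: int) -> str:
    return f"G{i:0{width}d}"


def generate_ppi(n_genes: int, mean_degree: float = 4.0,
                 seed: int = 0) -> nx.Graph:
    """Connected scale-free-like simple graph on ``n_genes`` gene ids.

    Preferential attachment with m = round(mean_degree / 2) edges per new
    node; components (possible only for degenerate parameters) are bridged to
    force connectivity.  Deterministic for a fixed seed.
    """
    if n_genes < 10:
        raise ValueError("need at least 10 genes")
    m = max(1, round(mean_degree / 2.0))
    if m >= n_genes:
        raise ValueError("mean_degree too large for n_genes")
    g = nx.barabasi_albert_graph(n_genes, m, seed=seed)
    if not nx.is_connected(g):  # pragma: no cover - BA graphs are connected
        comps = [sorted(c) for c in nx.connected_components(g)]
        for a, b in zip(comps, comps[1:]):
            g.add_edge(a[0], b[0])
    width = len(str(n_genes - 1))
    mapping = {i: _gene_name(i, width) for i in g.nodes}
    return nx.relabel_nodes(g, mapping)


def _grow_connected(g: nx.Graph, size: int, forbidden: set[str],
                    rng: np.random.Generator) -> set[str] | None:
    """Grow a connected node set by a seeded random walk over the frontier."""
    allowed = sorted(set(g.nodes) - forbidden)
    if len(allowed) < size:
        return None
    start = allowed[rng.integers(len(allowed))]
    module = {start}
    while len(module) < size:
        frontier = sorted(
            {nb for n in module for nb in g.neighbors(n)} - module - forbidden
        )
        if not frontier:
            return None
        module.add(frontier[rng.integers(len(frontier))])
    return module


def plant_modules(ppi: nx.Graph, common_size: int, specific_size: int,
                  n_regions: int, seed: int = 0,
                  max_tries: int = 200) -> SyntheticTruth:
    """Plant one common and ``n_regions`` specific connected modules.

    Modules are connected induced subgraphs chosen by seeded random walks;
    pairwise disjointness is enforced by rejection with bounded retries.
    """
    total = common_size + n_regions * specific_size
    if total > ppi.number_of_nodes() // 2:
        raise ValueError(
            f"requested {total} planted genes on a {ppi.number_of_nodes()}-gene "
            "network; planted genes must not exceed half the genes"
        )
    rng = np.random.default_rng(seed)
    sizes = [common_size] + [specific_size] * n_regions
    for _ in range(max_tries):
        taken: set[str] = set()
        modules: list[set[str]] = []
        ok = True
        for size in sizes:
            if size == 0:
                modules.append(set())
                continue
            mod = _grow_connected(ppi, size, taken, rng)
            if mod is None:
                ok = False
                break
            modules.append(mod)
            taken |= mod
        if ok:
            return SyntheticTruth(
                common_module=frozenset(modules[0]),
                specific_modules=[frozenset(m) for m in modules[1:]],
                params={"common_size": common_size,
                        "specific_size": specific_size,
                        "n_regions": n_regions, "seed": seed},
            )
    raise RuntimeError(
        f"could not place {n_regions + 1} disjoint connected modules "
        f"in {max_tries} tries"
    )


def densify_module(ppi: nx.Graph, module, rng: np.random.Generator,
                   min_degree: int) -> int:
    """Add intra-module edges until every member has ``min_degree`` partners.

    Planted modules emulate functional complexes and pathway cores, which are
    densely interconnected induced subgraphs rather than the trees a random
    walk traces on a sparse scale-free graph; without that density a planted
    "module" carries no connectivity signal for degree-based detection.
    Partners are drawn uniformly (seeded) among the member pairs not already
    linked.  Returns the number of edges added; the graph is modified in
    place.
    """
    mod = sorted(module)
    cap = len(mod) - 1
    added = 0
    for m in mod:
        have = sum(1 for x in mod if x != m and ppi.has_edge(m, x))
        need = min(min_degree, cap) - have
        if need <= 0:
            continue
        others = [x for x in mod if x != m and not ppi.has_edge(m, x)]
        for j in rng.permutation(len(others))[:need]:
            ppi.add_edge(m, others[j])
            added += 1
    return added


def generate_expression(ppi: nx.Graph, truth: SyntheticTruth, region_index: int,
                        n_control: int = 10, n_case: int = 10,
                        effect_delta: float = 2.0, coexpr_rho: float = 0.7,
                        seed: int = 0, region: str = "") -> ExpressionMatrix:
    """Simulate one region's genes x samples matrix.

    Background genes: i.i.d. N(0, 1).  Signal genes (common module plus this
    region's specific module): case means shifted by ``effect_delta``; each
    active module additionally shares a per-sample latent N(0, 1) factor with
    loading ``coexpr_rho``.  Draw order is fixed (background matrix, then the
    common factor, then the specific factor) so datasets regenerate exactly.
    """
    if n_control < 2 or n_case < 2:
        raise ValueError("need at least 2 samples per condition")
    if not 0 <= region_index < len(truth.specific_modules):
        raise IndexError(f"region_index {region_index} out of range")
    genes = sorted(ppi.nodes)
    row_of = {g: i for i, g in enumerate(genes)}
    n_samples = n_control + n_case
    rng = np.random.default_rng(seed)
    values = rng.standard_normal((len(genes), n_samples))

    for module in (truth.common_module, truth.specific_modules[region_index]):
        if not module:
            continue
        factor = rng.standard_normal(n_samples)
        rows = [row_of[g] for g in sorted(module)]
        values[rows, :] += coexpr_rho * factor

    signal = sorted(truth.common_module | truth.specific_modules[region_index])
    case_cols = np.arange(n_control, n_samples)
    for g in signal:
        values[row_of[g], case_cols] += effect_delta

    region = region or f"R{region_index + 1}"
    sample_ids = [f"{region}_ctrl{i + 1}" for i in range(n_control)] + \
                 [f"{region}_case{i + 1}" for i in range(n_case)]
    condition = pd.Series([CONTROL] * n_control + [CASE] * n_case,
                          index=sample_ids, dtype=object)
    data = pd.DataFrame(values, index=pd.Index(genes, name="gene"),
                        columns=sample_ids)
    return ExpressionMatrix(data, condition, region=region)


def generate_dataset(params: SyntheticParams | None = None
                     ) -> tuple[nx.Graph, SyntheticTruth, dict[str, ExpressionMatrix]]:
    """Full multi-region dataset from one parameter set and master seed.

    Substream seeds are derived deterministically from ``params.seed``
    (graph, planting, then one stream per region).
    """
    p = params or SyntheticParams()
    ppi = generate_ppi(p.n_genes, p.mean_degree, seed=p.seed)
    truth = plant_modules(ppi, p.common_size, p.specific_size, p.n_regions,
                          seed=p.seed + 1)
    truth.params = asdict(p)
    rng = np.random.default_rng(p.seed + 2)
    densify_module(ppi, truth.common_module, rng, p.common_min_degree)
    for mod in truth.specific_modules:
        densify_module(ppi, mod, rng, p.specific_min_degree)
    exprs: dict[str, ExpressionMatrix] = {}
    for r in range(p.n_regions):
        region = f"R{r + 1}"
        exprs[region] = generate_expression(
            ppi, truth, r, n_control=p.n_control, n_case=p.n_case,
            effect_delta=p.effect_delta, coexpr_rho=p.coexpr_rho,
            seed=p.seed + 3 + r, region=region,
        )
    return ppi, truth, exprs


class Recovery(NamedTuple):
    precision: float
    recall: float
    f1: float
    undefined: bool = False


def recovery_metrics(predicted, truth_set) -> Recovery:
    """Precision/recall/F1 of a predicted gene set against a planted one.

    An empty prediction has undefined precision; it is reported as 0 with the
    ``undefined`` flag set.
    """
    pred = set(predicted)
    truth = set(truth_set)
    if not pred:
        return Recovery(0.0, 0.0, 0.0, undefined=True)
    tp = len(pred & truth)
    precision = tp / len(pred)
    recall = tp / len(truth) if truth else 0.0
    f1 = (2 * precision * recall / (precision + recall)
          if precision + recall > 0 else 0.0)
    return Recovery(precision, recall, f1)
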