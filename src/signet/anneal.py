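"""Simulated-annealing refinement of an extracted subnetwork on edge scores.

The Heinz stage optimizes node scores along tree corridors; the annealer then
reshapes module membership under the combined objective

    node_score_total + normalized_edge_score

(the background-standardized edge total), letting strongly co-expressed
neighbors join and weakly supported members leave.  A final deterministic
threshold rule adds every strong interaction between members and removes the
weak ones (bridges excepted, to preserve connectivity).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import networkx as nx
import numpy as np

from .heinz import Subnetwork
from .scoring import ScoredNetwork

logger = logging.getLogger(__name__)

__all__ = ["AnnealConfig", "sa_optimize", "threshold_filter"]


@dataclass
class AnnealConfig:
    """Annealing schedule and the strong/weak interaction threshold.

    ``threshold`` (default 0.8) applies to the absolute background-
    standardized edge score |z|.  Geometric cooling from ``t_initial`` down to
    ``t_final`` with ``steps_per_temp`` proposals per temperature.
    """

    threshold: float = 0.8
    t_initial: float = 1.0
    t_final: float = 1e-3
    cooling: float = 0.95
    steps_per_temp: int = 100
    seed: int = 0

    def __post_init__(self):
        if not 0.0 < self.cooling < 1.0:
            raise ValueError("cooling factor must lie in (0,1)")
        if not 0.0 < self.t_final < self.t_initial:
            raise ValueError("need 0 < t_final < t_initial")
        if self.threshold < 0.0:
            raise ValueError("threshold must be >= 0")
        if self.steps_per_temp < 1:
            raise ValueError("steps_per_temp must be >= 1")


def _objective_parts(sn: ScoredNetwork, members: set[str]):
    node_total = sum(sn.node_score[n] for n in members)
    edges = sn.induced_edges(members)
    if edges and (not np.isfinite(sn.edge_sd) or sn.edge_sd <= 0.0):
        raise ValueError("edge score background sd must be positive")
    edge_total = sum(sn.z(u, v) for u, v in edges)
    return node_total, edge_total


def _is_articulation(sn, members: set[str], node: str, adj=None) -> bool:
    """Would removing ``node`` disconnect the induced subgraph on members?"""
    rest = members - {node}
    if not rest:
        return True  # never empty the module
    neighbors = adj.__getitem__ if adj is not None else sn.graph.neighbors
    start = min(rest)
    seen = {start}
    stack = [start]
    while stack:
        v = stack.pop()
        for nb in neighbors(v):
            if nb in rest and nb not in seen:
                seen.add(nb)
                stack.append(nb)
    return len(seen) != len(rest)


def sa_optimize(start: Subnetwork, sn: ScoredNetwork,
                cfg: AnnealConfig | None = None) -> Subnetwork:
    """Metropolis search over connected subnetworks around ``start``.

    Moves: add a one-hop network neighbor (with all its induced edges) or
    remove a non-articulation member.  Acceptance min(1, exp(delta/T)),
    geometric cooling, best-seen state returned — so the returned objective is
    never below the start's.  Fully deterministic for a fixed ``cfg.seed``.
    """
    cfg = cfg or AnnealConfig()
    if start.is_empty:
        raise ValueError("cannot anneal an empty subnetwork")
    if not start.is_connected():
        raise ValueError("sa_optimize requires a connected start subnetwork")

    rng = np.random.default_rng(cfg.seed)
    members = set(start.nodes)
    node_total, edge_total = _objective_parts(sn, members)
    current = node_total + edge_total
    best_members = set(members)
    best_obj = current

    adj = {n: sorted(sn.graph.neighbors(n)) for n in sn.graph.nodes}
    has_z = np.isfinite(sn.edge_sd) and sn.edge_sd > 0.0
    zcache = {e: (s - sn.edge_mean) / sn.edge_sd if has_z else 0.0
              for e, s in sn.edge_score.items()}
    ekey = ScoredNetwork.edge_key
    # frontier bookkeeping: count of member neighbors per non-member
    fcount: dict[str, int] = {}
    for m in members:
        for nb in adj[m]:
            if nb not in members:
                fcount[nb] = fcount.get(nb, 0) + 1

    def shift(node: str, joined: bool) -> None:
        for nb in adj[node]:
            if nb in members:
                continue
            c = fcount.get(nb, 0) + (1 if joined else -1)
            if c > 0:
                fcount[nb] = c
            else:
                fcount.pop(nb, None)

    temp = cfg.t_initial
    while temp > cfg.t_final:
        for _ in range(cfg.steps_per_temp):
            frontier = sorted(fcount)
            pool = frontier + sorted(members)
            if not pool:
                break
            node = pool[rng.integers(len(pool))]
            adding = node not in members
            if not adding and (len(members) == 1
                               or _is_articulation(sn, members, node, adj)):
                continue  # illegal removal proposal; rejected outright
            delta_edge = sum(zcache[ekey(node, nb)] for nb in adj[node]
                             if nb in members)
            delta = (sn.node_score[node] + delta_edge if adding
                     else -sn.node_score[node] - delta_edge)
            if delta >= 0 or rng.random() < math.exp(delta / temp):
                if adding:
                    members.add(node)
                    fcount.pop(node, None)
                else:
                    members.discard(node)
                    k = sum(1 for nb in adj[node] if nb in members)
                    if k:
                        fcount[node] = k
                shift(node, adding)
                current += delta
                if current > best_obj + 1e-12:
                    best_obj = current
                    best_members = set(members)
        temp *= cfg.cooling

    result = Subnetwork.from_nodes(sn, best_members)
    if result.objective() < start.objective() - 1e-9:  # bookkeeping guard
        logger.warning("annealer best-seen below start; returning start")
        return start
    return result


def threshold_filter(subnet: Subnetwork, sn: ScoredNetwork,
                     threshold: float = 0.8) -> Subnetwork:
    """Add strong and drop weak interactions among the module's members.

    Edge strength is the absolute background-standardized score |z|.  Every
    network edge between members with strength >= threshold is added; member
    edges below the threshold are removed unless removal would disconnect the
    module — such weak bridges are kept and flagged.  Idempotent; the node
    set never changes.
    """
    if subnet.is_empty:
        return subnet
    members = set(subnet.nodes)
    g = nx.Graph()
    g.add_nodes_from(members)
    g.add_edges_from(subnet.edges)
    # (1) add all strong member-member network edges
    for u, v in sn.induced_edges(members):
        if sn.strength(u, v) >= threshold:
            g.add_edge(u, v)
    # (2) drop weak edges, weakest first, unless they bridge
    weak = sorted(
        (e for e in g.edges if sn.strength(*e) < threshold),
        key=lambda e: (sn.strength(*e), ScoredNetwork.edge_key(*e)),
    )
    weak_bridges = []
    for u, v in weak:
        g.remove_edge(u, v)
        if g.number_of_nodes() > 1 and not _still_connected(g, u, v):
            g.add_edge(u, v)
            weak_bridges.append(ScoredNetwork.edge_key(u, v))
    flags = dict(subnet.flags)
    flags["weak_bridges"] = tuple(sorted(weak_bridges))
    return Subnetwork.from_nodes(sn, members, edges=g.edges, **flags)


def _still_connected(g: nx.Graph, u: str, v: str) -> bool:
    """True if u and v remain connected in g (after an edge removal)."""
    return nx.has_path(g, u, v)
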