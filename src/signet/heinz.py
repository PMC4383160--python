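"""MST-based extraction of maximal-scoring connected subnetworks.

Finding the maximum node-score connected subgraph of a network with positive
and negative scores is a Steiner-tree-like, NP-hard problem; the heuristic
here follows the "heaviest induced subgraph" (Heinz) lineage:

1. score all nodes;
2. turn node scores into edge weights, w(u, v) = -(s(u) + s(v)), so a
   minimum spanning tree seeks high-scoring corridors;
3. compute the MST per connected component (Kruskal, lexicographic
   tie-breaks);
4. within the MST, take the union of the unique tree paths between every
   pair of positive nodes, collecting the negative connector nodes;
5. re-span the induced subgraph on that candidate set with a second MST and
   extract its exact maximum-score subtree (tree dynamic programming, which
   prunes every branch — in particular every negative leaf — whose removal
   raises the total); return the best-scoring result across components.

Exactness on the final tree makes the output satisfy
``node_score_total >= max single node score``; global optimality is still
heuristic, and :func:`oracle_max_subnetwork` provides the exact answer by
enumeration on small instances.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from .scoring import ScoredNetwork, subnetwork_edge_score

__all__ = [
    "Subnetwork", "heinz_edge_weights", "heinz_extract",
    "prune_negative_leaves", "oracle_max_subnetwork",
]


@dataclass
class Subnetwork:
    """A connected node/edge subset of a scored network.

    ``edges`` need not be the full induced edge set (the strong/weak edge
    filter removes weak edges); single-node subnetworks have an empty edge
    set, and an all-empty instance (``nodes == ()``) is the flagged
    "no module" result.
    """

    nodes: tuple[str, ...]
    edges: tuple[tuple[str, str], ...]
    node_score_total: float
    normalized_edge_score: float
    flags: dict = field(default_factory=dict)

    @classmethod
    def from_nodes(cls, sn: ScoredNetwork, nodes, edges=None,
                   **flags) -> "Subnetwork":
        """Build a subnetwork from a node set (induced edges by default)."""
        nodes = tuple(sorted(set(nodes)))
        if edges is None:
            edges = sn.induced_edges(nodes)
        edges = tuple(sorted(ScoredNetwork.edge_key(u, v) for u, v in edges))
        total = float(sum(sn.node_score[n] for n in nodes))
        if edges:
            nes = subnetwork_edge_score(
                [sn.edge_score[e] for e in edges], sn.edge_mean, sn.edge_sd)
        else:
            nes = 0.0
        return cls(nodes, edges, total, nes, dict(flags))

    @classmethod
    def empty(cls, **flags) -> "Subnetwork":
        return cls((), (), 0.0, 0.0, dict(flags))

    @property
    def is_empty(self) -> bool:
        return not self.nodes

    def graph(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(self.nodes)
        g.add_edges_from(self.edges)
        return g

    def is_connected(self) -> bool:
        if not self.nodes:
            return True
        g = self.graph()
        return nx.is_connected(g)

    def objective(self) -> float:
        """Combined node + standardized-edge objective used by the annealer."""
        return self.node_score_total + self.normalized_edge_score


def heinz_edge_weights(sn: ScoredNetwork) -> dict[tuple[str, str], float]:
    """MST weight per edge: w(u, v) = -(score(u) + score(v)).

    Smaller weight = more attractive edge, so the MST gravitates to
    high-scoring corridors.
    """
    return {
        ScoredNetwork.edge_key(u, v): -(sn.node_score[u] + sn.node_score[v])
        for u, v in sn.graph.edges
    }


def _kruskal(nodes, weighted_edges) -> list[tuple[str, str]]:
    """Minimum spanning forest; ties broken lexicographically on (u, v)."""
    parent = {n: n for n in nodes}

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    tree = []
    for w, u, v in sorted((w, *e) for e, w in weighted_edges.items()):
        ru, rv = find(u), find(v)
        if ru != rv:
            parent[ru] = rv
            tree.append((u, v))
    return tree


def _steiner_subtree(tree: nx.Graph, terminals: set[str]) -> set[str]:
    """Union of the unique tree paths between every pair of terminals.

    Computed by repeatedly deleting non-terminal leaves — the classic minimal
    subtree spanning a terminal set.
    """
    keep = set(tree.nodes)
    degree = {n: tree.degree(n) for n in keep}
    leaves = [n for n in keep if degree[n] <= 1 and n not in terminals]
    while leaves:
        leaf = leaves.pop()
        keep.discard(leaf)
        for nb in tree.neighbors(leaf):
            if nb in keep:
                degree[nb] -= 1
                if degree[nb] <= 1 and nb not in terminals:
                    leaves.append(nb)
    return keep


def _best_subtree(tree: nx.Graph, score: dict[str, float]) -> set[str]:
    """Exact maximum-score connected subgraph of a tree (rooted DP).

    ``keep[v]`` is the best total of a subtree containing v within v's rooted
    branch; children contribute only when strictly positive, so ties resolve
    to the smaller node set.  Deterministic: children visited in sorted order,
    equal-total roots resolved to the lexicographically smallest.
    """
    if tree.number_of_nodes() == 0:
        return set()
    root = min(tree.nodes)
    keep: dict[str, float] = {}
    parent: dict[str, str | None] = {root: None}
    order = []
    stack = [root]
    while stack:
        v = stack.pop()
        order.append(v)
        for nb in sorted(tree.neighbors(v)):
            if nb not in parent:
                parent[nb] = v
                stack.append(nb)
    for v in reversed(order):
        total = score[v]
        for nb in tree.neighbors(v):
            if parent.get(nb) == v and keep[nb] > 0.0:
                total += keep[nb]
        keep[v] = total
    best_root = min(tree.nodes, key=lambda v: (-keep[v], v))
    # reconstruct: take best_root, then descend into strictly positive children
    chosen = {best_root}
    stack = [best_root]
    while stack:
        v = stack.pop()
        for nb in sorted(tree.neighbors(v)):
            if parent.get(nb) == v and keep[nb] > 0.0:
                chosen.add(nb)
                stack.append(nb)
    return chosen


def _tree_on(sn: ScoredNetwork, nodes: set[str]) -> nx.Graph:
    """MST of the induced subgraph on ``nodes`` under the Heinz edge weights."""
    weights = {
        ScoredNetwork.edge_key(u, v): -(sn.node_score[u] + sn.node_score[v])
        for u, v in sn.graph.subgraph(nodes).edges
    }
    t = nx.Graph()
    t.add_nodes_from(nodes)
    t.add_edges_from(_kruskal(nodes, weights))
    return t


def heinz_extract(sn: ScoredNetwork) -> Subnetwork:
    """Extract a maximal-scoring connected subnetwork (five-step heuristic).

    Handled per connected component; the best-scoring component result is
    returned.  If the network has no positive node the single highest-scoring
    node is returned (ties to the lexicographically smallest id).
    """
    if sn.graph.number_of_nodes() == 0:
        raise ValueError("empty network")
    positives = set(sn.positive_nodes())
    if not positives:
        best = min(sn.graph.nodes, key=lambda n: (-sn.node_score[n], n))
        return Subnetwork.from_nodes(sn, [best], fallback="no positive node")

    best_nodes: set[str] | None = None
    best_key = None
    for comp in nx.connected_components(sn.graph):
        terms = positives & comp
        if not terms:
            continue
        mst = _tree_on(sn, comp)
        candidates = _steiner_subtree(mst, terms)
        final_tree = _tree_on(sn, candidates)
        chosen = _best_subtree(final_tree, sn.node_score)
        total = sum(sn.node_score[n] for n in chosen)
        key = (-total, tuple(sorted(chosen)))
        if best_key is None or key < best_key:
            best_key, best_nodes = key, chosen
    assert best_nodes is not None
    return Subnetwork.from_nodes(sn, best_nodes)


def prune_negative_leaves(tree: Subnetwork, sn: ScoredNetwork) -> Subnetwork:
    """Iteratively remove negative-score degree-1 nodes while that raises the total.

    Stable order: lowest-score leaf first, ties to the smallest gene id.
    Removing a negative leaf always raises the node-score total, so this
    strips all recursively exposed negative leaves; the result stays
    connected.
    """
    if tree.is_empty or len(tree.nodes) == 1:
        return tree
    if not tree.is_connected():
        raise ValueError("prune_negative_leaves requires a connected subnetwork")
    g = tree.graph()
    while g.number_of_nodes() > 1:
        leaves = [n for n in g.nodes
                  if g.degree(n) == 1 and sn.node_score[n] < 0.0]
        if not leaves:
            break
        victim = min(leaves, key=lambda n: (sn.node_score[n], n))
        g.remove_node(victim)
    return Subnetwork.from_nodes(sn, g.nodes, edges=g.edges, **tree.flags)


def oracle_max_subnetwork(sn: ScoredNetwork, max_nodes: int = 14) -> Subnetwork:
    """Exact maximum node-score connected subgraph by subset enumeration.

    Only for small instances (test oracle); raises beyond ``max_nodes``.
    Ties resolve to the lexicographically smallest node tuple.
    """
    nodes = sorted(sn.graph.nodes)
    n = len(nodes)
    if n == 0:
        raise ValueError("empty network")
    if n > max_nodes or max_nodes > 20:
        raise ValueError(f"{n} nodes exceeds the oracle limit of {max_nodes}")
    idx = {g: i for i, g in enumerate(nodes)}
    adj = [0] * n
    for u, v in sn.graph.edges:
        adj[idx[u]] |= 1 << idx[v]
        adj[idx[v]] |= 1 << idx[u]
    scores = np.array([sn.node_score[g] for g in nodes])

    def connected(mask: int) -> bool:
        start = mask & -mask
        seen = start
        frontier = start
        while frontier:
            nxt = 0
            m = frontier
            while m:
                bit = m & -m
                nxt |= adj[bit.bit_length() - 1]
                m ^= bit
            frontier = nxt & mask & ~seen
            seen |= frontier
        return seen == mask

    best_key = None
    best_mask = 0
    for mask in range(1, 1 << n):
        if not connected(mask):
            continue
        total = float(scores[[i for i in range(n) if mask >> i & 1]].sum())
        members = tuple(nodes[i] for i in range(n) if mask >> i & 1)
        key = (-total, members)
        if best_key is None or key < best_key:
            best_key, best_mask = key, mask
    members = [nodes[i] for i in range(n) if best_mask >> i & 1]
    return Subnetwork.from_nodes(sn, members)
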