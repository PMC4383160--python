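import logging

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from signet.io import ExpressionMatrix
from signet.scoring import BUMFit, ScoredNetwork

logging.getLogger("signet").setLevel(logging.ERROR)


def toy_scored(edges, scores, edge_scores=None, edge_mean=0.0, edge_sd=1.0,
               tau=0.1):
    """Build a ScoredNetwork directly from score dicts (no expression data)."""
    g = nx.Graph()
    g.add_nodes_from(scores)
    g.add_edges_from(edges)
    ekeys = [ScoredNetwork.edge_key(u, v) for u, v in g.edges]
    if edge_scores is None:
        edge_scores = {e: 0.0 for e in ekeys}
    else:
        edge_scores = {ScoredNetwork.edge_key(u, v): s
                       for (u, v), s in edge_scores.items()}
        for e in ekeys:
            edge_scores.setdefault(e, 0.0)
    return ScoredNetwork(
        graph=g, node_score=dict(scores),
        pvalue={n: 0.5 for n in scores},
        edge_score=edge_scores, edge_mean=edge_mean, edge_sd=edge_sd,
        tau=tau, fdr=0.1, fit=BUMFit(a=0.5, lam=0.5, loglik=0.0, n=100),
    )


def random_scored(rng, n_nodes=10, edge_p=0.35, score_sd=2.0):
    """Random connected-ish scored instance for heuristic-quality checks."""
    while True:
        g = nx.gnp_random_graph(n_nodes, edge_p,
                                seed=int(rng.integers(2**31)))
        if g.number_of_edges() > 0:
            break
    names = {i: f"n{i:02d}" for i in g.nodes}
    g = nx.relabel_nodes(g, names)
    scores = {n: float(rng.normal(0.0, score_sd)) for n in sorted(g.nodes)}
    if all(s <= 0 for s in scores.values()):
        best = max(sorted(scores), key=lambda n: scores[n])
        scores[best] = abs(scores[best]) + 0.5
    edge_scores = {ScoredNetwork.edge_key(u, v): float(rng.normal(0.0, 1.0))
                   for u, v in g.edges}
    return toy_scored(g.edges, scores, edge_scores)


@pytest.fixture
def small_expr():
    """4 genes x 6 samples (3 control, 3 case) with one clear signal gene."""
    rng = np.random.default_rng(7)
    data = rng.normal(0.0, 0.3, size=(4, 6))
    data[0, 3:] += 4.0  # gene A strongly up in cases
    samples = [f"s{i}" for i in range(6)]
    df = pd.DataFrame(data, index=["A", "B", "C", "D"], columns=samples)
    cond = pd.Series(["control"] * 3 + ["case"] * 3, index=samples)
    return ExpressionMatrix(df, cond, region="toy")
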