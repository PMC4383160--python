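"""Reading and preprocessing of expression matrices, PPI edge lists and probe maps.

The downstream scoring machinery expects one matched (expression, network)
pair per condition/region: a genes x samples matrix of (log-scale) expression
with control/case labels, and a simple undirected graph on the same gene
identifiers.  This module parses the plain-text interchange formats, collapses
probe-level rows to one row per gene, and intersects the expression gene set
with the interaction network.
"""

from __future__ import annotations

import io as _io
import logging
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

CONTROL = "control"
CASE = "case"
_VALID_CONDITIONS = {CONTROL, CASE}


@dataclass
class ExpressionMatrix:
    """Genes x samples expression values for one region, with condition labels.

    ``data`` is indexed by gene/probe identifier (the index may contain
    duplicates before :func:`collapse_probes`); ``condition`` maps each sample
    (column) to ``"control"`` or ``"case"``.
    """

    data: pd.DataFrame
    condition: pd.Series
    region: str = ""

    @property
    def gene_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    def samples(self, condition: str) -> pd.DataFrame:
        """Sub-matrix of the samples with the given condition label."""
        cols = [s for s in self.data.columns if self.condition[s] == condition]
        return self.data[cols]

    def validate(self, *, require_unique: bool = True) -> None:
        if require_unique and self.data.index.has_duplicates:
            dups = self.data.index[self.data.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate gene identifiers after collapse: {dups[:5]}")
        for cond in _VALID_CONDITIONS:
            n = int((self.condition == cond).sum())
            if n < 2:
                raise ValueError(f"need at least 2 '{cond}' samples, got {n}")
        if self.data.isna().any().any():
            raise ValueError("expression matrix contains missing values")


def _parse_condition_line(line: str, sample_ids: list[str]) -> pd.Series:
    parts = line.rstrip("\n").split("\t")[1:]
    if len(parts) != len(sample_ids):
        raise ValueError(
            f"#condition line has {len(parts)} labels for {len(sample_ids)} samples"
        )
    return pd.Series(parts, index=sample_ids, dtype=object)


def read_condition_table(path) -> pd.Series:
    """Read a two-column (sample_id, condition) TSV into a Series."""
    tab = pd.read_csv(path, sep="\t", header=None, comment="!", dtype=str)
    if tab.shape[1] != 2:
        raise ValueError(f"{path}: expected 2 columns (sample_id, condition)")
    return pd.Series(tab[1].values, index=tab[0].values, dtype=object)


def read_expression(path, format: str = "tsv", condition_path=None,
                    region: str = "") -> ExpressionMatrix:
    """Parse an expression table with sample condition labels.

    ``tsv``: first column = probe/gene id, header row = sample ids; condition
    labels either on a second header line ``#condition<TAB>control...`` or in a
    sidecar two-column TSV given as ``condition_path``.

    ``series_matrix``: a permissive reader for GEO series-matrix-like tables;
    ``!``-prefixed metadata lines are skipped and conditions must come from the
    sidecar.

    Duplicate probe rows are retained (collapse happens later).
    """
    if format not in {"tsv", "series_matrix"}:
        raise ValueError(f"unknown expression format {format!r}")
    with open(path) as fh:
        lines = [ln for ln in fh if ln.strip()]
    if format == "series_matrix":
        lines = [ln for ln in lines if not ln.startswith("!")]
    if not lines:
        raise ValueError(f"{path}: no data lines")

    cond_line = None
    body = []
    for ln in lines:
        if ln.startswith("#condition"):
            cond_line = ln
        elif not ln.startswith("#"):
            body.append(ln)
    header = body[0].rstrip("\n").split("\t")
    sample_ids = header[1:]
    raw = pd.read_csv(
        _io.StringIO("".join(body)), sep="\t", index_col=0, dtype=str
    )
    raw.index = raw.index.astype(str)

    if cond_line is not None:
        condition = _parse_condition_line(cond_line, sample_ids)
    elif condition_path is not None:
        condition = read_condition_table(condition_path)
    else:
        raise ValueError(f"{path}: no condition labels (need #condition line or sidecar)")

    missing = [s for s in sample_ids if s not in condition.index]
    if missing:
        raise ValueError(f"samples lacking a condition label: {missing}")
    condition = condition.reindex(sample_ids)
    unknown = sorted(set(condition) - _VALID_CONDITIONS)
    if unknown:
        bad = [s for s in sample_ids if condition[s] in unknown]
        raise ValueError(
            f"unknown condition labels {unknown} for samples {bad}; "
            f"expected one of {sorted(_VALID_CONDITIONS)}"
        )

    try:
        values = raw.apply(pd.to_numeric, errors="raise")
    except (ValueError, TypeError):
        for i, (probe, row) in enumerate(raw.iterrows()):
            for col, cell in row.items():
                try:
                    float(cell)
                except (TypeError, ValueError):
                    raise ValueError(
                        f"{path}: non-numeric value {cell!r} at row {probe!r} "
                        f"(line {i + 2}), column {col!r}"
                    ) from None
        raise

    if values.index.has_duplicates:
        dups = values.index[values.index.duplicated()].unique().tolist()
        logger.warning("%s: %d duplicated probe ids retained (e.g. %s)",
                       path, len(dups), dups[:3])
    return ExpressionMatrix(values.astype(float), condition, region=region)


def read_ppi(path, format: str = "tsv_edgelist") -> nx.Graph:
    """Read an undirected PPI edge list (2-column TSV or 3-column SIF).

    Duplicate and reversed-duplicate lines are merged.  Self-loop lines are
    kept in the raw graph but flagged with a warning; removing them is a
    preprocessing step (:func:`match_network`).
    """
    if format not in {"tsv_edgelist", "sif"}:
        raise ValueError(f"unknown PPI format {format!r}")
    g = nx.Graph()
    n_self = 0
    with open(path) as fh:
        for lineno, ln in enumerate(fh, start=1):
            if not ln.strip() or ln.startswith("#"):
                continue
            parts = ln.split()
            if format == "sif":
                if len(parts) == 1:
                    g.add_node(parts[0])
                    continue
                if len(parts) != 3:
                    raise ValueError(f"{path}:{lineno}: malformed SIF line {ln!r}")
                u, _, v = parts
            else:
                if len(parts) != 2:
                    raise ValueError(f"{path}:{lineno}: malformed edge line {ln!r}")
                u, v = parts
            if u == v:
                n_self += 1
            g.add_edge(u, v)
    if n_self:
        logger.warning("%s: %d self-loop line(s) read (removed at match_network)",
                       path, n_self)
    if g.number_of_nodes() == 0:
        logger.warning("%s: empty network", path)
    return g


def read_idmap(path) -> dict[str, str]:
    """Read a two-column (probe_id, gene_id) TSV; many-to-one allowed."""
    idmap: dict[str, str] = {}
    with open(path) as fh:
        for lineno, ln in enumerate(fh, start=1):
            if not ln.strip() or ln.startswith("#"):
                continue
            parts = ln.split()
            if len(parts) != 2:
                raise ValueError(f"{path}:{lineno}: malformed idmap line {ln!r}")
            probe, gene = parts
            if not gene:
                raise ValueError(f"{path}:{lineno}: empty gene id")
            if probe in idmap and idmap[probe] != gene:
                raise ValueError(f"{path}:{lineno}: conflicting mapping for {probe!r}")
            idmap[probe] = gene
    return idmap


def collapse_probes(expr: ExpressionMatrix, idmap: dict[str, str],
                    method: str = "max_variance") -> ExpressionMatrix:
    """Collapse probe-level rows to one row per gene.

    Rows with any missing value are dropped first.  A row id that is a key of
    ``idmap`` is mapped to its gene; an id that is already a gene id (a value
    of ``idmap``) passes through, which makes the operation idempotent;
    anything else is dropped (count logged).

    When several probes map to one gene, ``max_variance`` keeps the probe with
    the largest across-sample variance (ties broken by smallest probe id);
    ``mean`` averages the probe rows.
    """
    if method not in {"max_variance", "mean"}:
        raise ValueError(f"unknown collapse method {method!r}")
    data = expr.data
    n_na = int(data.isna().any(axis=1).sum())
    if n_na:
        logger.warning("dropping %d probe row(s) with missing values", n_na)
        data = data.dropna(axis=0)

    gene_values = set(idmap.values())
    targets: list[str | None] = []
    for probe in data.index:
        if probe in idmap:
            targets.append(idmap[probe])
        elif probe in gene_values:
            targets.append(probe)
        else:
            targets.append(None)
    n_unmapped = sum(t is None for t in targets)
    if n_unmapped:
        logger.warning("dropping %d unmapped probe row(s)", n_unmapped)

    keep = [t is not None for t in targets]
    data = data.loc[keep]
    genes = pd.Index([t for t in targets if t is not None], name="gene")

    if method == "mean":
        out = data.groupby(genes, sort=True).mean()
    else:
        variances = data.var(axis=1, ddof=1).to_numpy()
        order = pd.DataFrame({
            "gene": genes.to_numpy(),
            "var": variances,
            "probe": data.index.to_numpy(),
            "pos": np.arange(len(data)),
        })
        # max variance wins; ties go to the lexicographically smallest probe id
        order = order.sort_values(["gene", "var", "probe"],
                                  ascending=[True, False, True], kind="mergesort")
        best = order.drop_duplicates("gene", keep="first").sort_values("gene")
        out = data.iloc[best["pos"].to_numpy()]
        out.index = pd.Index(best["gene"].to_numpy(), name="gene")
    return ExpressionMatrix(out, expr.condition.copy(), region=expr.region)


def match_network(expr: ExpressionMatrix,
                  ppi: nx.Graph) -> tuple[ExpressionMatrix, nx.Graph]:
    """Restrict expression and network to their common gene set.

    Self-loops are removed; isolated matched nodes are retained (an isolated
    positive-score node is a legal degenerate subnetwork).  Raises if the
    intersection is empty.
    """
    genes = sorted(set(expr.data.index) & set(ppi.nodes))
    if not genes:
        raise ValueError("no genes shared between expression matrix and PPI network")
    g = ppi.subgraph(genes).copy()
    g.remove_edges_from(nx.selfloop_edges(g))
    matched = ExpressionMatrix(expr.data.loc[genes], expr.condition.copy(),
                               region=expr.region)
    logger.info("matched %d genes, %d edges (region %s)",
                g.number_of_nodes(), g.number_of_edges(), expr.region or "-")
    return matched, g
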