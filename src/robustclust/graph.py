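"""Pearson co-expression graphs with hard thresholding.

Genes are vertices; every gene pair is weighted by the Pearson
product-moment correlation of their expression profiles, and an edge is
retained iff its weight is at or above a threshold tau.  By default the
comparison is signed (weight >= tau, so strong negative correlations are
dropped); ``absolute=True`` keeps |weight| >= tau instead, as many
co-expression pipelines do.

``suggest_threshold`` is a heuristic: it scans candidate thresholds, tracks
the largest adjacency eigenvalue of the thresholded graph, and proposes the
candidate at the steepest relative drop of that eigenvalue — the point where
the dominant dense structure starts to disintegrate.  Its output is advisory;
every pipeline accepts a user-supplied tau.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from .io import ExpressionMatrix

__all__ = [
    "CorrelationGraph",
    "correlation_matrix",
    "threshold_graph",
    "suggest_threshold",
    "write_edge_list",
    "read_edge_list",
]

_WEIGHT_TOL = 1e-12


@dataclass(frozen=True)
class CorrelationGraph:
    """A thresholded gene-gene correlation graph.

    ``graph`` is an undirected networkx Graph whose nodes are gene ids and
    whose edges carry the Pearson weight; isolated vertices are retained.
    ``tau`` records the threshold used, as provenance.
    """

    graph: nx.Graph
    tau: float
    absolute: bool = field(default=False)

    @property
    def vertices(self) -> tuple[str, ...]:
        return tuple(self.graph.nodes)

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()


def correlation_matrix(expr: ExpressionMatrix) -> pd.DataFrame:
    """All-pairs Pearson correlation of gene expression profiles.

    Requires at least 3 samples and no constant genes (their correlation is
    undefined).  Returns a symmetric DataFrame with unit diagonal, indexed by
    gene id.
    """
    if expr.n_samples < 3:
        raise ValueError(
            f"need >= 3 samples to estimate correlations, got {expr.n_samples}"
        )
    flat = [
        g for g, row in zip(expr.gene_ids, expr.values) if np.ptp(row) == 0.0
    ]
    if flat:
        raise ValueError(
            "constant gene(s) present, Pearson correlation undefined: "
            f"{flat[:10]}; drop them first (ExpressionMatrix.drop_constant)"
        )
    corr = np.corrcoef(expr.values)
    corr = np.clip(corr, -1.0, 1.0)
    np.fill_diagonal(corr, 1.0)
    return pd.DataFrame(corr, index=list(expr.gene_ids), columns=list(expr.gene_ids))


def _as_frame(corr: pd.DataFrame | np.ndarray) -> pd.DataFrame:
    if isinstance(corr, pd.DataFrame):
        return corr
    corr = np.asarray(corr, dtype=float)
    labels = [f"g{i}" for i in range(corr.shape[0])]
    return pd.DataFrame(corr, index=labels, columns=labels)


def threshold_graph(
    corr: pd.DataFrame | np.ndarray,
    tau: float,
    absolute: bool = False,
) -> CorrelationGraph:
    """Apply a hard threshold: keep edges with weight >= tau.

    All genes remain as vertices even when isolated.  With ``absolute=True``
    the criterion is |weight| >= tau.
    """
    if not -1.0 <= tau <= 1.0:
        raise ValueError(f"tau must lie in [-1, 1], got {tau}")
    frame = _as_frame(corr)
    values = frame.to_numpy(dtype=float)
    if values.shape[0] != values.shape[1]:
        raise ValueError("correlation matrix must be square")
    if np.abs(values).max() > 1.0 + _WEIGHT_TOL:
        raise ValueError("correlation weights must lie in [-1, 1]")
    genes = [str(g) for g in frame.index]
    graph = nx.Graph()
    graph.add_nodes_from(genes)
    weights = np.abs(values) if absolute else values
    ii, jj = np.where(np.triu(weights >= tau, k=1))
    graph.add_weighted_edges_from(
        (genes[i], genes[j], float(values[i, j])) for i, j in zip(ii, jj)
    )
    return CorrelationGraph(graph=graph, tau=float(tau), absolute=absolute)


def suggest_threshold(
    corr: pd.DataFrame | np.ndarray,
    candidates: list[float],
) -> tuple[float, pd.DataFrame]:
    """Propose tau from the spectrum of the thresholded adjacency matrix.

    For each candidate tau (sorted ascending, each in [0, 1]) the graph is
    thresholded and the largest eigenvalue of its 0/1 adjacency matrix,
    the edge count and the number of connected components are recorded.  The
    proposed tau is the candidate at which the leading eigenvalue shows the
    steepest relative drop from its predecessor — a topological inflection
    marking where the densest coherent subgraph breaks apart.  Deterministic
    for fixed input.

    Returns ``(tau, diagnostics)`` where diagnostics is a per-candidate
    DataFrame (threshold, n_edges, lead_eigenvalue, n_components).
    """
    candidates = [float(c) for c in candidates]
    if len(candidates) < 3:
        raise ValueError("need >= 3 candidate thresholds to locate an inflection")
    if sorted(candidates) != candidates:
        raise ValueError("candidate thresholds must be sorted ascending")
    if candidates[0] < 0.0 or candidates[-1] > 1.0:
        raise ValueError("candidate thresholds must lie in [0, 1]")
    frame = _as_frame(corr)
    rows = []
    for tau in candidates:
        cg = threshold_graph(frame, tau)
        adj = nx.to_numpy_array(cg.graph, weight=None)
        lead = float(np.linalg.eigvalsh(adj)[-1]) if adj.size else 0.0
        rows.append(
            {
                "threshold": tau,
                "n_edges": cg.n_edges,
                "lead_eigenvalue": lead,
                "n_components": nx.number_connected_components(cg.graph),
            }
        )
    diagnostics = pd.DataFrame(rows)
    lead = diagnostics["lead_eigenvalue"].to_numpy()
    prev = lead[:-1]
    drop = np.where(prev > 0, (prev - lead[1:]) / np.maximum(prev, 1e-300), 0.0)
    best = int(np.argmax(drop)) + 1  # right endpoint of the steepest decline
    return candidates[best], diagnostics


def write_edge_list(cg: CorrelationGraph, path: str | Path) -> Path:
    """Weighted edge list TSV: gene_a, gene_b, weight."""
    path = Path(path)
    lines = ["gene_a\tgene_b\tweight"]
    for a, b, w in sorted(cg.graph.edges(data="weight")):
        lines.append(f"{a}\t{b}\t{w:.6g}")
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")
    return path


def read_edge_list(path: str | Path, tau: float) -> CorrelationGraph:
    path = Path(path)
    graph = nx.Graph()
    with path.open(encoding="utf-8") as handle:
        header = handle.readline()
        if not header.startswith("gene_a"):
            raise ValueError(f"{path}: missing edge-list header")
        for raw in handle:
            if not raw.strip():
                continue
            a, b, w = raw.rstrip("\n").split("\t")
            graph.add_edge(a, b, weight=float(w))
    return CorrelationGraph(graph=graph, tau=float(tau))
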