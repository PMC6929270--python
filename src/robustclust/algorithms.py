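"""Native implementations of the swept clustering methods.

Agglomerative hierarchical clustering (average/UPGMA, complete,
McQuitty/WPGMA, Ward), k-means, quality-threshold (QT) clustering,
self-organizing maps (SOM), paraclique and nearest-neighbor-network (NNN)
clustering, plus an adapter that ingests membership files produced by
external tools (WGCNA, CLICK, ...).

Conventions shared by all operations:

* Correlation-driven methods (hierarchical, QT, NNN, paraclique) use
  Pearson-based measures: dissimilarity 1 - r for hierarchical/QT,
  similarity r for NNN, thresholded correlation graphs for paraclique.
  k-means and SOM are centroid-based and work on the expression profiles
  directly (Euclidean geometry).
* Every tie (nearest centroid, QT candidate, clique ordering, k-NN
  similarity) is broken by lexicographic item id, so every deterministic
  algorithm is bit-reproducible, and the stochastic ones (k-means, SOM) are
  bit-reproducible given a seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import networkx as nx
import numpy as np
import pandas as pd
import scipy.cluster.hierarchy as sch
from scipy.spatial.distance import squareform
from sklearn.cluster import KMeans

from .graph import CorrelationGraph, correlation_matrix
from .io import ExpressionMatrix
from .robustness import ClusterRun, ValidationError

__all__ = [
    "LINKAGES",
    "Dendrogram",
    "ParacliqueParams",
    "NNNParams",
    "expression_dissimilarity",
    "build_dendrogram",
    "cut_dendrogram",
    "hierarchical_cluster",
    "kmeans_cluster",
    "qt_cluster",
    "som_cluster",
    "maximum_cliques",
    "paraclique_cluster",
    "nnn_cluster",
    "ingest_external_run",
]

#: Implemented linkage criteria mapped to their scipy method names.
#: McQuitty is WPGMA; Ward follows the squared-dissimilarity (ward.D2-style)
#: convention that scipy applies to a precomputed distance matrix.
LINKAGES = {
    "average": "average",
    "complete": "complete",
    "mcquitty": "weighted",
    "ward": "ward",
}


def _square(
    matrix: pd.DataFrame | np.ndarray,
    labels: Sequence[str] | None = None,
    *,
    zero_diagonal: bool,
) -> tuple[np.ndarray, list[str]]:
    """Validate a square symmetric matrix and resolve its item labels."""
    if isinstance(matrix, pd.DataFrame):
        labels = [str(x) for x in matrix.index]
        values = matrix.to_numpy(dtype=float)
    else:
        values = np.asarray(matrix, dtype=float)
        if labels is None:
            labels = [f"g{i}" for i in range(values.shape[0])]
        labels = [str(x) for x in labels]
    if values.ndim != 2 or values.shape[0] != values.shape[1]:
        raise ValueError(f"expected a square matrix, got shape {values.shape}")
    if len(labels) != values.shape[0]:
        raise ValueError("label count does not match matrix size")
    if not np.allclose(values, values.T, atol=1e-10):
        raise ValueError("matrix must be symmetric")
    if zero_diagonal and not np.allclose(np.diag(values), 0.0, atol=1e-10):
        raise ValueError("dissimilarity matrix must have a zero diagonal")
    return values, labels


def _run_from_labels(
    assignment: Sequence[int],
    items: Sequence[str],
    run_id: str,
    setting_value: str,
) -> ClusterRun:
    clusters: dict[int, set[str]] = {}
    for item, lab in zip(items, assignment):
        clusters.setdefault(int(lab), set()).add(item)
    ordered = sorted(clusters.values(), key=lambda c: min(c))
    return ClusterRun(
        run_id=run_id,
        setting_value=setting_value,
        clusters=tuple(frozenset(c) for c in ordered),
    )


def expression_dissimilarity(
    expr: ExpressionMatrix, metric: str = "correlation"
) -> pd.DataFrame:
    """Gene-gene dissimilarity matrix: 1 - Pearson r (default) or Euclidean."""
    if metric == "correlation":
        corr = correlation_matrix(expr)
        dissim = 1.0 - corr.to_numpy()
        np.fill_diagonal(dissim, 0.0)
        dissim = np.clip(dissim, 0.0, 2.0)
        dissim = (dissim + dissim.T) / 2.0
        return pd.DataFrame(dissim, index=corr.index, columns=corr.columns)
    if metric == "euclidean":
        from scipy.spatial.distance import pdist

        dissim = squareform(pdist(expr.values))
        return pd.DataFrame(
            dissim, index=list(expr.gene_ids), columns=list(expr.gene_ids)
        )
    raise ValueError(f"unknown metric {metric!r}")


# ---------------------------------------------------------------------------
# hierarchical clustering


@dataclass(frozen=True)
class Dendrogram:
    """An agglomerative merge tree over n items.

    ``merges`` is the scipy linkage matrix: n-1 rows of
    (left, right, height, size).  Heights are non-decreasing for the four
    implemented linkages on valid dissimilarities (they are monotone).
    Cutting the same tree at k' < k clusters always coarsens the k-cut.
    """

    merges: np.ndarray
    labels: tuple[str, ...]
    linkage: str

    @property
    def n_items(self) -> int:
        return len(self.labels)


def build_dendrogram(
    dissim: pd.DataFrame | np.ndarray,
    linkage: str,
    labels: Sequence[str] | None = None,
) -> Dendrogram:
    """Agglomerate a dissimilarity matrix under the named linkage criterion."""
    if linkage not in LINKAGES:
        raise ValueError(
            f"unknown linkage {linkage!r}; choose from {sorted(LINKAGES)}"
        )
    values, items = _square(dissim, labels, zero_diagonal=True)
    condensed = squareform(values, checks=False)
    merges = sch.linkage(condensed, method=LINKAGES[linkage])
    return Dendrogram(merges=merges, labels=tuple(items), linkage=linkage)


def cut_dendrogram(dendro: Dendrogram, n_clusters: int, run_id: str = "") -> ClusterRun:
    """Cut the merge tree into exactly ``n_clusters`` disjoint clusters."""
    n = dendro.n_items
    if not 1 <= n_clusters <= n:
        raise ValueError(f"n_clusters must lie in [1, {n}], got {n_clusters}")
    assignment = sch.cut_tree(dendro.merges, n_clusters=n_clusters).ravel()
    return _run_from_labels(
        assignment,
        dendro.labels,
        run_id or f"{dendro.linkage}-k{n_clusters}",
        f"n_clusters={n_clusters}",
    )


def hierarchical_cluster(
    dissim: pd.DataFrame | np.ndarray,
    linkage: str,
    n_clusters: int,
    labels: Sequence[str] | None = None,
) -> ClusterRun:
    """Agglomerate, then cut into exactly ``n_clusters`` clusters."""
    return cut_dendrogram(build_dendrogram(dissim, linkage, labels), n_clusters)


# ---------------------------------------------------------------------------
# k-means


def _profiles(expr: ExpressionMatrix, standardize: bool) -> np.ndarray:
    """Gene profiles for centroid-based methods.

    With ``standardize`` (the default) each gene is z-scored across samples,
    so Euclidean distance reflects profile shape (proportional to
    1 - Pearson r) rather than absolute log2 intensity; constant genes
    cannot be standardized and are rejected.
    """
    values = np.asarray(expr.values, dtype=float)
    if not standardize:
        return values
    sd = values.std(axis=1, keepdims=True)
    if np.any(sd == 0):
        bad = [g for g, s in zip(expr.gene_ids, sd.ravel()) if s == 0]
        raise ValueError(f"constant gene(s) cannot be standardized: {bad[:10]}")
    return (values - values.mean(axis=1, keepdims=True)) / sd


def kmeans_cluster(
    expr: ExpressionMatrix, k: int, seed: int, standardize: bool = True
) -> ClusterRun:
    """k-means on expression profiles (Euclidean), deterministic per seed.

    Profiles are z-scored per gene by default (see ``_profiles``).  Clusters
    that end up empty are dropped, so a run may carry fewer than k clusters;
    robustness consumes only the partition.
    """
    n = expr.n_genes
    if not 1 <= k <= n:
        raise ValueError(f"k must lie in [1, {n}], got {k}")
    model = KMeans(n_clusters=k, random_state=int(seed), n_init=10)
    assignment = model.fit_predict(_profiles(expr, standardize))
    return _run_from_labels(
        assignment, expr.gene_ids, f"kmeans-k{k}", f"k={k}"
    )


# ---------------------------------------------------------------------------
# QT clustering


def qt_cluster(
    dissim: pd.DataFrame | np.ndarray,
    max_diameter: float,
    labels: Sequence[str] | None = None,
) -> ClusterRun:
    """Quality-threshold clustering under a maximum cluster diameter.

    For every remaining item a candidate cluster is grown greedily: start
    from the seed and repeatedly add the item that minimizes the resulting
    diameter (max pairwise dissimilarity), stopping when no addition stays
    within ``max_diameter``.  The largest candidate is extracted, its items
    removed, and the process repeats until nothing remains.  Candidate-size
    ties go to the lexicographically lowest seed id; within-growth ties go
    to the lexicographically lowest item id.
    """
    if max_diameter <= 0:
        raise ValueError(f"max_diameter must be positive, got {max_diameter}")
    values, items = _square(dissim, labels, zero_diagonal=True)
    index = {item: i for i, item in enumerate(items)}
    remaining = sorted(items)
    clusters: list[frozenset[str]] = []
    while remaining:
        best_candidate: list[str] | None = None
        for seed in remaining:  # lexicographic seed order; strict > keeps first
            candidate = _qt_grow(seed, remaining, values, index, max_diameter)
            if best_candidate is None or len(candidate) > len(best_candidate):
                best_candidate = candidate
        assert best_candidate is not None
        clusters.append(frozenset(best_candidate))
        chosen = set(best_candidate)
        remaining = [x for x in remaining if x not in chosen]
    return ClusterRun(
        run_id=f"qt-d{max_diameter:g}",
        setting_value=f"max_diameter={max_diameter:g}",
        clusters=tuple(clusters),
    )


def _qt_grow(
    seed: str,
    remaining: list[str],
    values: np.ndarray,
    index: dict[str, int],
    max_diameter: float,
) -> list[str]:
    cluster = [seed]
    in_cluster = {seed}
    # max dissimilarity from each outside item to the current cluster
    reach = {x: values[index[seed], index[x]] for x in remaining if x != seed}
    while True:
        best_item = None
        best_diam = None
        for item in sorted(reach):  # lexicographic tie-break via strict <
            if best_diam is None or reach[item] < best_diam:
                best_item, best_diam = item, reach[item]
        if best_item is None or best_diam > max_diameter:
            break
        cluster.append(best_item)
        in_cluster.add(best_item)
        del reach[best_item]
        bi = index[best_item]
        for item in reach:
            reach[item] = max(reach[item], values[bi, index[item]])
    return cluster


# ---------------------------------------------------------------------------
# SOM


def _grid_positions(rows: int, cols: int, topology: str) -> np.ndarray:
    """Node coordinates for the map lattice (rectangular or hexagonal offset)."""
    pos = []
    for i in range(rows):
        for j in range(cols):
            if topology == "hexagonal":
                pos.append((j + 0.5 * (i % 2), i * np.sqrt(3.0) / 2.0))
            else:
                pos.append((float(j), float(i)))
    return np.asarray(pos)


def som_cluster(
    expr: ExpressionMatrix,
    grid_rows: int,
    grid_cols: int,
    topology: str = "rectangular",
    seed: int = 0,
    presentations_per_item: int = 100,
    standardize: bool = True,
) -> ClusterRun:
    """Self-organizing map; one cluster per non-empty grid node.

    Profiles are z-scored per gene by default (see ``_profiles``).  Online
    training with a fixed, documented schedule: 100 presentations per item
    (in reshuffled epochs), learning rate decaying linearly from 0.05 to
    0.01, and a Gaussian neighborhood whose radius decays linearly from half
    the grid diagonal to 1.  The codebook is initialized by sampling item
    profiles.  Bit-reproducible for a fixed seed.
    """
    if topology not in ("rectangular", "hexagonal"):
        raise ValueError(f"topology must be rectangular or hexagonal, got {topology!r}")
    n = expr.n_genes
    n_nodes = grid_rows * grid_cols
    if n_nodes > n:
        raise ValueError(
            f"grid {grid_rows}x{grid_cols} has more nodes ({n_nodes}) than items ({n})"
        )
    if n_nodes < 1:
        raise ValueError("grid must have at least one node")
    rng = np.random.default_rng(int(seed))
    data = _profiles(expr, standardize)
    pos = _grid_positions(grid_rows, grid_cols, topology)
    grid_d2 = ((pos[:, None, :] - pos[None, :, :]) ** 2).sum(-1)

    codebook = data[rng.choice(n, size=n_nodes, replace=False)].copy()
    total = presentations_per_item * n
    diag = float(np.sqrt(grid_d2.max())) if n_nodes > 1 else 1.0
    sigma0, sigma1 = max(diag / 2.0, 1.0), 1.0
    lr0, lr1 = 0.05, 0.01

    step = 0
    for _ in range(presentations_per_item):
        for idx in rng.permutation(n):
            frac = step / max(total - 1, 1)
            lr = lr0 + (lr1 - lr0) * frac
            sigma = sigma0 + (sigma1 - sigma0) * frac
            x = data[idx]
            d2 = ((codebook - x) ** 2).sum(axis=1)
            bmu = int(np.argmin(d2))  # ties -> lowest node index
            h = np.exp(-grid_d2[bmu] / (2.0 * sigma * sigma))
            codebook += (lr * h)[:, None] * (x - codebook)
            step += 1

    d2 = ((data[:, None, :] - codebook[None, :, :]) ** 2).sum(-1)
    assignment = np.argmin(d2, axis=1)
    return _run_from_labels(
        assignment,
        expr.gene_ids,
        f"som-{grid_rows}x{grid_cols}-{topology}",
        f"grid={grid_rows}x{grid_cols}:{topology}",
    )


# ---------------------------------------------------------------------------
# maximum cliques / paraclique


def _as_nx(graph: CorrelationGraph | nx.Graph) -> nx.Graph:
    return graph.graph if isinstance(graph, CorrelationGraph) else graph


def maximum_cliques(graph: CorrelationGraph | nx.Graph) -> list[frozenset[str]]:
    """All cliques of maximum cardinality, in lexicographic order.

    Maximal cliques are enumerated (Bron-Kerbosch via networkx) and those of
    maximum size kept, deduplicated, and ordered by their sorted vertex ids.
    An edgeless graph has no clique of size >= 2 and yields an empty list.
    """
    g = _as_nx(graph)
    if g.number_of_edges() == 0:
        return []
    cliques = [frozenset(c) for c in nx.find_cliques(g)]
    top = max(len(c) for c in cliques)
    best = {c for c in cliques if len(c) == top}
    return sorted(best, key=lambda c: tuple(sorted(c)))


@dataclass(frozen=True)
class ParacliqueParams:
    """Settings for paraclique extraction.

    ``starting_clique_index`` selects which maximum clique (in lexicographic
    order) seeds the first paraclique — the setting varied in robustness
    sweeps.  ``glom_factor`` g admits a vertex once it is adjacent to at
    least (current paraclique size - g) members.  Extraction stops when the
    residual graph's maximum clique falls below ``min_clique_size``, or when
    ``max_paracliques`` have been emitted.
    """

    starting_clique_index: int = 0
    glom_factor: int = 1
    min_clique_size: int = 3
    max_paracliques: int | None = None

    def __post_init__(self) -> None:
        if self.starting_clique_index < 0:
            raise ValueError("starting_clique_index must be >= 0")
        if self.glom_factor < 1:
            raise ValueError("glom_factor must be >= 1")
        if self.min_clique_size < 3:
            raise ValueError("min_clique_size must be >= 3")


def paraclique_cluster(
    graph: CorrelationGraph | nx.Graph,
    params: ParacliqueParams,
) -> ClusterRun:
    """Extract paracliques: maximum cliques glommed with high-degree vertices.

    The first paraclique is seeded from the maximum clique selected by
    ``starting_clique_index``; accretion repeatedly admits the
    lexicographically lowest vertex adjacent to at least
    (current size - g) paraclique members, rescanning until fixpoint.  The
    paraclique's vertices are removed and the process repeats, seeding from
    the first maximum clique of the residual graph, until the residual
    maximum clique is smaller than ``min_clique_size``.  Residual vertices
    stay unclustered.
    """
    g = _as_nx(graph).copy()
    clusters: list[frozenset[str]] = []
    first = True
    while True:
        if params.max_paracliques is not None and len(clusters) >= params.max_paracliques:
            break
        cliques = maximum_cliques(g)
        if not cliques or len(cliques[0]) < params.min_clique_size:
            if first and params.starting_clique_index > 0:
                raise ValueError(
                    f"starting_clique_index={params.starting_clique_index} out "
                    f"of range: graph has {len(cliques)} maximum clique(s)"
                )
            break
        if first:
            if params.starting_clique_index >= len(cliques):
                raise ValueError(
                    f"starting_clique_index={params.starting_clique_index} out "
                    f"of range: graph has {len(cliques)} maximum clique(s)"
                )
            seed = cliques[params.starting_clique_index]
            first = False
        else:
            seed = cliques[0]
        if params.glom_factor >= len(seed):
            raise ValueError(
                f"glom factor {params.glom_factor} must be smaller than the "
                f"seed clique size {len(seed)}"
            )
        para = set(seed)
        changed = True
        while changed:
            changed = False
            for v in sorted(set(g.nodes) - para):
                if sum(1 for u in para if g.has_edge(u, v)) >= len(para) - params.glom_factor:
                    para.add(v)
                    changed = True
                    break  # rescan from the lexicographic start
        clusters.append(frozenset(para))
        g.remove_nodes_from(para)
    return ClusterRun(
        run_id=f"paraclique-i{params.starting_clique_index}",
        setting_value=f"starting_clique={params.starting_clique_index}",
        clusters=tuple(clusters),
    )


# ---------------------------------------------------------------------------
# NNN


@dataclass(frozen=True)
class NNNParams:
    """Settings for nearest-neighbor-network clustering.

    ``k`` is the neighborhood size (the swept setting); ``clique_size`` is
    the fixed, small clique order used to assemble initial networks.  The
    largest admissible cluster is half the item count (fixed fraction 0.5).
    """

    k: int
    clique_size: int = 3
    max_cluster_fraction: float = field(default=0.5)

    def __post_init__(self) -> None:
        if self.k < 2:
            raise ValueError("neighborhood size k must be >= 2")
        if self.clique_size < 3:
            raise ValueError("clique_size must be >= 3")
        if self.k < self.clique_size - 1:
            raise ValueError("k must be >= clique_size - 1")


def nnn_cluster(
    similarity: pd.DataFrame | np.ndarray,
    params: NNNParams,
    labels: Sequence[str] | None = None,
) -> ClusterRun:
    """Nearest-neighbor-network clustering on a similarity matrix.

    Steps: (1) connect each item to its k most similar others (ties by id),
    symmetrized by union; (2) enumerate all cliques of exactly
    ``clique_size`` in that graph; (3) merge cliques sharing a vertex into
    preliminary networks; (4) split each network at its articulation points
    (biconnected decomposition — an articulation vertex would belong to each
    resulting block, and is assigned to the first block by cluster order so
    the output partition stays non-overlapping); (5) recursively split any
    cluster larger than half the item count by removing its weakest
    similarity edges until it disconnects.  Items in no clique stay
    unclustered.
    """
    values, items = _square(similarity, labels, zero_diagonal=False)
    n = len(items)
    if params.k >= n:
        raise ValueError(f"k={params.k} must be smaller than the item count {n}")
    # (1) symmetrized k-NN graph; ties in similarity broken by item id
    knn = nx.Graph()
    knn.add_nodes_from(items)
    for i, u in enumerate(items):
        sims = [(-values[i, j], items[j]) for j in range(n) if j != i]
        sims.sort()
        for _, v in sims[: params.k]:
            knn.add_edge(u, v)

    # (2) all cliques of exactly clique_size
    cliques: list[frozenset[str]] = []
    for c in nx.enumerate_all_cliques(knn):
        if len(c) > params.clique_size:
            break
        if len(c) == params.clique_size:
            cliques.append(frozenset(c))
    if not cliques:
        return ClusterRun(
            run_id=f"nnn-k{params.k}", setting_value=f"k={params.k}", clusters=()
        )

    # (3) merge overlapping cliques into preliminary networks
    parent: dict[str, str] = {}

    def find(x: str) -> str:
        while parent.get(x, x) != x:
            parent[x] = parent.get(parent[x], parent[x])
            x = parent[x]
        return x

    for clique in cliques:
        members = sorted(clique)
        for other in members[1:]:
            ra, rb = find(members[0]), find(other)
            if ra != rb:
                parent[rb] = ra
    networks: dict[str, set[str]] = {}
    for clique in cliques:
        for v in clique:
            networks.setdefault(find(v), set()).add(v)

    # (4) split at articulation points
    blocks: list[set[str]] = []
    for group in networks.values():
        sub = knn.subgraph(group)
        parts = [set(b) for b in nx.biconnected_components(sub)]
        parts = [b for b in parts if len(b) >= 2] or [set(group)]
        blocks.extend(parts)

    # (5) cap cluster size at half the item universe (items are whole, so
    # the admissible maximum is ceil(fraction * n))
    limit = max(int(np.ceil(params.max_cluster_fraction * n)), 1)
    final: list[set[str]] = []
    queue = list(blocks)
    while queue:
        block = queue.pop()
        if len(block) <= limit:
            final.append(block)
            continue
        queue.extend(_split_weakest(knn.subgraph(block).copy(), values,
                                    {item: i for i, item in enumerate(items)}))

    # articulation vertices may sit in several blocks; keep first occurrence
    final.sort(key=lambda b: tuple(sorted(b)))
    seen: set[str] = set()
    clusters = []
    for block in final:
        kept = frozenset(block - seen)
        if len(kept) >= 2:
            clusters.append(kept)
            seen.update(kept)
    return ClusterRun(
        run_id=f"nnn-k{params.k}",
        setting_value=f"k={params.k}",
        clusters=tuple(clusters),
    )


def _split_weakest(
    sub: nx.Graph, values: np.ndarray, index: dict[str, int]
) -> list[set[str]]:
    """Remove weakest-similarity edges (ties by id) until the graph splits."""
    edges = sorted(
        sub.edges(),
        key=lambda e: (values[index[e[0]], index[e[1]]], tuple(sorted(e))),
    )
    for a, b in edges:
        sub.remove_edge(a, b)
        if not nx.is_connected(sub):
            comps = [set(c) for c in nx.connected_components(sub)]
            return [c for c in comps if len(c) >= 2]
    return [set(sub.nodes)]  # fully disconnected: give up splitting


# ---------------------------------------------------------------------------
# external runs


def ingest_external_run(
    path: str | Path,
    algorithm: str,
    setting_value: str = "",
    exclude_labels: Sequence[str] = (),
    allow_shared: bool = False,
) -> ClusterRun:
    """Read a membership file produced by an external tool (WGCNA, CLICK, ...).

    ``exclude_labels`` drops pseudo-clusters such as WGCNA's grey/unassigned
    module.  With ``allow_shared=True`` (for NNN-style output) an item listed
    in exactly two clusters is kept in the first of them, matching the
    pair-counting convention; any other overlap is rejected.
    """
    path = Path(path)
    clusters: dict[str, list[str]] = {}
    with path.open(encoding="utf-8") as handle:
        for lineno, raw in enumerate(handle, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise ValidationError(
                    f"{path}:{lineno}: expected 'cluster_id<TAB>item_id', got {line!r}"
                )
            cluster_id, item_id = parts
            if cluster_id in set(exclude_labels):
                continue
            clusters.setdefault(cluster_id, []).append(item_id)
    occurrences: dict[str, int] = {}
    for members in clusters.values():
        for item in members:
            occurrences[item] = occurrences.get(item, 0) + 1
    shared = {item for item, c in occurrences.items() if c > 1}
    if shared and not allow_shared:
        raise ValidationError(
            f"{path}: item(s) in more than one cluster: {sorted(shared)[:10]}"
        )
    if any(c > 2 for c in occurrences.values()):
        raise ValidationError(
            f"{path}: item(s) in more than two clusters; only a single shared "
            "element between two clusters is admissible"
        )
    seen: set[str] = set()
    cleaned = []
    for cluster_id in clusters:  # file order; shared item stays in first cluster
        members = [x for x in clusters[cluster_id] if x not in seen]
        seen.update(members)
        if members:
            cleaned.append(frozenset(members))
    if not cleaned:
        raise ValidationError(f"{path}: no clusters after exclusions")
    return ClusterRun(
        run_id=path.stem,
        setting_value=setting_value or algorithm,
        clusters=tuple(cleaned),
    )
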