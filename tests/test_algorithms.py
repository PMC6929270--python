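"""Tests for the clustering algorithm suite."""

from __future__ import annotations

from itertools import combinations

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from robustclust import (
    ExpressionMatrix,
    NNNParams,
    ParacliqueParams,
    SyntheticConfig,
    ValidationError,
    correlation_matrix,
    generate_expression,
    hierarchical_cluster,
    ingest_external_run,
    kmeans_cluster,
    maximum_cliques,
    nnn_cluster,
    paraclique_cluster,
    qt_cluster,
    som_cluster,
)
from robustclust.algorithms import build_dendrogram, cut_dendrogram


def random_dissim(rng, n):
    m = rng.uniform(0, 1, (n, n))
    d = (m + m.T) / 2.0
    np.fill_diagonal(d, 0.0)
    return d


def partition_of(run):
    return {frozenset(c) for c in run.clusters}


# ---------------------------------------------------------------------------
# hierarchical


class TestHierarchical:
    @pytest.mark.parametrize("linkage", ["average", "complete", "mcquitty", "ward"])
    def test_extreme_cuts(self, linkage):
        d = random_dissim(np.random.default_rng(0), 6)
        all_one = hierarchical_cluster(d, linkage, 1)
        assert partition_of(all_one) == {frozenset(f"g{i}" for i in range(6))}
        singles = hierarchical_cluster(d, linkage, 6)
        assert len(singles.clusters) == 6

    @pytest.mark.parametrize("linkage", ["average", "complete", "mcquitty", "ward"])
    def test_two_tight_groups_recovered(self, linkage):
        """Six points in two tight groups; the 2-cut equals the partition
        minimizing the maximum intra-group distance (checked by brute force
        over all 2-partitions)."""
        pts = np.array([[0.0, 0], [0.1, 0], [0.2, 0], [5.0, 0], [5.1, 0], [5.2, 0]])
        d = np.sqrt(((pts[:, None] - pts[None]) ** 2).sum(-1))
        run = hierarchical_cluster(d, linkage, 2)
        items = [f"g{i}" for i in range(6)]
        best, best_cost = None, np.inf
        for mask in range(1, 2**5):  # item 0 stays in part A
            a = {items[i] for i in range(6) if i == 0 or (mask >> (i - 1)) & 1}
            b = set(items) - a
            if not b:
                continue
            cost = 0.0
            for part in (a, b):
                idx = [items.index(x) for x in part]
                for i, j in combinations(idx, 2):
                    cost = max(cost, d[i, j])
            if cost < best_cost:
                best, best_cost = {frozenset(a), frozenset(b)}, cost
        assert partition_of(run) == best

    def test_non_symmetric_rejected(self):
        bad = np.array([[0.0, 1.0], [2.0, 0.0]])
        with pytest.raises(ValueError, match="symmetric"):
            hierarchical_cluster(bad, "average", 1)

    @pytest.mark.parametrize("linkage", ["average", "complete", "mcquitty", "ward"])
    def test_cuts_are_nested(self, linkage):
        """Co-clustered at a finer cut implies co-clustered at any coarser
        cut of the same tree."""
        rng = np.random.default_rng(9)
        for _ in range(5):
            d = random_dissim(rng, 30)
            dendro = build_dendrogram(d, linkage)
            runs = [cut_dendrogram(dendro, k) for k in (20, 12, 6, 2)]
            for fine, coarse in zip(runs, runs[1:]):
                for cluster in fine.clusters:
                    for a, b in combinations(sorted(cluster), 2):
                        assert coarse.contains_pair((a, b))

    @pytest.mark.parametrize("linkage", ["average", "complete", "mcquitty", "ward"])
    def test_merge_heights_monotone(self, linkage):
        d = random_dissim(np.random.default_rng(3), 15)
        dendro = build_dendrogram(d, linkage)
        heights = dendro.merges[:, 2]
        assert (np.diff(heights) >= -1e-12).all()


# ---------------------------------------------------------------------------
# k-means


class TestKMeans:
    @pytest.fixture()
    def two_modules(self):
        config = SyntheticConfig(
            n_modules=2, module_sizes=(15, 15), n_background=0,
            n_samples=40, seed=5,
        )
        return generate_expression(config)

    def test_k_equals_n_gives_singletons(self, two_modules):
        expr, _ = two_modules
        run = kmeans_cluster(expr, expr.n_genes, seed=0)
        assert all(len(c) == 1 for c in run.clusters)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_separated_modules_recovered_any_seed(self, two_modules, seed):
        expr, labels = two_modules
        run = kmeans_cluster(expr, 2, seed=seed)
        assert partition_of(run) == {
            frozenset(g for g in expr.gene_ids if labels[g] == "module1"),
            frozenset(g for g in expr.gene_ids if labels[g] == "module2"),
        }

    def test_same_seed_is_bit_reproducible(self, two_modules):
        expr, _ = two_modules
        assert kmeans_cluster(expr, 4, seed=7) == kmeans_cluster(expr, 4, seed=7)

    def test_k_above_n_rejected(self, two_modules):
        expr, _ = two_modules
        with pytest.raises(ValueError):
            kmeans_cluster(expr, expr.n_genes + 1, seed=0)


# ---------------------------------------------------------------------------
# QT


def qt_oracle_max_size(d, cap):
    """Brute force: the largest subset whose diameter fits under the cap."""
    n = d.shape[0]
    best = 1
    for r in range(2, n + 1):
        for subset in combinations(range(n), r):
            if max(d[i, j] for i, j in combinations(subset, 2)) <= cap:
                best = max(best, r)
    return best


class TestQT:
    def test_tiny_cap_gives_singletons(self):
        d = random_dissim(np.random.default_rng(2), 6)
        run = qt_cluster(d, 1e-6)
        assert all(len(c) == 1 for c in run.clusters)

    def test_huge_cap_gives_one_cluster(self):
        d = random_dissim(np.random.default_rng(2), 6)
        run = qt_cluster(d, 10.0)
        assert len(run.clusters) == 1

    def test_matches_exhaustive_oracle_round_by_round(self):
        """On 5-item instances the greedily extracted cluster attains the
        brute-force maximum feasible size at every extraction round."""
        rng = np.random.default_rng(17)
        for _ in range(40):
            d = random_dissim(rng, 5)
            cap = 0.5
            run = qt_cluster(d, cap)
            items = [f"g{i}" for i in range(5)]
            remaining = list(range(5))
            for cluster in run.clusters:
                sub = d[np.ix_(remaining, remaining)]
                assert len(cluster) == qt_oracle_max_size(sub, cap)
                remaining = [i for i in remaining if items[i] not in cluster]
            assert not remaining

    def test_diameter_bound_always_respected(self):
        rng = np.random.default_rng(23)
        for _ in range(20):
            n = int(rng.integers(4, 12))
            d = random_dissim(rng, n)
            cap = float(rng.uniform(0.2, 0.8))
            run = qt_cluster(d, cap)
            labels = [f"g{i}" for i in range(n)]
            for cluster in run.clusters:
                idx = [labels.index(x) for x in cluster]
                for i, j in combinations(idx, 2):
                    assert d[i, j] <= cap

    def test_invalid_cap_rejected(self):
        with pytest.raises(ValueError):
            qt_cluster(np.zeros((2, 2)), 0.0)


# ---------------------------------------------------------------------------
# SOM


class TestSOM:
    @pytest.fixture()
    def four_modules(self):
        config = SyntheticConfig(
            n_modules=4, module_sizes=(12,) * 4, n_background=0,
            n_samples=30, seed=3,
        )
        return generate_expression(config)

    def test_single_node_grid_is_one_cluster(self, four_modules):
        expr, _ = four_modules
        run = som_cluster(expr, 1, 1, seed=0)
        assert partition_of(run) == {frozenset(expr.gene_ids)}

    def test_same_seed_identical(self, four_modules):
        expr, _ = four_modules
        a = som_cluster(expr, 2, 2, "hexagonal", seed=4)
        b = som_cluster(expr, 2, 2, "hexagonal", seed=4)
        assert a == b

    def test_nodes_dominated_by_planted_modules(self, four_modules):
        expr, labels = four_modules
        run = som_cluster(expr, 2, 2, "rectangular", seed=0)
        for cluster in run.clusters:
            counts: dict[str, int] = {}
            for g in cluster:
                counts[labels[g]] = counts.get(labels[g], 0) + 1
            assert max(counts.values()) / len(cluster) >= 0.8

    def test_grid_larger_than_items_rejected(self, four_modules):
        expr, _ = four_modules
        with pytest.raises(ValueError, match="grid"):
            som_cluster(expr, 10, 10, seed=0)


# ---------------------------------------------------------------------------
# cliques / paraclique


def brute_force_max_cliques(g: nx.Graph):
    nodes = sorted(g.nodes)
    best: list[frozenset] = []
    size = 0
    for r in range(2, len(nodes) + 1):
        for subset in combinations(nodes, r):
            if all(g.has_edge(a, b) for a, b in combinations(subset, 2)):
                if r > size:
                    best, size = [frozenset(subset)], r
                elif r == size:
                    best.append(frozenset(subset))
    return sorted(set(best), key=lambda c: tuple(sorted(c)))


class TestMaximumCliques:
    def test_triangle_with_pendant(self):
        g = nx.Graph([("a", "b"), ("b", "c"), ("a", "c"), ("c", "d")])
        assert maximum_cliques(g) == [frozenset({"a", "b", "c"})]

    def test_k22_has_four_edge_cliques(self):
        g = nx.complete_bipartite_graph(2, 2)
        g = nx.relabel_nodes(g, {0: "a", 1: "b", 2: "x", 3: "y"})
        assert len(maximum_cliques(g)) == 4

    def test_two_disjoint_k4s_both_listed(self):
        g = nx.disjoint_union(nx.complete_graph(4), nx.complete_graph(4))
        g = nx.relabel_nodes(g, {i: f"v{i}" for i in g.nodes})
        cliques = maximum_cliques(g)
        assert len(cliques) == 2 and all(len(c) == 4 for c in cliques)

    def test_edgeless_graph_gives_empty_list(self):
        g = nx.empty_graph(5)
        assert maximum_cliques(g) == []

    def test_matches_brute_force_on_random_graphs(self):
        rng = np.random.default_rng(31)
        for _ in range(60):
            n = int(rng.integers(3, 11))
            p = float(rng.uniform(0.2, 0.8))
            g = nx.gnp_random_graph(n, p, seed=int(rng.integers(1 << 30)))
            g = nx.relabel_nodes(g, {i: f"v{i:02d}" for i in g.nodes})
            assert maximum_cliques(g) == brute_force_max_cliques(g)


def k8_minus_matching():
    g = nx.complete_graph(8)
    g = nx.relabel_nodes(g, {i: f"v{i}" for i in range(8)})
    for i in range(0, 8, 2):
        g.remove_edge(f"v{i}", f"v{i+1}")
    return g


class TestParaclique:
    def test_k5_minus_edge_absorbs_everything(self):
        g = nx.complete_graph(5)
        g = nx.relabel_nodes(g, {i: f"v{i}" for i in range(5)})
        g.remove_edge("v0", "v1")
        run = paraclique_cluster(g, ParacliqueParams(glom_factor=1))
        assert partition_of(run) == {frozenset(g.nodes)}

    @pytest.mark.parametrize("index", [0, 1])
    def test_two_disjoint_k4s(self, index):
        g = nx.disjoint_union(nx.complete_graph(4), nx.complete_graph(4))
        g = nx.relabel_nodes(g, {i: f"v{i}" for i in g.nodes})
        run = paraclique_cluster(
            g, ParacliqueParams(starting_clique_index=index, glom_factor=1)
        )
        assert partition_of(run) == {
            frozenset({"v0", "v1", "v2", "v3"}),
            frozenset({"v4", "v5", "v6", "v7"}),
        }

    def test_overlapping_cliques_yield_identical_clusters(self):
        g = k8_minus_matching()
        runs = [
            paraclique_cluster(g, ParacliqueParams(starting_clique_index=i))
            for i in range(len(maximum_cliques(g)))
        ]
        assert all(partition_of(r) == partition_of(runs[0]) for r in runs)

    def test_out_of_range_start_index_reports_count(self):
        g = nx.complete_graph(4)
        g = nx.relabel_nodes(g, {i: f"v{i}" for i in range(4)})
        with pytest.raises(ValueError, match="1 maximum clique"):
            paraclique_cluster(g, ParacliqueParams(starting_clique_index=5))

    def test_density_bound_on_random_graphs(self):
        """Every emitted paraclique of size s misses at most
        g * (s - seed_size) edges, the accretion budget."""
        rng = np.random.default_rng(41)
        for _ in range(20):
            n = int(rng.integers(6, 14))
            graph = nx.gnp_random_graph(
                n, 0.6, seed=int(rng.integers(1 << 30))
            )
            graph = nx.relabel_nodes(graph, {i: f"v{i:02d}" for i in graph.nodes})
            glom = int(rng.integers(1, 3))
            params = ParacliqueParams(glom_factor=glom, min_clique_size=3)
            cliques = maximum_cliques(graph)
            if not cliques or len(cliques[0]) < 3:
                continue
            seed_size = len(cliques[0])
            run = paraclique_cluster(graph, params)
            first = run.clusters[0]
            s = len(first)
            sub = graph.subgraph(first)
            max_missing = glom * (s - seed_size)
            assert s * (s - 1) // 2 - sub.number_of_edges() <= max_missing


# ---------------------------------------------------------------------------
# NNN


class TestNNN:
    def test_two_planted_modules(self):
        config = SyntheticConfig(
            n_modules=2, module_sizes=(10, 10), n_background=0,
            n_samples=40, seed=2,
        )
        expr, labels = generate_expression(config)
        run = nnn_cluster(correlation_matrix(expr), NNNParams(k=5))
        assert partition_of(run) == {
            frozenset(g for g in expr.gene_ids if labels[g] == "module1"),
            frozenset(g for g in expr.gene_ids if labels[g] == "module2"),
        }

    def test_split_at_articulation_vertex(self):
        """Two triangles sharing vertex c: the merged network splits at c,
        and c is kept in the first cluster only."""
        items = ["a", "b", "c", "d", "e"]
        sim = np.full((5, 5), 0.1)
        np.fill_diagonal(sim, 1.0)
        for x, y, w in [("a", "b", 0.9), ("a", "c", 0.8), ("b", "c", 0.8),
                        ("d", "e", 0.9), ("c", "d", 0.8), ("c", "e", 0.8)]:
            i, j = items.index(x), items.index(y)
            sim[i, j] = sim[j, i] = w
        run = nnn_cluster(sim, NNNParams(k=2), labels=items)
        assert partition_of(run) == {
            frozenset({"a", "b", "c"}),
            frozenset({"d", "e"}),
        }

    def test_no_clique_of_requested_size_gives_zero_clusters(self):
        """Six points on a ring: the 2-NN graph is a cycle, triangle-free."""
        angles = 2 * np.pi * np.arange(6) / 6
        pts = np.c_[np.cos(angles), np.sin(angles)]
        dist = np.sqrt(((pts[:, None] - pts[None]) ** 2).sum(-1))
        sim = -dist
        run = nnn_cluster(sim, NNNParams(k=2))
        assert run.clusters == ()

    def test_k_not_smaller_than_n_rejected(self):
        sim = np.eye(4)
        with pytest.raises(ValueError, match="smaller than"):
            nnn_cluster(sim, NNNParams(k=4))

    def test_cluster_size_cap_at_half(self):
        rng = np.random.default_rng(8)
        m = rng.uniform(0, 1, (14, 14))
        sim = (m + m.T) / 2
        np.fill_diagonal(sim, 1.0)
        run = nnn_cluster(sim, NNNParams(k=6))
        assert all(len(c) <= 7 for c in run.clusters)


# ---------------------------------------------------------------------------
# external runs


class TestIngestExternal:
    def test_valid_module_file(self, tmp_path):
        path = tmp_path / "wgcna.tsv"
        path.write_text("blue\tg1\nblue\tg2\nbrown\tg3\nbrown\tg4\n")
        run = ingest_external_run(path, "wgcna")
        assert partition_of(run) == {frozenset({"g1", "g2"}), frozenset({"g3", "g4"})}

    def test_grey_module_excluded(self, tmp_path):
        path = tmp_path / "wgcna.tsv"
        path.write_text("blue\tg1\nblue\tg2\ngrey\tg3\ngrey\tg4\n")
        run = ingest_external_run(path, "wgcna", exclude_labels=["grey"])
        assert partition_of(run) == {frozenset({"g1", "g2"})}

    def test_overlap_rejected_by_default(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text("1\tg1\n1\tg2\n2\tg2\n2\tg3\n")
        with pytest.raises(ValidationError):
            ingest_external_run(path, "click")

    def test_single_shared_element_kept_in_first_cluster(self, tmp_path):
        path = tmp_path / "nnn.tsv"
        path.write_text("1\tg1\n1\tg2\n2\tg2\n2\tg3\n2\tg4\n")
        run = ingest_external_run(path, "nnn", allow_shared=True)
        assert partition_of(run) == {frozenset({"g1", "g2"}), frozenset({"g3", "g4"})}
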