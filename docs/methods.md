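# Methods

## The robustness metric

Given one algorithm, one dataset, and *r* runs that differ only in the value
of a single setting, define for every unordered item pair *P* that shares a
cluster in at least one run the score `count(P) / r`, where `count(P)` is the
number of runs co-clustering *P*. Robustness is the mean score,
`R = t / (d·r)` with `t = Σ count(P)` and `d` the number of distinct
co-clustered pairs. Properties the implementation guarantees and the tests
assert:

- `R ∈ (0, 1]` whenever `d ≥ 1`; `R = 1` iff every co-clustered pair is
  co-clustered in all runs.
- `R` is invariant under relabeling of items and clusters and reordering of
  runs, and coarsening any single run never decreases `t` or any pair count.
- Co-clustering is boolean per run: clusters within a run are disjoint, so a
  pair can contribute at most 1 per run. For ingested NNN-style output, where
  two clusters may share one element, the shared item is assigned to the
  first cluster before counting, preserving the boolean convention.
- `d = 0` (no pair ever co-clustered, e.g. all-singleton runs) raises a
  dedicated "undefined robustness" error rather than returning 0 or NaN: the
  metric is a mean over co-clustered pairs and has no value on an empty set.

R is stored as an exact rational (`t`, `d`, `r` are kept; `fractions.Fraction`
does the arithmetic) and rendered to 3 decimals in reports, per-pair scores to
4. Cross-dataset summaries report the mean of R and the coefficient of
variation using the **sample** standard deviation (n−1); with a single dataset
the CV is reported as absent, not zero. Pair counting aggregates per-pair
hash keys, so memory scales with `d` rather than the square of the universe.

## Why hierarchical sweeps are structurally stable

All four linkages cut one fixed merge tree. Sweeping the cut count downward
only merges clusters, so the set of runs co-clustering a given pair is a
suffix of the run order, and

```
R = Σ_P (r − first_run(P) + 1) / (d·r)
```

The test suite asserts both the suffix property and this closed form with
exact rational arithmetic on random dissimilarity matrices. Paraclique's
stability has a different source: on correlation graphs the maximum cliques
overlap heavily, so varying the starting clique leaves the accreted
paraclique nearly unchanged (on a fixture whose maximum cliques all pairwise
overlap, K8 minus a perfect matching, the sweep yields identical clusters and
R = 1 exactly).

## Algorithms

- **Hierarchical** (average/UPGMA, complete, McQuitty/WPGMA, Ward):
  agglomeration and tree cutting are delegated to
  `scipy.cluster.hierarchy.linkage` / `cut_tree` on the condensed
  dissimilarity. `cut_tree` guarantees exactly k clusters and nested cuts.
  Ward follows scipy's convention for precomputed distances (the
  ward.D2-style update on the given dissimilarities); documented because R's
  two Ward variants differ.
- **k-means**: `sklearn.cluster.KMeans`, `n_init=10`, seeded — bit-reproducible
  per seed. Empty clusters cannot survive scikit-learn's implementation, but
  the contract documents that a run may carry fewer than k clusters.
- **QT clustering**: for each remaining seed item, grow a candidate by
  repeatedly adding the item minimizing the resulting diameter until the cap
  would be exceeded; extract the largest candidate; repeat. Ties: candidate
  size → lowest seed id; growth → lowest item id. Verified round-by-round
  against a brute-force maximum-feasible-subset oracle on 5-item instances
  (the oracle's full partition is ambiguous under ties, so the test compares
  per-round cluster sizes and the diameter bound, which pin the behavior).
- **SOM**: hand-written online SOM (no installed package provides one).
  Rectangular or hexagonal (offset) lattice; codebook initialized by sampling
  item profiles; 100 presentations per item in reshuffled epochs; learning
  rate 0.05 → 0.01 linear; Gaussian neighborhood radius from half the grid
  diagonal to 1, linear. One cluster per non-empty node. Seeded and
  bit-reproducible.
- **Maximum cliques**: Bron–Kerbosch maximal-clique enumeration via
  `networkx.find_cliques`, filtered to maximum cardinality and ordered
  lexicographically by sorted vertex ids; checked against subset enumeration
  on random graphs ≤ 12 vertices.
- **Paraclique**: seed with the selected maximum clique; repeatedly admit the
  lexicographically lowest vertex adjacent to at least `size − g` current
  members (g = glom factor, default 1), rescanning to fixpoint — so a
  paraclique of size s misses at most `g·(s − seed)` edges, an invariant the
  tests assert. Remove, re-seed from the residual graph's first maximum
  clique, stop when the residual maximum clique is below `min_clique_size`
  (default 3 at test scale; 5 is the conventional floor for genome-scale
  graphs) or an optional paraclique cap is reached. Residue stays
  unclustered.
- **NNN**: connect each vertex to its k most similar others (union
  symmetrization, ties by id); enumerate cliques of exactly `clique_size`
  (default 3); merge overlapping cliques into preliminary networks; split at
  articulation points via biconnected decomposition, an articulation vertex
  staying with the first cluster so the partition remains disjoint; cap
  cluster size at half the items. Items are whole, so the admissible cap is
  `ceil(n/2)` — the strict `n/2` would force a second split in the canonical
  two-triangles-sharing-a-vertex case, contradicting the articulation rule.
  Oversize clusters are split by deleting weakest-similarity edges (ties by
  id) until the subgraph disconnects; this rule is this package's choice —
  the original description does not specify one.

### Measures and standardization

Correlation-driven methods use Pearson-based measures: dissimilarity
`1 − r` for hierarchical and QT, similarity `r` for NNN, and hard-thresholded
correlation graphs for paraclique. k-means and SOM are centroid methods in
Euclidean space; their profiles are z-scored per gene by default, because raw
log2 baselines (a per-gene offset) otherwise dominate Euclidean distance and
hide the correlation structure entirely — after z-scoring, squared Euclidean
distance is proportional to `1 − r`, keeping all methods on one similarity
footing. `standardize=False` and `metric="euclidean"` expose the raw
geometry where wanted.

## Co-expression graphs

Edges are weighted by Pearson correlation and kept iff weight ≥ τ (signed
comparison, matching the retention rule's wording; `absolute=True` gives
|weight| ≥ τ). Isolated vertices are retained — they can never join a
paraclique of size ≥ 2, consistent with the metric ignoring
never-co-clustered items. `suggest_threshold` is an explicitly heuristic
stand-in for spectral threshold selection: it computes the largest adjacency
eigenvalue of the thresholded graph over a candidate grid and proposes the
candidate at the steepest relative drop (the point where the dominant dense
subgraph disintegrates). It is advisory, deterministic, and every pipeline
accepts a user-supplied τ, which is the supported way to reproduce published
per-dataset thresholds.

## Synthetic data

A gene in module m is `√ρ·z_m + √(1−ρ)·ε` with `z_m` a module-shared latent
sample profile and `ε` independent noise, all unit variance — the expected
intra-module Pearson correlation is exactly ρ (`intra_module_corr`), so the
generator is calibrated in closed form rather than by tuning. Background
genes share one weak global latent with loading `√background_corr`
(independent at 0). Each gene is then scaled by `noise_sd` (default 1) and
shifted by a baseline drawn around 8, emulating log2 microarray intensities;
neither affects correlations. Defaults: 3 modules × 20 genes, 50 background
genes, 40 samples, ρ = 0.9 vs background 0.1 — well-separated module
structure at desk scale. Generation is O(genes × samples), deterministic per
seed, and labels are emitted separately and consumed only by tests.

What the generator does **not** emulate: platform artifacts, batch effects,
missingness, heavy-tailed noise, overlapping modules, correlation between
modules. Passing tests therefore demonstrate the metric's and algorithms'
behavior on idealized module structure, not performance on real microarray
data.

## Sweep harness and problem sizes

`run_sweep` holds everything fixed (including the seed) except the one swept
setting; hierarchical sweeps agglomerate once and cut the same tree at each
value. Failures on one dataset (incompatible setting, undefined robustness)
become missing cells in the report, and summaries are computed over the
remaining cells. Conventional sweep ranges ship as defaults (cluster counts
200–300 in steps of 10, giving r = 11, with a scale factor for small inputs;
QT diameters 0.05–0.5 step 0.05; NNN k 16–25; five SOM grids × two
topologies; paraclique over maximum cliques). "Clusters of the same scale"
across algorithms is reported as a diagnostic (mean cluster size), not
enforced — no enforcement rule is defensible in general.

The test and acceptance workloads run at desk scale — tens of genes, ≤ 40
samples, 30-item dissimilarity matrices, graphs ≤ 14 vertices — chosen so the
whole suite completes in seconds while still exercising every code path and
every structural property (the suffix law, oracle equivalence, clique
overlap) exactly.

## Numerical choices

- Correlations are clipped to [−1, 1] and the diagonal forced to 1; constant
  genes are rejected by name (undefined Pearson), and loaders flag them.
- Dissimilarity matrices must be symmetric (1e−10 tolerance) with zero
  diagonal.
- All deterministic tie-breaks are lexicographic by item id; stochastic
  algorithms consume a single integer seed through `numpy` Generators or
  scikit-learn's `random_state`.
- Membership files are UTF-8 TSV; cluster ids are file-scoped, so round-trips
  preserve pair structure (which is all the metric consumes), not label
  spelling.

## Known limitations

- WGCNA and CLICK are not reimplemented; their output is ingested from
  membership files only.
- The spectral threshold heuristic is not claimed to reproduce any published
  per-dataset threshold table.
- NNN's oversize-split rule and the articulation-vertex assignment are
  documented package choices where the original descriptions are silent;
  alternative choices would change cluster boundaries but not the metric's
  contracts.
- Absolute robustness values on real genome-scale data are outside the test
  envelope; the suite validates mechanisms and orderings, not the published
  magnitudes.
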