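"""Shared fixtures: the six-item worked example and small random generators."""

from __future__ import annotations

from fractions import Fraction
from itertools import combinations

import numpy as np
import pytest

from robustclust import ClusterRun, RunCollection


def make_run(run_id: str, *clusters: str) -> ClusterRun:
    """Build a run from strings of single-character item ids, e.g. 'ABCD'."""
    return ClusterRun(
        run_id=run_id,
        setting_value=run_id,
        clusters=tuple(frozenset(c) for c in clusters),
    )


@pytest.fixture
def fig_runs() -> RunCollection:
    """Three clusterings of {A..F} realizing the canonical pair scores:

    (A,B)=3/3, (C,D)=(E,F)=2/3, and 1/3 for (A,C),(A,D),(B,C),(B,D),(C,E),
    (D,F); t=13, d=9, R=13/27.
    """
    return RunCollection(
        algorithm="demo",
        dataset="toy",
        runs=(
            make_run("run1", "ABCD", "EF"),
            make_run("run2", "AB", "CD", "EF"),
            make_run("run3", "AB", "CE", "DF"),
        ),
    )


def random_collection(rng: np.random.Generator, max_items: int = 10,
                      max_runs: int = 5) -> RunCollection:
    """A random collection of flat partitions over a shared small universe."""
    n = int(rng.integers(2, max_items + 1))
    r = int(rng.integers(1, max_runs + 1))
    items = [f"i{j}" for j in range(n)]
    runs = []
    for ri in range(r):
        n_clusters = int(rng.integers(1, n + 1))
        assignment = rng.integers(0, n_clusters, size=n)
        clusters: dict[int, set[str]] = {}
        # some runs leave items unclustered, as paraclique does
        keep = rng.random(n) > 0.1
        for item, lab, k in zip(items, assignment, keep):
            if k:
                clusters.setdefault(int(lab), set()).add(item)
        if not clusters:
            clusters[0] = {items[0]}
        runs.append(
            ClusterRun(f"r{ri}", f"v={ri}",
                       tuple(frozenset(c) for c in clusters.values()))
        )
    return RunCollection("rand", "rand", tuple(runs))


def brute_force_robustness(runs: RunCollection) -> Fraction | None:
    """Independent oracle: enumerate all C(n,2) pairs, scan every run,
    average the scores of pairs seen together at least once."""
    items = sorted(runs.universe)
    scores = []
    for a, b in combinations(items, 2):
        count = 0
        for run in runs.runs:
            for cluster in run.clusters:
                if a in cluster and b in cluster:
                    count += 1
                    break
        if count:
            scores.append(Fraction(count, runs.r))
    if not scores:
        return None
    return sum(scores) / len(scores)
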