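"""Pair-based robustness metric for collections of clustering runs.

A clustering algorithm is run *r* times on one dataset, varying a single
setting (number of clusters, threshold, starting clique, ...).  For every
unordered pair of items that is co-clustered in at least one run, the pair's
score is the fraction of runs in which its members share a cluster.  The
robustness of the algorithm on that dataset is the mean of those scores,

    R = t / (d * r)

where *t* is the total number of (not necessarily distinct) co-clustered
pairs summed over all runs, and *d* is the number of distinct pairs that are
co-clustered in at least one run.  R lies in (0, 1]; pairs that are never
co-clustered do not enter the average.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from fractions import Fraction
from itertools import combinations
from statistics import mean, stdev
from typing import Iterator, Mapping

__all__ = [
    "Pair",
    "ValidationError",
    "UndefinedRobustnessError",
    "ClusterRun",
    "RunCollection",
    "PairTable",
    "RobustnessResult",
    "RobustnessSummary",
    "make_pair",
    "count_pairs",
    "robustness",
    "pair_score",
    "summarize",
]

#: An unordered item pair, stored in sorted order.
Pair = tuple[str, str]


class ValidationError(ValueError):
    """Raised when a clustering violates the non-overlap contract."""


class UndefinedRobustnessError(ValueError):
    """Raised when no pair is ever co-clustered (d = 0), so R is undefined.

    An all-singleton collection is degenerate input, not R = 0: the metric
    is the mean over co-clustered pairs and the mean of an empty set has no
    value.
    """


def make_pair(a: str, b: str) -> Pair:
    """Canonical (sorted) form of an unordered item pair."""
    if a == b:
        raise ValueError(f"a pair needs two distinct items, got {a!r} twice")
    return (a, b) if a < b else (b, a)


@dataclass(frozen=True)
class ClusterRun:
    """One flat, non-overlapping clustering of an item universe.

    Parameters
    ----------
    run_id:
        Label for the run, unique within its collection.
    setting_value:
        The value of the varied setting that produced this run, e.g.
        ``"k=250"`` or ``"clique=3"``.
    clusters:
        Disjoint, non-empty sets of item identifiers.  Singletons are
        allowed; they contribute no pairs.
    """

    run_id: str
    setting_value: str
    clusters: tuple[frozenset[str], ...]

    def __post_init__(self) -> None:
        clusters = tuple(frozenset(c) for c in self.clusters)
        object.__setattr__(self, "clusters", clusters)
        seen: set[str] = set()
        for cluster in clusters:
            if not cluster:
                raise ValidationError(f"run {self.run_id!r}: empty cluster")
            for item in cluster:
                if item in seen:
                    raise ValidationError(
                        f"run {self.run_id!r}: item {item!r} appears in more "
                        "than one cluster"
                    )
            seen.update(cluster)

    @property
    def items(self) -> frozenset[str]:
        """All items assigned to some cluster in this run."""
        out: set[str] = set()
        for cluster in self.clusters:
            out.update(cluster)
        return frozenset(out)

    def pairs(self) -> Iterator[Pair]:
        """Yield every co-clustered pair of this run, each exactly once.

        Clusters are disjoint, so no pair can arise from two clusters and
        co-clustering is inherently boolean per run.
        """
        for cluster in self.clusters:
            for a, b in combinations(sorted(cluster), 2):
                yield (a, b)

    def contains_pair(self, pair: Pair) -> bool:
        a, b = pair
        return any(a in cluster and b in cluster for cluster in self.clusters)


@dataclass(frozen=True)
class RunCollection:
    """The *r* runs of one algorithm on one dataset.

    Runs are ordered (the sweep order of the varied setting) and drawn from
    a shared item universe, though a run need not cluster every item —
    paraclique, for instance, leaves residual vertices unclustered.
    """

    algorithm: str
    dataset: str
    runs: tuple[ClusterRun, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "runs", tuple(self.runs))
        if len(self.runs) < 1:
            raise ValidationError("a run collection needs at least one run")

    @property
    def r(self) -> int:
        return len(self.runs)

    @property
    def universe(self) -> frozenset[str]:
        """Union of all items appearing in any run."""
        out: set[str] = set()
        for run in self.runs:
            out.update(run.items)
        return frozenset(out)


@dataclass(frozen=True)
class PairTable:
    """Co-occurrence counts for every pair co-clustered in >= 1 run.

    ``counts`` maps each distinct co-clustered pair to the number of runs in
    which it is co-clustered (1..r).  Pairs never co-clustered are absent.
    """

    counts: Mapping[Pair, int]
    r: int

    @property
    def t(self) -> int:
        """Total co-clustered pairs summed over runs."""
        return sum(self.counts.values())

    @property
    def d(self) -> int:
        """Number of distinct co-clustered pairs."""
        return len(self.counts)


@dataclass(frozen=True)
class RobustnessResult:
    """R together with its exact decomposition.

    ``R`` is kept as an exact rational t/(d*r); ``value`` rounds it to a
    float.  ``pair_scores`` holds count(P)/r for every pair entering the
    average.
    """

    t: int
    d: int
    r: int
    pair_scores: Mapping[Pair, Fraction]

    @property
    def R(self) -> Fraction:
        return Fraction(self.t, self.d * self.r)

    @property
    def value(self) -> float:
        return float(self.R)

    def rounded(self, ndigits: int = 3) -> float:
        """R rendered to ``ndigits`` decimal places (reporting convention)."""
        return round(float(self.R), ndigits)


@dataclass(frozen=True)
class RobustnessSummary:
    """Cross-dataset summary of one algorithm's robustness.

    ``cv`` is the coefficient of variation, sample standard deviation over
    mean, of the per-dataset R values; it is ``None`` (undefined, not zero)
    when fewer than two datasets are present.
    """

    per_dataset: Mapping[str, float]
    mean_R: float
    cv: float | None
    sd_convention: str = field(default="sample (n-1)", compare=False)


def count_pairs(runs: RunCollection) -> PairTable:
    """Count, for every pair, the number of runs in which it is co-clustered.

    Co-clustering is boolean per run: a pair contributes at most 1 to its
    count for each run.  Pairs never co-clustered are omitted, so memory
    scales with the number of distinct co-clustered pairs, not with the
    square of the universe size.
    """
    counts: Counter[Pair] = Counter()
    for run in runs.runs:
        counts.update(run.pairs())
    return PairTable(counts=dict(counts), r=runs.r)


def robustness(runs: RunCollection) -> RobustnessResult:
    """Compute R = t/(d*r) for one algorithm on one dataset.

    Raises
    ------
    UndefinedRobustnessError
        If no pair is ever co-clustered (d = 0), e.g. all-singleton runs.
    """
    table = count_pairs(runs)
    if table.d == 0:
        raise UndefinedRobustnessError(
            f"robustness undefined for {runs.algorithm!r} on "
            f"{runs.dataset!r}: no pair of items is co-clustered in any of "
            f"the {runs.r} runs"
        )
    scores = {pair: Fraction(c, runs.r) for pair, c in table.counts.items()}
    return RobustnessResult(t=table.t, d=table.d, r=runs.r, pair_scores=scores)


def pair_score(pair: Pair, runs: RunCollection) -> Fraction:
    """The fraction of runs in which ``pair``'s members share a cluster.

    Returns 0 for pairs that are never co-clustered; such pairs do not
    enter R.  Items must belong to the collection's universe.
    """
    pair = make_pair(*pair)
    universe = runs.universe
    for item in pair:
        if item not in universe:
            raise KeyError(f"item {item!r} not in the run collection's universe")
    n = sum(1 for run in runs.runs if run.contains_pair(pair))
    return Fraction(n, runs.r)


def summarize(
    results: Mapping[str, "RobustnessResult | float"],
) -> RobustnessSummary:
    """Mean and coefficient of variation of per-dataset R values.

    Accepts RobustnessResult objects or plain R floats.  With a single
    dataset the CV is undefined and reported as ``None``.
    """
    if not results:
        raise ValueError("summarize needs at least one dataset")
    per_dataset = {
        name: (res.value if isinstance(res, RobustnessResult) else float(res))
        for name, res in results.items()
    }
    values = list(per_dataset.values())
    mean_r = mean(values)
    if len(values) < 2:
        cv = None
    elif mean_r == 0:
        raise ValueError("CV undefined: mean robustness is zero")
    else:
        cv = stdev(values) / mean_r
    return RobustnessSummary(per_dataset=per_dataset, mean_R=mean_r, cv=cv)
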