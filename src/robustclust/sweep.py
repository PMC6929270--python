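"""Parameter-sweep harness: one run per setting value, robustness per sweep.

A SweepSpec names an algorithm, the single setting being varied, and the
ordered list of values; everything else (including the seed) is held fixed,
so the swept setting is the only varying factor.  ``run_sweep`` produces the
RunCollection over which robustness is computed, and ``robustness_report``
assembles the algorithm x dataset table with per-algorithm mean and CV.
Sweeps that fail on a dataset become missing cells, not fatal errors.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Any, Mapping

import numpy as np
import pandas as pd

from . import algorithms as alg
from .graph import CorrelationGraph
from .io import ExpressionMatrix
from .robustness import (
    RobustnessResult,
    RobustnessSummary,
    RunCollection,
    UndefinedRobustnessError,
    robustness,
    summarize,
)

__all__ = ["SweepSpec", "run_sweep", "robustness_report", "default_sweep_values"]

logger = logging.getLogger(__name__)

_HIERARCHICAL = set(alg.LINKAGES)


@dataclass(frozen=True)
class SweepSpec:
    """One algorithm's sweep: the varied setting and its ordered values.

    ``algorithm`` is one of average/complete/mcquitty/ward (hierarchical
    linkages), kmeans, qt, som, paraclique, nnn, or external.  Each entry of
    ``values`` yields one run (r = len(values)).  ``fixed_params`` carries
    everything held constant, e.g. ``{"glom_factor": 1}`` for paraclique or
    ``{"files": [...], "name": "wgcna"}`` for external runs.
    """

    algorithm: str
    setting_name: str
    values: tuple[Any, ...]
    fixed_params: Mapping[str, Any] = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "values", tuple(self.values))
        if not self.values:
            raise ValueError("a sweep needs at least one setting value")

    @property
    def r(self) -> int:
        return len(self.values)


def default_sweep_values(algorithm: str, scale: float = 1.0) -> list[Any]:
    """Commonly used sweep ranges for each algorithm.

    Cluster-count sweeps span 200-300 in steps of 10 (r = 11), QT diameters
    0.05-0.5 in steps of 0.05, NNN neighborhood sizes 16-25.  ``scale``
    shrinks the cluster-count range proportionally for small inputs.
    """
    if algorithm in _HIERARCHICAL or algorithm == "kmeans":
        return [max(2, round(k * scale)) for k in range(200, 301, 10)]
    if algorithm == "qt":
        return [round(0.05 * i, 2) for i in range(1, 11)]
    if algorithm == "nnn":
        return list(range(16, 26))
    if algorithm == "som":
        return ["14x15:rectangular", "14x16:rectangular", "15x16:rectangular",
                "14x15:hexagonal", "15x16:hexagonal"]
    if algorithm == "paraclique":
        return list(range(9))
    raise ValueError(f"no default sweep for algorithm {algorithm!r}")


def _parse_grid(value: Any) -> tuple[int, int, str]:
    if isinstance(value, (tuple, list)):
        rows, cols, topo = value
        return int(rows), int(cols), str(topo)
    text = str(value)
    grid, _, topo = text.partition(":")
    rows, _, cols = grid.partition("x")
    return int(rows), int(cols), topo or "rectangular"


def run_sweep(
    spec: SweepSpec,
    data: ExpressionMatrix | CorrelationGraph | pd.DataFrame,
    dataset: str = "",
) -> RunCollection:
    """Execute one sweep: one ClusterRun per setting value, in order.

    ``data`` is an ExpressionMatrix for hierarchical/kmeans/qt/som/nnn, a
    CorrelationGraph for paraclique, or a precomputed square DataFrame
    (dissimilarity for hierarchical/qt, similarity for nnn).  Hierarchical
    sweeps agglomerate once and cut the same tree at every value.  Errors
    name the offending value.
    """
    name = spec.algorithm
    params = dict(spec.fixed_params)
    runs = []

    def fail(value: Any, exc: Exception) -> Exception:
        return type(exc)(f"{name} sweep failed at {spec.setting_name}={value}: {exc}")

    if name in _HIERARCHICAL:
        dissim = _dissimilarity(data, params)
        dendro = alg.build_dendrogram(dissim, name)
        for value in spec.values:
            try:
                run = alg.cut_dendrogram(dendro, int(value))
            except ValueError as exc:
                raise fail(value, exc) from exc
            runs.append(_tag(run, spec, value))
    elif name == "kmeans":
        expr = _expression(data)
        for value in spec.values:
            try:
                run = alg.kmeans_cluster(expr, int(value), seed=spec.seed)
            except ValueError as exc:
                raise fail(value, exc) from exc
            runs.append(_tag(run, spec, value))
    elif name == "qt":
        dissim = _dissimilarity(data, params)
        for value in spec.values:
            runs.append(_tag(alg.qt_cluster(dissim, float(value)), spec, value))
    elif name == "som":
        expr = _expression(data)
        for value in spec.values:
            rows_, cols_, topo = _parse_grid(value)
            try:
                run = alg.som_cluster(expr, rows_, cols_, topo, seed=spec.seed)
            except ValueError as exc:
                raise fail(value, exc) from exc
            runs.append(_tag(run, spec, value))
    elif name == "paraclique":
        if not isinstance(data, CorrelationGraph):
            raise TypeError("paraclique sweeps need a CorrelationGraph")
        for value in spec.values:
            p = alg.ParacliqueParams(
                starting_clique_index=int(value),
                glom_factor=int(params.get("glom_factor", 1)),
                min_clique_size=int(params.get("min_clique_size", 3)),
                max_paracliques=params.get("max_paracliques"),
            )
            try:
                run = alg.paraclique_cluster(data, p)
            except ValueError as exc:
                raise fail(value, exc) from exc
            runs.append(_tag(run, spec, value))
    elif name == "nnn":
        sim = _similarity(data)
        for value in spec.values:
            p = alg.NNNParams(
                k=int(value), clique_size=int(params.get("clique_size", 3))
            )
            try:
                run = alg.nnn_cluster(sim, p)
            except ValueError as exc:
                raise fail(value, exc) from exc
            runs.append(_tag(run, spec, value))
    elif name == "external":
        files = params.get("files")
        if not files:
            raise ValueError(
                "external sweeps need fixed_params['files'], one membership "
                "file per setting value"
            )
        if len(files) != len(spec.values):
            raise ValueError("external sweep: len(files) != len(values)")
        for value, path in zip(spec.values, files):
            run = alg.ingest_external_run(
                path,
                algorithm=params.get("name", "external"),
                exclude_labels=params.get("exclude_labels", ()),
                allow_shared=bool(params.get("allow_shared", False)),
            )
            runs.append(_tag(run, spec, value))
    else:
        raise ValueError(f"unknown algorithm {name!r}")

    return RunCollection(algorithm=name, dataset=dataset, runs=tuple(runs))


def _tag(run, spec: SweepSpec, value: Any):
    from dataclasses import replace

    return replace(
        run,
        run_id=f"{spec.algorithm}-{spec.setting_name}-{value}",
        setting_value=f"{spec.setting_name}={value}",
    )


def _expression(data) -> ExpressionMatrix:
    if isinstance(data, ExpressionMatrix):
        return data
    raise TypeError("this algorithm needs an ExpressionMatrix")


def _labeled(matrix) -> pd.DataFrame:
    values = np.asarray(matrix, dtype=float)
    labels = [f"g{i}" for i in range(values.shape[0])]
    return pd.DataFrame(values, index=labels, columns=labels)


def _dissimilarity(data, params) -> pd.DataFrame:
    if isinstance(data, pd.DataFrame):
        return data
    if isinstance(data, ExpressionMatrix):
        return alg.expression_dissimilarity(
            data, metric=params.get("metric", "correlation")
        )
    try:
        return _labeled(data)
    except (TypeError, ValueError):
        raise TypeError(
            "need an ExpressionMatrix or a square dissimilarity matrix"
        ) from None


def _similarity(data) -> pd.DataFrame:
    if isinstance(data, pd.DataFrame):
        return data
    if isinstance(data, ExpressionMatrix):
        from .graph import correlation_matrix

        return correlation_matrix(data)
    try:
        return _labeled(data)
    except (TypeError, ValueError):
        raise TypeError(
            "need an ExpressionMatrix or a square similarity matrix"
        ) from None


def robustness_report(
    specs: list[SweepSpec],
    datasets: Mapping[str, ExpressionMatrix | CorrelationGraph | pd.DataFrame],
) -> tuple[pd.DataFrame, dict[str, RobustnessSummary], list[tuple[str, str, str]]]:
    """Robustness of every algorithm on every dataset.

    Returns the algorithm x dataset table of R values (NaN for failures),
    a per-algorithm RobustnessSummary over its successful datasets, and the
    list of failures as (algorithm, dataset, reason).  A sweep that raises
    (non-termination analogues, undefined robustness, incompatible
    settings) yields a missing cell, not a fatal error.
    """
    table: dict[str, dict[str, float]] = {}
    results: dict[str, dict[str, RobustnessResult]] = {}
    failures: list[tuple[str, str, str]] = []
    for spec in specs:
        for ds_name, data in datasets.items():
            try:
                runs = run_sweep(spec, data, dataset=ds_name)
                res = robustness(runs)
            except (ValueError, TypeError, UndefinedRobustnessError) as exc:
                logger.warning("%s on %s failed: %s", spec.algorithm, ds_name, exc)
                failures.append((spec.algorithm, ds_name, str(exc)))
                continue
            table.setdefault(spec.algorithm, {})[ds_name] = res.value
            results.setdefault(spec.algorithm, {})[ds_name] = res
    frame = pd.DataFrame(table).T.reindex(
        index=[s.algorithm for s in specs], columns=list(datasets)
    )
    summaries = {
        algo: summarize(per_ds) for algo, per_ds in results.items() if per_ds
    }
    return frame, summaries, failures
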