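"""File formats: cluster-membership TSVs, run manifests, expression matrices.

Membership files carry two tab-separated columns, ``cluster_id`` and
``item_id``; ``#``-prefixed lines are comments.  A run collection is a
directory of membership files plus a manifest TSV with columns ``run_id``,
``setting_value`` and ``filename`` (relative to the manifest's directory).

Expression matrices are TSVs with a header row of sample identifiers and a
first column of gene identifiers, values on the log2 scale.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .robustness import ClusterRun, RobustnessResult, RunCollection, ValidationError

__all__ = [
    "ExpressionMatrix",
    "read_membership",
    "write_run",
    "read_run_collection",
    "write_run_collection",
    "read_expression",
    "write_expression",
    "write_robustness_report",
    "write_pair_scores",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ExpressionMatrix:
    """A genes x samples matrix of log2 expression values.

    Gene and sample identifiers are unique; rows containing missing values
    are dropped at load time (and logged) rather than imputed.  Genes whose
    row is constant are kept but flagged in ``constant_genes``: their Pearson
    correlation with anything is undefined and correlation-based steps
    reject them.
    """

    gene_ids: tuple[str, ...]
    sample_ids: tuple[str, ...]
    values: np.ndarray
    constant_genes: tuple[str, ...] = field(default=())

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "gene_ids", tuple(self.gene_ids))
        object.__setattr__(self, "sample_ids", tuple(self.sample_ids))
        if values.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise ValueError(
                f"values shape {values.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.sample_ids)} samples"
            )
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ValueError("duplicate gene identifiers")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValueError("duplicate sample identifiers")

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=list(self.gene_ids), columns=list(self.sample_ids)
        )

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "ExpressionMatrix":
        values = frame.to_numpy(dtype=float)
        constant = tuple(
            gene
            for gene, row in zip(frame.index, values)
            if np.ptp(row) == 0.0
        )
        return cls(
            gene_ids=tuple(str(g) for g in frame.index),
            sample_ids=tuple(str(s) for s in frame.columns),
            values=values,
            constant_genes=constant,
        )

    def drop_constant(self) -> "ExpressionMatrix":
        """Return a copy without constant-valued genes."""
        if not self.constant_genes:
            return self
        keep = [g not in set(self.constant_genes) for g in self.gene_ids]
        return ExpressionMatrix(
            gene_ids=tuple(g for g, k in zip(self.gene_ids, keep) if k),
            sample_ids=self.sample_ids,
            values=self.values[np.array(keep)],
        )


def read_membership(
    path: str | Path,
    run_id: str | None = None,
    setting_value: str = "",
) -> ClusterRun:
    """Read one membership TSV into a ClusterRun.

    Overlap (an item listed under two cluster ids) is rejected with an error
    naming the run and the item.
    """
    path = Path(path)
    run_id = run_id if run_id is not None else path.stem
    clusters: dict[str, list[str]] = {}
    any_line = False
    with path.open(encoding="utf-8") as handle:
        for lineno, raw in enumerate(handle, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise ValidationError(
                    f"{path}:{lineno}: expected 'cluster_id<TAB>item_id', "
                    f"got {line!r}"
                )
            cluster_id, item_id = parts
            clusters.setdefault(cluster_id, []).append(item_id)
            any_line = True
    if not any_line:
        raise ValidationError(f"empty membership file for run {run_id!r}: {path}")
    return ClusterRun(
        run_id=run_id,
        setting_value=setting_value,
        clusters=tuple(frozenset(members) for members in clusters.values()),
    )


def write_run(run: ClusterRun, path: str | Path) -> Path:
    """Write a ClusterRun as a membership TSV; returns the path written.

    Cluster ids are generated as c1, c2, ... — they are file-scoped labels,
    so round-tripping preserves pair structure, not the original ids.  Item
    ids containing tabs or newlines cannot be represented and are rejected.
    """
    path = Path(path)
    lines = [f"# run_id={run.run_id}\tsetting={run.setting_value}"]
    for i, cluster in enumerate(run.clusters, start=1):
        for item in sorted(cluster):
            if "\t" in item or "\n" in item:
                raise ValueError(
                    f"item id {item!r} contains a tab or newline and cannot "
                    "be written in the membership TSV dialect"
                )
            lines.append(f"c{i}\t{item}")
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")
    return path


def read_run_collection(
    manifest_path: str | Path,
    algorithm: str = "",
    dataset: str = "",
) -> RunCollection:
    """Read a manifest TSV and all referenced membership files.

    The manifest has columns ``run_id``, ``setting_value``, ``filename``;
    filenames are resolved relative to the manifest's directory.  Runs keep
    manifest order.
    """
    manifest_path = Path(manifest_path)
    base = manifest_path.parent
    runs: list[ClusterRun] = []
    with manifest_path.open(encoding="utf-8") as handle:
        for lineno, raw in enumerate(handle, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 3:
                raise ValidationError(
                    f"{manifest_path}:{lineno}: expected "
                    f"'run_id<TAB>setting_value<TAB>filename', got {line!r}"
                )
            run_id, setting_value, filename = parts
            member_path = base / filename
            if not member_path.exists():
                raise FileNotFoundError(
                    f"{manifest_path}:{lineno}: membership file not found: "
                    f"{member_path}"
                )
            runs.append(read_membership(member_path, run_id, setting_value))
    if not runs:
        raise ValidationError(f"manifest lists no runs: {manifest_path}")
    return RunCollection(algorithm=algorithm, dataset=dataset, runs=tuple(runs))


def write_run_collection(runs: RunCollection, directory: str | Path) -> Path:
    """Write every run plus a manifest into ``directory``; returns manifest path."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    manifest_lines = []
    for i, run in enumerate(runs.runs):
        filename = f"run_{i:03d}.tsv"
        write_run(run, directory / filename)
        manifest_lines.append(f"{run.run_id}\t{run.setting_value}\t{filename}")
    manifest = directory / "manifest.tsv"
    manifest.write_text("\n".join(manifest_lines) + "\n", encoding="utf-8")
    return manifest


def read_expression(path: str | Path) -> ExpressionMatrix:
    """Load an expression TSV (genes x samples, log2 values).

    Duplicate gene identifiers and non-numeric cells are errors; rows with
    missing values are dropped and logged; constant genes are loaded but
    flagged (their Pearson correlation is undefined downstream).
    """
    path = Path(path)
    frame = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    if frame.index.has_duplicates:
        dupes = frame.index[frame.index.duplicated()].unique().tolist()
        raise ValidationError(f"{path}: duplicate gene identifier(s): {dupes}")
    if frame.columns.has_duplicates:
        dupes = frame.columns[frame.columns.duplicated()].unique().tolist()
        raise ValidationError(f"{path}: duplicate sample identifier(s): {dupes}")
    numeric = frame.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna() & frame.notna()
    if bad.any().any():
        gene = bad.any(axis=1).idxmax()
        col = bad.loc[gene].idxmax()
        raise ValidationError(
            f"{path}: non-numeric value {frame.loc[gene, col]!r} at gene "
            f"{gene!r}, sample {col!r}"
        )
    missing = numeric.isna().any(axis=1)
    if missing.any():
        dropped = numeric.index[missing].tolist()
        logger.warning(
            "%s: dropping %d gene(s) with missing values: %s",
            path,
            len(dropped),
            dropped[:10],
        )
        numeric = numeric.loc[~missing]
    return ExpressionMatrix.from_frame(numeric)


def write_expression(expr: ExpressionMatrix, path: str | Path) -> Path:
    path = Path(path)
    expr.to_frame().to_csv(path, sep="\t", index_label="gene")
    return path


def write_robustness_report(
    rows: list[tuple[str, str, RobustnessResult]],
    path: str | Path,
    ndigits: int = 3,
) -> Path:
    """Write the report TSV: algorithm, dataset, r, t, d, R."""
    path = Path(path)
    lines = ["algorithm\tdataset\tr\tt\td\tR"]
    for algorithm, dataset, res in rows:
        lines.append(
            f"{algorithm}\t{dataset}\t{res.r}\t{res.t}\t{res.d}\t"
            f"{res.rounded(ndigits):.{ndigits}f}"
        )
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")
    return path


def write_pair_scores(
    result: RobustnessResult, path: str | Path, ndigits: int = 4
) -> Path:
    """Write the per-pair TSV: item_a, item_b, count, score."""
    path = Path(path)
    lines = ["item_a\titem_b\tcount\tscore"]
    for (a, b), score in sorted(result.pair_scores.items()):
        count = int(score * result.r)
        lines.append(f"{a}\t{b}\t{count}\t{float(score):.{ndigits}f}")
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")
    return path
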