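"""Module-structured synthetic log2 expression data with known ground truth.

Each planted module is driven by a shared latent sample profile: a gene in
module m is sqrt(rho) * z_m + sqrt(1 - rho) * eps, with z_m and eps standard
normal over samples, so the expected Pearson correlation between two genes
of the same module is exactly rho (= ``intra_module_corr``).  Background
genes share a single weak global latent with loading
sqrt(``background_corr``) (independent when it is 0).  Each gene is then
shifted by a baseline drawn around 8 and scaled by ``noise_sd``, emulating
log2 microarray intensities; neither affects correlations.

Ground-truth labels are returned alongside (and can be written to a side
TSV); no clustering algorithm ever consumes them — only tests do.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .graph import CorrelationGraph, correlation_matrix, threshold_graph
from .io import ExpressionMatrix

__all__ = ["SyntheticConfig", "generate_expression", "generate_graph", "write_labels"]


@dataclass(frozen=True)
class SyntheticConfig:
    """Parameters of the planted-module generator.

    Defaults describe a desk-scale co-expression matrix: three modules of 20
    genes over 40 samples, intra-module correlation 0.9 against a 0.1
    background — well separated, as the tests require
    (``intra_module_corr > background_corr`` is enforced).
    """

    n_modules: int = 3
    module_sizes: tuple[int, ...] | None = None
    n_background: int = 50
    n_samples: int = 40
    intra_module_corr: float = 0.9
    background_corr: float = 0.1
    noise_sd: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        sizes = self.module_sizes
        if sizes is None:
            sizes = (20,) * self.n_modules
        sizes = tuple(int(s) for s in sizes)
        object.__setattr__(self, "module_sizes", sizes)
        if len(sizes) != self.n_modules:
            raise ValueError(
                f"module_sizes has {len(sizes)} entries for {self.n_modules} modules"
            )
        if any(s < 2 for s in sizes):
            raise ValueError("each module needs >= 2 genes")
        if not 0.0 < self.intra_module_corr < 1.0:
            raise ValueError("intra_module_corr must lie in (0, 1)")
        if not 0.0 <= self.background_corr < 1.0:
            raise ValueError("background_corr must lie in [0, 1)")
        if self.intra_module_corr <= self.background_corr:
            raise ValueError(
                "intra_module_corr must exceed background_corr (separability)"
            )
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        if self.n_samples < 3:
            raise ValueError("need >= 3 samples")
        if self.n_background < 0:
            raise ValueError("n_background must be >= 0")

    @property
    def n_genes(self) -> int:
        return sum(self.module_sizes) + self.n_background


def generate_expression(
    config: SyntheticConfig,
) -> tuple[ExpressionMatrix, dict[str, str]]:
    """Generate an expression matrix plus gene -> module labels.

    Module genes are named ``m<i>_g<j>``, background genes ``bg_g<j>``;
    labels map each gene to ``module<i>`` or ``background``.  Deterministic
    for a fixed ``config.seed``.
    """
    rng = np.random.default_rng(int(config.seed))
    s = config.n_samples
    rho = config.intra_module_corr
    rows: list[np.ndarray] = []
    gene_ids: list[str] = []
    labels: dict[str, str] = {}

    for m, size in enumerate(config.module_sizes, start=1):
        latent = rng.standard_normal(s)
        for j in range(size):
            eps = rng.standard_normal(s)
            signal = np.sqrt(rho) * latent + np.sqrt(1.0 - rho) * eps
            gene = f"m{m}_g{j:03d}"
            gene_ids.append(gene)
            labels[gene] = f"module{m}"
            rows.append(signal)

    bg_rho = config.background_corr
    bg_latent = rng.standard_normal(s) if bg_rho > 0 else None
    for j in range(config.n_background):
        eps = rng.standard_normal(s)
        if bg_latent is not None:
            signal = np.sqrt(bg_rho) * bg_latent + np.sqrt(1.0 - bg_rho) * eps
        else:
            signal = eps
        gene = f"bg_g{j:03d}"
        gene_ids.append(gene)
        labels[gene] = "background"
        rows.append(signal)

    baseline = rng.normal(8.0, 1.0, size=len(rows))
    values = config.noise_sd * np.vstack(rows) + baseline[:, None]
    sample_ids = tuple(f"s{j:03d}" for j in range(s))
    expr = ExpressionMatrix(
        gene_ids=tuple(gene_ids), sample_ids=sample_ids, values=values
    )
    return expr, labels


def generate_graph(
    config: SyntheticConfig, tau: float
) -> tuple[CorrelationGraph, dict[str, str]]:
    """Thresholded correlation graph of a generated expression matrix."""
    expr, labels = generate_expression(config)
    corr = correlation_matrix(expr)
    return threshold_graph(corr, tau), labels


def write_labels(labels: dict[str, str], path: str | Path) -> Path:
    path = Path(path)
    lines = ["gene\tlabel"] + [f"{g}\t{lab}" for g, lab in sorted(labels.items())]
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")
    return path
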