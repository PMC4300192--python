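"""Genetic information entropy filtering.

A gene's abundance profile across n samples is normalized to a
probability vector p_ij = |x_ij| / sum_k |x_ik|, and its Shannon
entropy H_i = -sum_j p_ij ln p_ij (nats) measures how uniform the
profile is. A gene expressed identically in every sample attains the
maximum H = ln n; such genes carry no differential-expression signal,
so the filter removes the configured fraction of *highest*-entropy
genes before the pairwise correlation stage.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .io import ExpressionMatrix

__all__ = ["EntropyReport", "gene_entropy", "filter_genes"]


@dataclass
class EntropyReport:
    """Per-gene entropies (nats) and, once a filter ran, retention flags."""

    gene_ids: list[str]
    entropy: np.ndarray
    retained: np.ndarray | None = None


def gene_entropy(expr: ExpressionMatrix) -> EntropyReport:
    """Compute per-gene entropy of the normalized absolute abundances.

    Terms with p_ij = 0 contribute zero; an all-zero gene row has an
    undefined probability vector and is assigned H = 0 (a point-mass
    reading), so it survives the entropy cut and is neutralized later
    at the correlation stage.

    Raises
    ------
    ValueError
        If there are fewer than two samples: entropy over a single
        sample is vacuous.
    """
    if expr.n_samples < 2:
        raise ValueError("entropy requires at least 2 samples")
    a = np.abs(expr.values)
    total = a.sum(axis=1)
    nonzero = total > 0
    p = np.zeros_like(a)
    p[nonzero] = a[nonzero] / total[nonzero, None]
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(p > 0, p * np.log(p), 0.0)
    h = -terms.sum(axis=1)
    h[~nonzero] = 0.0
    # numerical guard: entropy is non-negative and bounded by ln(n)
    np.clip(h, 0.0, math.log(expr.n_samples), out=h)
    return EntropyReport(gene_ids=list(expr.gene_ids), entropy=h)


def filter_genes(
    expr: ExpressionMatrix, report: EntropyReport, fraction: float
) -> ExpressionMatrix:
    """Remove the ``ceil(fraction * m)`` genes with the largest entropy.

    Surviving genes keep their original relative order. Ties at the cut
    boundary retain the gene with the smaller original row index.
    ``fraction = 0`` returns the input unchanged. The report's
    ``retained`` flags are filled in as a side effect.

    Raises
    ------
    ValueError
        If `fraction` is outside [0, 1], if ``fraction = 1`` (nothing
        would remain), or if the report is not aligned to `expr`.
    """
    if not 0.0 <= fraction <= 1.0:
        raise ValueError(f"filter fraction {fraction} outside [0, 1]")
    if list(report.gene_ids) != list(expr.gene_ids):
        raise ValueError("entropy report is not aligned to the expression matrix")
    m = expr.n_genes
    if fraction == 0.0:
        report.retained = np.ones(m, dtype=bool)
        return expr
    n_remove = math.ceil(fraction * m)
    if n_remove >= m:
        raise ValueError(
            "filtering would remove every gene; lower the filter fraction"
        )
    # descending entropy, ties broken toward removing the larger row index
    order = np.lexsort((-np.arange(m), -report.entropy))
    retained = np.ones(m, dtype=bool)
    retained[order[:n_remove]] = False
    report.retained = retained
    return expr.subset_genes(np.flatnonzero(retained))
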