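"""Synthetic expression matrices with planted co-expression modules.

Each planted module shares one latent factor: for module member g and
sample j,

    x_gj = baseline + loading * f_j + noise_sd * e_gj,    f_j, e_gj ~ N(0, 1)

so the expected correlation between two members is
loading^2 / (loading^2 + noise_sd^2). Background genes carry noise
only; "flat" genes are near-constant (a constant plus sd = 1e-6
jitter), giving them the maximal entropy in the matrix so they are the
designed targets of the entropy filter. The positive baseline keeps
abundances nonnegative, as with real quantifications.

The defaults — 4 modules of 50 genes with within-module correlation
0.6, 100 background genes, 20 flat genes, 200 samples — are the fixed
study conditions used throughout the test suite; a fixed seed gives
bit-identical output.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .io import ExpressionMatrix
from .modules import ModuleAssignment

__all__ = ["SyntheticSpec", "generate", "DEFAULT_LOADING"]

#: loading giving within-module correlation 0.6 at the default noise_sd = 0.5
DEFAULT_LOADING = 0.5 * math.sqrt(1.5)

BACKGROUND = "background"
FLAT = "flat"


@dataclass
class SyntheticSpec:
    """Parameters of the planted-module factor model."""

    n_samples: int = 200
    modules: tuple[tuple[int, float], ...] = ((50, DEFAULT_LOADING),) * 4
    n_background: int = 100
    n_flat: int = 20
    noise_sd: float = 0.5
    baseline: float = 10.0
    flat_jitter_sd: float = 1e-6
    seed: int = 0

    @property
    def n_genes(self) -> int:
        return sum(size for size, _ in self.modules) + self.n_background + self.n_flat

    def validate(self) -> None:
        if self.n_samples < 2:
            raise ValueError("n_samples must be >= 2")
        for size, loading in self.modules:
            if size < 1:
                raise ValueError("module sizes must be >= 1")
            if not 0.0 < loading < 1.0:
                raise ValueError(f"loading {loading} outside (0, 1)")
        if self.n_background < 0 or self.n_flat < 0:
            raise ValueError("gene counts must be nonnegative")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        if self.baseline < 0:
            raise ValueError("baseline must be nonnegative")
        if self.flat_jitter_sd <= 0:
            raise ValueError("flat_jitter_sd must be positive")
        if self.n_genes < 2:
            raise ValueError("need at least 2 genes in total")

    def expected_module_correlation(self, module: int = 0) -> float:
        """Closed-form within-module correlation implied by the factor model."""
        loading = self.modules[module][1]
        return loading**2 / (loading**2 + self.noise_sd**2)


def generate(spec: SyntheticSpec) -> tuple[ExpressionMatrix, ModuleAssignment]:
    """Draw an expression matrix and its ground-truth labels.

    Truth labels are the module number ("1", "2", ...) for planted
    members, "background" for pure-noise genes, and "flat" for the
    near-constant entropy-filter targets. Identical seeds give
    bit-identical output.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    n = spec.n_samples

    rows: list[np.ndarray] = []
    gene_ids: list[str] = []
    labels: list[str] = []

    for m_idx, (size, loading) in enumerate(spec.modules, start=1):
        factor = rng.standard_normal(n)
        noise = rng.standard_normal((size, n))
        rows.append(spec.baseline + loading * factor + spec.noise_sd * noise)
        gene_ids.extend(f"MOD{m_idx}_G{g + 1:03d}" for g in range(size))
        labels.extend([str(m_idx)] * size)

    if spec.n_background:
        rows.append(
            spec.baseline + spec.noise_sd * rng.standard_normal((spec.n_background, n))
        )
        gene_ids.extend(f"BG_G{g + 1:03d}" for g in range(spec.n_background))
        labels.extend([BACKGROUND] * spec.n_background)

    if spec.n_flat:
        rows.append(
            spec.baseline
            + spec.flat_jitter_sd * rng.standard_normal((spec.n_flat, n))
        )
        gene_ids.extend(f"FLAT_G{g + 1:03d}" for g in range(spec.n_flat))
        labels.extend([FLAT] * spec.n_flat)

    values = np.vstack(rows)
    sample_ids = [f"S{j + 1:03d}" for j in range(n)]
    expr = ExpressionMatrix(gene_ids=gene_ids, sample_ids=sample_ids, values=values)
    truth = ModuleAssignment(gene_ids=list(gene_ids), labels=labels)
    return expr, truth
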