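"""Edge significance: population z-normalization, p-values, and FDR.

The default test statistic standardizes each pairwise correlation
against the mean and standard deviation of the *whole* population of
t = k(k-1)/2 coefficients:

    z_i = (rho_i - rho_bar) / S,       S = sd over all t values (t-1 denom.)

treating z as asymptotically standard normal. This tests each
coefficient against the coefficient population, not against a per-pair
null with n-2 degrees of freedom; the classical Fisher transform is
available separately (``method="fisher"``) as an explicitly labeled
alternative. Multiple testing is controlled with Benjamini–Hochberg
step-up q-values.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

from .correlation import PackedTriangular

__all__ = [
    "EdgeStatistics",
    "normalize_coefficients",
    "z_to_p",
    "fisher_z",
    "fdr_qvalues",
    "compute_edge_statistics",
]


@dataclass
class EdgeStatistics:
    """Per-pair rho, z, p and q in packed index order, plus the
    coefficient-population mean and standard deviation."""

    k: int
    rho: PackedTriangular
    z: np.ndarray
    p: np.ndarray
    q: np.ndarray
    rho_bar: float
    s: float


def normalize_coefficients(
    rho: PackedTriangular | np.ndarray,
) -> tuple[np.ndarray, float, float]:
    """Standardize the coefficient population to z-scores.

    Returns ``(z, rho_bar, s)`` where `rho_bar` is the mean over all t
    coefficients and `s` the sample standard deviation (t-1
    denominator).

    Raises
    ------
    ValueError
        For fewer than two coefficients, or when every coefficient is
        identical (S = 0): a degenerate population that cannot be
        standardized.
    """
    v = np.asarray(getattr(rho, "values", rho), dtype=np.float64)
    t = len(v)
    if t < 2:
        raise ValueError("z-normalization needs at least 2 coefficients")
    rho_bar = float(v.mean())
    s = float(v.std(ddof=1))
    if s == 0.0:
        raise ValueError(
            "all correlation coefficients are identical (S = 0); the "
            "coefficient population is degenerate and cannot be normalized"
        )
    return (v - rho_bar) / s, rho_bar, s


def z_to_p(z: np.ndarray, tail: str = "two") -> np.ndarray:
    """Convert z-scores to p-values under the standard normal.

    ``tail="two"`` gives p = 2(1 - Phi(|z|)); ``tail="right"`` gives
    p = 1 - Phi(z) (positive co-expression only).
    """
    z = np.asarray(z, dtype=np.float64)
    if not np.isfinite(z).all():
        raise ValueError("non-finite z-score")
    if tail == "two":
        return 2.0 * sps.norm.sf(np.abs(z))
    if tail == "right":
        return sps.norm.sf(z)
    raise ValueError(f"unknown tail {tail!r} (expected 'two' or 'right')")


def fisher_z(rho: PackedTriangular | np.ndarray, n_samples: int) -> np.ndarray:
    """Fisher-transformed per-pair z-scores, z = atanh(rho) * sqrt(n-3).

    A per-pair alternative to the population normalization; requires the
    sample count.
    """
    if n_samples < 4:
        raise ValueError("Fisher transform requires at least 4 samples")
    v = np.asarray(getattr(rho, "values", rho), dtype=np.float64)
    r = np.clip(v, -1.0 + 1e-15, 1.0 - 1e-15)
    return np.arctanh(r) * np.sqrt(n_samples - 3)


def fdr_qvalues(p: np.ndarray) -> np.ndarray:
    """Benjamini–Hochberg step-up q-values.

    q_(i) = min_{j >= i} t * p_(j) / j over the ascending-sorted
    p-values, capped at 1 and mapped back to input order; tied p-values
    share a q-value.
    """
    p = np.asarray(p, dtype=np.float64)
    if p.size == 0:
        return p.copy()
    if not np.isfinite(p).all() or ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    t = p.size
    order = np.argsort(p, kind="stable")
    raw = t * p[order] / np.arange(1, t + 1)
    q_sorted = np.minimum(np.minimum.accumulate(raw[::-1])[::-1], 1.0)
    q = np.empty(t, dtype=np.float64)
    q[order] = q_sorted
    return q


def compute_edge_statistics(
    rho: PackedTriangular,
    tail: str = "two",
    method: str = "fastgcn",
    n_samples: int | None = None,
) -> EdgeStatistics:
    """Full significance pass: z-scores, p-values and q-values.

    `method` selects the z statistic: ``"fastgcn"`` (population
    normalization, the default) or ``"fisher"`` (per-pair Fisher
    transform, needs `n_samples`). The population mean and standard
    deviation are reported either way.
    """
    z_pop, rho_bar, s = normalize_coefficients(rho)
    if method == "fastgcn":
        z = z_pop
    elif method == "fisher":
        if n_samples is None:
            raise ValueError("method='fisher' requires n_samples")
        z = fisher_z(rho, n_samples)
    else:
        raise ValueError(f"unknown method {method!r} (expected 'fastgcn' or 'fisher')")
    p = z_to_p(z, tail=tail)
    q = fdr_qvalues(p)
    return EdgeStatistics(k=rho.k, rho=rho, z=z, p=p, q=q, rho_bar=rho_bar, s=s)
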