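"""Shared test utilities and independent reference oracles.

Every oracle here is deliberately written in the most direct form
possible (per-element loops, textbook formulas) and never shares code
with the implementation it checks.
"""

from __future__ import annotations

import math

import numpy as np

from fastgcn.io import ExpressionMatrix


def expr_from(values, gene_ids=None, sample_ids=None) -> ExpressionMatrix:
    values = np.asarray(values, dtype=float)
    m, n = values.shape
    return ExpressionMatrix(
        gene_ids=gene_ids or [f"G{i}" for i in range(m)],
        sample_ids=sample_ids or [f"S{j}" for j in range(n)],
        values=values,
    )


def entropy_oracle(row) -> float:
    """Term-by-term Shannon entropy of the normalized absolute row."""
    row = [abs(v) for v in row]
    total = sum(row)
    if total == 0:
        return 0.0
    h = 0.0
    for v in row:
        p = v / total
        if p > 0:
            h -= p * math.log(p)
    return h


def pearson_two_pass(x, y) -> float:
    """Textbook covariance / (sd * sd) with explicit mean subtraction."""
    n = len(x)
    mx = sum(x) / n
    my = sum(y) / n
    cov = sum((a - mx) * (b - my) for a, b in zip(x, y))
    vx = sum((a - mx) ** 2 for a in x)
    vy = sum((b - my) ** 2 for b in y)
    return cov / math.sqrt(vx * vy)


def pearson_one_pass(x, y) -> float:
    """The one-pass sums-of-products form of the Pearson coefficient."""
    n = len(x)
    sx, sy = sum(x), sum(y)
    sxy = sum(a * b for a, b in zip(x, y))
    sxx = sum(a * a for a in x)
    syy = sum(b * b for b in y)
    return (sxy - sx * sy / n) / math.sqrt((sxx - sx**2 / n) * (syy - sy**2 / n))


def bh_step_up_oracle(p) -> np.ndarray:
    """Benjamini-Hochberg by an explicit back-to-front loop over ranks."""
    p = np.asarray(p, dtype=float)
    t = len(p)
    order = np.argsort(p, kind="stable")
    q = np.empty(t)
    running = 1.0
    for rank in range(t, 0, -1):
        idx = order[rank - 1]
        running = min(running, t * p[idx] / rank)
        q[idx] = running
    return q


def shared_neighbors_brute(adj) -> np.ndarray:
    """h_ij = number of nodes u with a_iu = a_uj = 1, by triple loop."""
    adj = np.asarray(adj)
    k = adj.shape[0]
    h = np.zeros((k, k), dtype=np.int64)
    for i in range(k):
        for j in range(k):
            h[i, j] = sum(adj[i, u] and adj[u, j] for u in range(k))
    return h
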