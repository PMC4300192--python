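"""Binary adjacency, connectivity pruning, and topological-overlap similarity.

An edge is called between genes i and j when the pair's FDR q-value is
at or below the threshold tau:

    a_ij = 1 if q_ij <= tau else 0        (i != j; the diagonal is 0)

Node connectivity is the degree c_i = sum_j a_ij; genes with c_i = 0
are pruned before the similarity stage. On the pruned network the
topological-overlap similarity is

    s_ij = (h_ij + a_ij) / (c_i + c_j - h_ij - a_ij)

where h_ij = sum_u a_iu a_uj counts the neighbors shared by i and j.
s is a Jaccard-like score in [0, 1]: 1 when two genes have identical
neighborhoods, 0 when they are unlinked and share no neighbor.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .significance import EdgeStatistics

__all__ = [
    "AdjacencyNetwork",
    "SimilarityMatrix",
    "build_adjacency",
    "prune_isolated",
    "topological_similarity",
]


@dataclass
class AdjacencyNetwork:
    """Binary symmetric adjacency with zero diagonal and per-node degree."""

    gene_ids: list[str]
    adjacency: np.ndarray
    connectivity: np.ndarray
    tau: float
    #: indices of these nodes in the pre-pruning network (identity before pruning)
    original_indices: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.adjacency = np.asarray(self.adjacency, dtype=np.int8)
        if self.original_indices is None:
            self.original_indices = np.arange(len(self.gene_ids))
        k = len(self.gene_ids)
        if self.adjacency.shape != (k, k):
            raise ValueError("adjacency must be k x k")
        if (np.diag(self.adjacency) != 0).any():
            raise ValueError("adjacency diagonal must be zero")
        if (self.adjacency != self.adjacency.T).any():
            raise ValueError("adjacency must be symmetric")

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_edges(self) -> int:
        return int(self.adjacency.sum()) // 2


@dataclass
class SimilarityMatrix:
    """Topological-overlap similarity s (unit diagonal) and shared-neighbor
    counts h for the pruned network."""

    gene_ids: list[str]
    s: np.ndarray
    h: np.ndarray

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)


def build_adjacency(
    stats: EdgeStatistics, tau: float = 0.05, gene_ids: list[str] | None = None
) -> AdjacencyNetwork:
    """Threshold q-values into a binary adjacency network.

    The q-vector is unpacked from its lower-triangular layout; the
    diagonal is forced to zero (no self-edges) and connectivity is the
    resulting row sum. `gene_ids` labels the nodes (defaults to
    ``g0..g{k-1}``).
    """
    if not 0.0 <= tau <= 1.0:
        raise ValueError(f"tau {tau} outside [0, 1]")
    k = stats.k
    if gene_ids is None:
        gene_ids = [f"g{i}" for i in range(k)]
    elif len(gene_ids) != k:
        raise ValueError(f"{len(gene_ids)} gene IDs for {k} genes")
    adj = np.zeros((k, k), dtype=np.int8)
    rows, cols = np.tril_indices(k, -1)
    called = stats.q <= tau
    adj[rows, cols] = called
    adj[cols, rows] = called
    return AdjacencyNetwork(
        gene_ids=list(gene_ids),
        adjacency=adj,
        connectivity=adj.sum(axis=1, dtype=np.int64),
        tau=tau,
    )


def prune_isolated(net: AdjacencyNetwork) -> AdjacencyNetwork:
    """Induced subnetwork on nodes with connectivity >= 1.

    Original gene order is preserved; the returned network records each
    surviving node's index in the input via ``original_indices``.

    Raises
    ------
    ValueError
        If every node is isolated — nothing would remain; a larger tau
        admits more edges.
    """
    keep = np.flatnonzero(net.connectivity >= 1)
    if keep.size == 0:
        raise ValueError(
            "every gene is isolated at this threshold; increase tau to call edges"
        )
    adj = net.adjacency[np.ix_(keep, keep)]
    return AdjacencyNetwork(
        gene_ids=[net.gene_ids[i] for i in keep],
        adjacency=adj,
        connectivity=adj.sum(axis=1, dtype=np.int64),
        tau=net.tau,
        original_indices=net.original_indices[keep],
    )


def topological_similarity(net: AdjacencyNetwork) -> SimilarityMatrix:
    """Topological-overlap similarity of a pruned network.

    Shared-neighbor counts h = A @ A are computed as a dense matrix
    product; the similarity follows elementwise with the diagonal set
    to 1. On a pruned network the denominator is provably >= 1 for
    every pair (h_ij <= min(c_i, c_j) - a_ij), which is asserted.

    Raises
    ------
    ValueError
        If the input still contains zero-connectivity nodes.
    """
    if (net.connectivity == 0).any():
        raise ValueError(
            "similarity requires a pruned network (zero-connectivity nodes present)"
        )
    a = net.adjacency.astype(np.int64)
    h = a @ a  # h[i, j] = shared neighbors; h[i, i] = c_i
    c = net.connectivity.astype(np.int64)
    denom = c[:, None] + c[None, :] - h - a
    numer = h + a
    off = ~np.eye(net.n_genes, dtype=bool)
    if (denom[off] < 1).any():
        raise AssertionError("similarity denominator < 1 on a pruned network")
    s = np.ones((net.n_genes, net.n_genes), dtype=np.float64)
    s[off] = numer[off] / denom[off]
    return SimilarityMatrix(gene_ids=list(net.gene_ids), s=s, h=h)
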