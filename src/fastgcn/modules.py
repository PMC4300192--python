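"""Module detection on the topological-overlap similarity matrix.

Genes with highly overlapping neighborhoods form "hot blocks" along the
diagonal of the similarity matrix once its rows and columns are ordered
by a clustering of the genes. Modules are identified by average-linkage
agglomerative clustering on the dissimilarity d = 1 - s with a static
height cut: every cluster of at least `min_size` genes below the cut
becomes a module, smaller clusters are labeled "unassigned". Module
labels are positive integers numbered by decreasing size (ties broken
by the smallest member index), so identical inputs always produce
identical labels.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .network import SimilarityMatrix

__all__ = ["ModuleAssignment", "identify_modules", "order_for_heatmap"]

UNASSIGNED = "unassigned"
UNCONNECTED = "unconnected"


@dataclass
class ModuleAssignment:
    """Per-gene module labels: positive integers (as strings) for
    modules, "unassigned" for clustered-but-small groups, "unconnected"
    for genes pruned from the network."""

    gene_ids: list[str]
    labels: list[str]

    def as_dict(self) -> dict[str, str]:
        return dict(zip(self.gene_ids, self.labels))


def _average_linkage(sim: SimilarityMatrix) -> np.ndarray:
    d = 1.0 - sim.s
    np.fill_diagonal(d, 0.0)
    np.clip(d, 0.0, None, out=d)  # guard tiny negative round-off
    condensed = squareform(d, checks=False)
    return hierarchy.linkage(condensed, method="average")


def identify_modules(
    sim: SimilarityMatrix, cut_height: float = 0.5, min_size: int = 5
) -> ModuleAssignment:
    """Cluster the similarity matrix into modules.

    Parameters
    ----------
    sim:
        Topological-overlap similarity of the pruned network.
    cut_height:
        Static dendrogram cut on the dissimilarity scale (0, 1]; genes
        whose average-linkage merge height stays at or below it end up
        in the same cluster.
    min_size:
        Minimum gene count for a cluster to be reported as a module.
    """
    if not 0.0 < cut_height <= 1.0:
        raise ValueError(f"cut_height {cut_height} outside (0, 1]")
    if min_size < 1:
        raise ValueError("min_size must be >= 1")
    k = sim.n_genes
    if k == 0:
        return ModuleAssignment(gene_ids=[], labels=[])
    if k == 1:
        label = "1" if min_size <= 1 else UNASSIGNED
        return ModuleAssignment(gene_ids=list(sim.gene_ids), labels=[label])

    flat = hierarchy.fcluster(_average_linkage(sim), t=cut_height, criterion="distance")

    groups: dict[int, list[int]] = {}
    for idx, cl in enumerate(flat):
        groups.setdefault(int(cl), []).append(idx)
    modules = [g for g in groups.values() if len(g) >= min_size]
    # number 1..M by decreasing size, ties by smallest member index
    modules.sort(key=lambda g: (-len(g), min(g)))

    labels = [UNASSIGNED] * k
    for number, members in enumerate(modules, start=1):
        for idx in members:
            labels[idx] = str(number)
    return ModuleAssignment(gene_ids=list(sim.gene_ids), labels=labels)


def order_for_heatmap(
    sim: SimilarityMatrix, assignment: ModuleAssignment
) -> np.ndarray:
    """Dendrogram leaf order for displaying the similarity matrix.

    Members of each cluster occupy contiguous positions, so applying
    the permutation to the rows and columns of s places high-similarity
    blocks along the diagonal.
    """
    if list(assignment.gene_ids) != list(sim.gene_ids):
        raise ValueError("assignment does not cover the similarity matrix's genes")
    if sim.n_genes < 2:
        return np.arange(sim.n_genes)
    return hierarchy.leaves_list(_average_linkage(sim))
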