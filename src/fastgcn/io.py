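"""Reading and writing expression matrices and pipeline outputs.

The expression matrix is a genes x samples table of real abundances:
tab- or comma-separated text with a header row of sample identifiers and
a first column of gene identifiers. Missing cells are an error, never
imputed. All other outputs (entropy table, edge table, module table,
GraphML network) are plain text with fixed schemas so runs are
byte-reproducible.
"""

from __future__ import annotations

import struct
from dataclasses import dataclass
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

__all__ = [
    "ExpressionMatrix",
    "read_expression",
    "write_expression",
    "write_entropy_table",
    "write_edge_table",
    "write_modules_table",
    "write_graphml",
    "write_packed",
    "read_packed",
]

PACKED_MAGIC = b"FGCN1"


@dataclass
class ExpressionMatrix:
    """Gene x sample abundance matrix with identifiers.

    Rows are genes, columns are samples. Values are unit-agnostic real
    abundances stored in double precision.
    """

    gene_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D matrix")
        m, n = self.values.shape
        if m != len(self.gene_ids):
            raise ValueError(
                f"row count {m} does not match gene_ids length {len(self.gene_ids)}"
            )
        if n != len(self.sample_ids):
            raise ValueError(
                f"column count {n} does not match sample_ids length {len(self.sample_ids)}"
            )
        _check_unique(self.gene_ids, "gene ID")
        _check_unique(self.sample_ids, "sample ID")
        if not np.isfinite(self.values).all():
            bad = np.argwhere(~np.isfinite(self.values))[0]
            raise ValueError(
                f"non-finite value for gene {self.gene_ids[bad[0]]!r}, "
                f"sample {self.sample_ids[bad[1]]!r}"
            )

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def transpose(self) -> "ExpressionMatrix":
        """Swap the gene/sample orientation (for samples-as-rows input)."""
        return ExpressionMatrix(
            gene_ids=list(self.sample_ids),
            sample_ids=list(self.gene_ids),
            values=self.values.T.copy(),
        )

    def subset_genes(self, index: np.ndarray) -> "ExpressionMatrix":
        """Induced matrix on a gene index array, preserving order."""
        index = np.asarray(index)
        return ExpressionMatrix(
            gene_ids=[self.gene_ids[i] for i in index],
            sample_ids=list(self.sample_ids),
            values=self.values[index],
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=list(self.gene_ids), columns=list(self.sample_ids)
        )


def _check_unique(ids: list[str], what: str) -> None:
    seen: set[str] = set()
    for name in ids:
        if name in seen:
            raise ValueError(f"duplicate {what} {name!r}")
        seen.add(name)


def _detect_delimiter(path: Path, delimiter: str | None) -> str:
    if delimiter is not None:
        return delimiter
    return "," if path.suffix.lower() == ".csv" else "\t"


def read_expression(path: str | Path, delimiter: str | None = None) -> ExpressionMatrix:
    """Read an expression matrix from delimited text.

    The first row is a header of sample IDs (corner cell ignored); the
    first column holds gene IDs. Every data cell must parse as a finite
    real number.

    Parameters
    ----------
    path:
        Input file. The delimiter defaults to ``,`` for ``.csv`` and to
        a tab otherwise; pass `delimiter` to override.

    Raises
    ------
    ValueError
        On duplicate gene or sample IDs, missing or non-numeric cells
        (reported with gene/sample coordinates), or ragged rows.
    """
    path = Path(path)
    sep = _detect_delimiter(path, delimiter)
    with open(path, "r", encoding="utf-8") as fh:
        header = fh.readline()
    if not header.strip():
        raise ValueError(f"{path}: empty file")
    sample_ids = [c.strip() for c in header.rstrip("\r\n").split(sep)[1:]]
    _check_unique(sample_ids, "sample ID")

    try:
        df = pd.read_csv(
            path,
            sep=sep,
            index_col=0,
            header=0,
            dtype=str,
            keep_default_na=False,
            skipinitialspace=True,
        )
    except pd.errors.ParserError as exc:  # ragged rows, mostly
        raise ValueError(f"{path}: malformed table ({exc})") from exc
    if df.shape[1] != len(sample_ids):
        raise ValueError(f"{path}: ragged header/data rows")

    gene_ids = [str(g) for g in df.index]
    _check_unique(gene_ids, "gene ID")

    raw = df.to_numpy(dtype=object)

    def _cell_error(r: int, c: int) -> ValueError:
        return ValueError(
            f"{path}: cell {raw[r, c]!r} for gene {gene_ids[r]!r}, "
            f"sample {sample_ids[c]!r} (row {r + 2}, column {c + 2}) "
            "is missing or not a finite number"
        )

    try:
        # element-wise float() via the object-array cast: exact round-trip
        values = raw.astype(np.float64)
    except (TypeError, ValueError):
        for (r, c), cell in np.ndenumerate(raw):
            try:
                float(cell)
            except (TypeError, ValueError):
                raise _cell_error(r, c) from None
        raise ValueError(f"{path}: unparseable numeric data") from None
    finite = np.isfinite(values)
    if not finite.all():
        r, c = map(int, np.argwhere(~finite)[0])
        raise _cell_error(r, c)
    return ExpressionMatrix(gene_ids=gene_ids, sample_ids=sample_ids, values=values)


def write_expression(
    expr: ExpressionMatrix, path: str | Path, delimiter: str | None = None
) -> None:
    """Write a matrix at full precision (round-trips exactly through
    :func:`read_expression`)."""
    path = Path(path)
    sep = _detect_delimiter(path, delimiter)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("gene_id" + sep + sep.join(expr.sample_ids) + "\n")
        for gid, row in zip(expr.gene_ids, expr.values):
            fh.write(gid + sep + sep.join(repr(float(v)) for v in row) + "\n")


def write_entropy_table(
    gene_ids: list[str],
    entropy: np.ndarray,
    retained: np.ndarray,
    path: str | Path,
) -> None:
    """Write the per-gene entropy report: gene_id, entropy, retained flag."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("gene_id\tentropy\tretained\n")
        for gid, h, keep in zip(gene_ids, entropy, retained):
            fh.write(f"{gid}\t{h:.6g}\t{int(keep)}\n")


def write_edge_table(stats, net, path: str | Path) -> None:
    """Write the per-pair statistics table in ascending packed order.

    Columns: gene_a, gene_b, rho, z, p, q, adjacent — one row per
    stored pair (``k(k-1)/2`` rows). ``gene_a`` is the higher-index gene
    of the pair, matching the packed lower-triangle layout. Floats use
    6 significant digits.
    """
    from .correlation import index_to_pair

    k = net.n_genes
    t = k * (k - 1) // 2
    if len(stats.rho.values) != t:
        raise ValueError(
            f"edge statistics hold {len(stats.rho.values)} pairs but the "
            f"network's {k} genes require {t}"
        )
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("gene_a\tgene_b\trho\tz\tp\tq\tadjacent\n")
        for idx in range(t):
            i, j = index_to_pair(idx, k)
            fh.write(
                f"{net.gene_ids[i]}\t{net.gene_ids[j]}\t"
                f"{stats.rho.values[idx]:.6g}\t{stats.z[idx]:.6g}\t"
                f"{stats.p[idx]:.6g}\t{stats.q[idx]:.6g}\t"
                f"{int(net.adjacency[i, j])}\n"
            )


def write_modules_table(assignment, path: str | Path) -> None:
    """Write gene_id → module_label (positive integers, "unassigned",
    or "unconnected")."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("gene_id\tmodule_label\n")
        for gid, label in zip(assignment.gene_ids, assignment.labels):
            fh.write(f"{gid}\t{label}\n")


def write_graphml(net, assignment, path: str | Path) -> None:
    """Export the network as GraphML with gene_id and module node attributes.

    Every node in `net` must carry a module label in `assignment`.
    """
    labels = dict(zip(assignment.gene_ids, assignment.labels))
    missing = [g for g in net.gene_ids if g not in labels]
    if missing:
        raise ValueError(f"genes missing from module assignment: {missing[:5]}")
    graph = nx.Graph()
    for g in net.gene_ids:
        graph.add_node(g, gene_id=g, module=str(labels[g]))
    rows, cols = np.nonzero(np.tril(net.adjacency, k=-1))
    for i, j in zip(rows.tolist(), cols.tolist()):
        graph.add_edge(net.gene_ids[i], net.gene_ids[j])
    nx.write_graphml(graph, path)


def write_packed(packed, path: str | Path) -> None:
    """Write a packed triangular vector to the binary container.

    Layout: magic ``FGCN1``, gene count k as little-endian uint64, then
    the k(k-1)/2 values as little-endian float64 in packed order.
    """
    with open(path, "wb") as fh:
        fh.write(PACKED_MAGIC)
        fh.write(struct.pack("<Q", packed.k))
        fh.write(np.asarray(packed.values, dtype="<f8").tobytes())


def read_packed(path: str | Path):
    """Read a packed triangular vector written by :func:`write_packed`."""
    from .correlation import PackedTriangular

    with open(path, "rb") as fh:
        magic = fh.read(5)
        if magic != PACKED_MAGIC:
            raise ValueError(f"{path}: not a packed-statistic container")
        (k,) = struct.unpack("<Q", fh.read(8))
        values = np.frombuffer(fh.read(), dtype="<f8").astype(np.float64)
    t = k * (k - 1) // 2
    if len(values) != t:
        raise ValueError(f"{path}: expected {t} values for k={k}, found {len(values)}")
    return PackedTriangular(k=int(k), values=values)
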