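"""Four-stage co-expression pipeline orchestration.

Stages: (1) entropy filtering of non-differential genes, (2) all-pairs
Pearson correlation into packed storage, (3) population z-normalization
with FDR-controlled edge calling, (4) network construction, pruning,
topological-overlap similarity and module detection. Outputs are
entropy.tsv, edges.tsv, modules.tsv, network.graphml and a JSON
run-manifest with parameters, input checksum, per-stage gene counts and
wall-clock timings. When filter_fraction is 0 the entropy stage is
skipped entirely — the entropies are never computed.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np

from . import correlation, entropy, io, modules, network, significance

__all__ = ["PipelineConfig", "run_pipeline", "PipelineError"]

logger = logging.getLogger(__name__)

OUTPUT_FILES = (
    "entropy.tsv",
    "edges.tsv",
    "modules.tsv",
    "network.graphml",
    "run_manifest.json",
)


class PipelineError(RuntimeError):
    """A stage failure; the message names the stage."""


@dataclass
class PipelineConfig:
    """All pipeline parameters; mirrors the command-line flags."""

    input_path: str
    out_dir: str
    filter_fraction: float = 0.5
    tau: float = 0.05
    tail: str = "two"
    method: str = "fastgcn"
    cut_height: float = 0.5
    min_module_size: int = 5
    transpose: bool = False
    delimiter: str | None = None
    overwrite: bool = False
    log_base: str = "e"
    log_level: str = "INFO"

    def validate(self) -> None:
        if not 0.0 <= self.filter_fraction <= 1.0:
            raise ValueError("filter_fraction outside [0, 1]")
        if not 0.0 <= self.tau <= 1.0:
            raise ValueError("tau outside [0, 1]")
        if not 0.0 < self.cut_height <= 1.0:
            raise ValueError("cut_height outside (0, 1]")
        if self.min_module_size < 1:
            raise ValueError("min_module_size must be >= 1")
        if self.tail not in ("two", "right"):
            raise ValueError("tail must be 'two' or 'right'")
        if self.method not in ("fastgcn", "fisher"):
            raise ValueError("method must be 'fastgcn' or 'fisher'")
        if self.log_base not in ("e", "2"):
            raise ValueError("log_base must be 'e' or '2'")


def _sha256(path: Path) -> str:
    digest = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            digest.update(chunk)
    return digest.hexdigest()


def run_pipeline(config: PipelineConfig) -> dict:
    """Run all stages and write every output file.

    Returns the run manifest (also written to ``run_manifest.json``).
    On any stage failure the partially written outputs of this run are
    removed and a :class:`PipelineError` naming the stage is raised.
    """
    config.validate()
    in_path = Path(config.input_path)
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    existing = [f for f in OUTPUT_FILES if (out_dir / f).exists()]
    if existing and not config.overwrite:
        raise FileExistsError(
            f"output files already exist in {out_dir} ({', '.join(existing)}); "
            "pass overwrite=True / --overwrite to replace them"
        )

    written: list[Path] = []
    manifest: dict = {
        "parameters": asdict(config),
        "input_sha256": _sha256(in_path),
        "stages": {},
    }
    stage = "read"
    timings: dict[str, float] = {}

    def _finish(name: str, t0: float, **info) -> None:
        manifest["stages"][name] = {
            "seconds": round(time.perf_counter() - t0, 6),
            "status": "completed",
            **info,
        }

    try:
        t0 = time.perf_counter()
        expr = io.read_expression(in_path, delimiter=config.delimiter)
        if config.transpose:
            expr = expr.transpose()
        manifest["n_genes_input"] = expr.n_genes
        manifest["n_samples"] = expr.n_samples
        _finish("read", t0)

        stage = "entropy"
        if config.filter_fraction == 0.0:
            # no filtering requested: the entropy computation is never invoked
            manifest["stages"]["entropy"] = {"status": "skipped"}
            filtered = expr
        else:
            t0 = time.perf_counter()
            report = entropy.gene_entropy(expr)
            filtered = entropy.filter_genes(expr, report, config.filter_fraction)
            scale = np.log(2.0) if config.log_base == "2" else 1.0
            path = out_dir / "entropy.tsv"
            io.write_entropy_table(
                report.gene_ids, report.entropy / scale, report.retained, path
            )
            written.append(path)
            _finish("entropy", t0)
        manifest["n_genes_after_entropy"] = filtered.n_genes
        manifest["n_genes_removed_by_entropy"] = expr.n_genes - filtered.n_genes

        stage = "correlation"
        t0 = time.perf_counter()
        rho = correlation.pearson_all_pairs(filtered)
        manifest["n_pairs"] = rho.n_pairs
        _finish("correlation", t0)

        stage = "significance"
        t0 = time.perf_counter()
        stats = significance.compute_edge_statistics(
            rho, tail=config.tail, method=config.method, n_samples=filtered.n_samples
        )
        manifest["rho_bar"] = stats.rho_bar
        manifest["rho_sd"] = stats.s
        _finish("significance", t0)

        stage = "network"
        t0 = time.perf_counter()
        net = network.build_adjacency(stats, tau=config.tau, gene_ids=filtered.gene_ids)
        manifest["n_edges"] = net.n_edges
        pruned = network.prune_isolated(net)
        manifest["n_genes_unconnected"] = net.n_genes - pruned.n_genes
        manifest["n_genes_in_network"] = pruned.n_genes
        sim = network.topological_similarity(pruned)
        _finish("network", t0)

        stage = "modules"
        t0 = time.perf_counter()
        assignment = modules.identify_modules(
            sim, cut_height=config.cut_height, min_size=config.min_module_size
        )
        manifest["n_modules"] = len({lab for lab in assignment.labels if lab.isdigit()})
        _finish("modules", t0)

        stage = "write"
        t0 = time.perf_counter()
        # module table covers every post-filter gene; pruned genes stay auditable
        label_map = assignment.as_dict()
        full_assignment = modules.ModuleAssignment(
            gene_ids=list(filtered.gene_ids),
            labels=[label_map.get(g, modules.UNCONNECTED) for g in filtered.gene_ids],
        )
        for name, writer in (
            ("edges.tsv", lambda p: io.write_edge_table(stats, net, p)),
            ("modules.tsv", lambda p: io.write_modules_table(full_assignment, p)),
            ("network.graphml", lambda p: io.write_graphml(pruned, assignment, p)),
        ):
            path = out_dir / name
            writer(path)
            written.append(path)
        _finish("write", t0)

        manifest_path = out_dir / "run_manifest.json"
        with open(manifest_path, "w", encoding="utf-8") as fh:
            json.dump(manifest, fh, indent=2)
            fh.write("\n")
        return manifest
    except Exception as exc:
        for path in written:
            path.unlink(missing_ok=True)
        logger.error("pipeline stage %s failed: %s", stage, exc)
        raise PipelineError(f"[stage {stage}] {exc}") from exc
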