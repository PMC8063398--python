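"""End-to-end orchestration: QC -> normalize -> HVG -> first clustering ->
sensitive-gene detection -> removal + HVG re-selection -> re-clustering ->
optional ECA/ECP scoring, with a JSON manifest that reproduces the run."""

from __future__ import annotations

import json
import logging
import math
from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import pandas as pd

from . import io as sio
from .cluster import EmbeddingParams, run_clustering, select_hvg
from .containers import CellLabelTable, ClusterLabels, CountMatrix, SensitiveGeneReport
from .evaluate import score_clustering
from .preprocess import QCParams, exclude_cells, normalize_log, qc_filter
from .sensitive import detect_sensitive_genes, remove_and_reselect

__all__ = ["RunConfig", "PipelineResult", "run_pipeline", "run_pipeline_on"]

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Every stage parameter of the pipeline; defaults follow the standard
    workflow (QC < 500 genes / > 20% mito, scale factor 10,000, top-2000 CV
    HVGs, Louvain at resolution 0.6)."""

    input_path: str = ""
    orientation: str = "auto"            # for dense tables: cells-in-rows / genes-in-rows
    truth_path: str | None = None
    exclude_barcodes_path: str | None = None
    out_dir: str = "scsensitive_out"
    min_genes: int = 500
    max_mito: float | None = 0.20
    mito_prefix: str = "MT-"
    scale_factor: float = 10_000.0
    n_hvg: int = 2000
    n_pcs: int = 50
    n_neighbors: int = 20
    resolution: float = 0.6
    algorithm: str = "louvain"
    top_k: int = 2000
    candidate_rule: str = "ge_half"
    log_base: str = "e"                  # 'e' or '2'
    seed: int = 0

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    def to_dict(self) -> dict:
        return asdict(self)

    def log_base_value(self) -> float:
        return math.e if self.log_base == "e" else float(self.log_base)


@dataclass
class PipelineResult:
    report: SensitiveGeneReport
    labels_first: ClusterLabels
    labels_second: ClusterLabels
    hvg_first: list[str]
    hvg_second: list[str]
    scores: pd.DataFrame | None = None
    n_cells_in: int = 0
    n_cells_kept: int = 0
    manifest: dict = field(default_factory=dict)


def _load_counts(config: RunConfig) -> CountMatrix:
    path = Path(config.input_path)
    if not path.exists():
        raise FileNotFoundError(f"input path {path} does not exist")
    if path.is_dir():
        def find(*names):
            for n in names:
                for suffix in ("", ".gz"):
                    p = path / f"{n}{suffix}"
                    if p.exists():
                        return p
            raise FileNotFoundError(f"none of {names} found in {path}")

        return sio.read_10x_mtx(
            find("matrix.mtx"), find("features.tsv", "genes.tsv"), find("barcodes.tsv")
        )
    orientation = config.orientation
    if orientation == "auto":
        raise ValueError("dense input requires an explicit orientation (cells-in-rows/genes-in-rows)")
    return sio.read_dense_counts(path, orientation=orientation)


def run_pipeline_on(
    counts: CountMatrix,
    config: RunConfig,
    truth: CellLabelTable | None = None,
    write: bool = True,
) -> PipelineResult:
    """Run the full workflow on an in-memory CountMatrix."""
    n_in = counts.n_cells
    if config.exclude_barcodes_path:
        counts = exclude_cells(counts, sio.read_gene_list(config.exclude_barcodes_path))
    qc = QCParams(
        min_genes_per_cell=config.min_genes,
        max_mito_fraction=config.max_mito,
        mito_prefix=config.mito_prefix,
    )
    counts = qc_filter(counts, qc)
    logger.info("stage qc: %d -> %d cells", n_in, counts.n_cells)
    norm = normalize_log(counts, scale_factor=config.scale_factor)
    emb = EmbeddingParams(
        n_hvg=config.n_hvg, n_pcs=config.n_pcs, n_neighbors=config.n_neighbors
    )
    hvg_first = select_hvg(norm, n_hvg=config.n_hvg)
    labels_first = run_clustering(
        norm, hvg_first, emb, resolution=config.resolution,
        algorithm=config.algorithm, seed=config.seed,
    )
    logger.info("stage first-clustering: %d clusters", labels_first.n_clusters)
    report = detect_sensitive_genes(
        norm, labels_first, top_k=config.top_k,
        candidate_rule=config.candidate_rule, log_base=config.log_base_value(),
    )
    logger.info(
        "stage detect: %d candidates, %d sensitive genes",
        report.params["n_candidates"], report.params["n_sensitive"],
    )
    hvg_second = remove_and_reselect(norm, report, n_hvg=config.n_hvg)
    labels_second = run_clustering(
        norm, hvg_second, emb, resolution=config.resolution,
        algorithm=config.algorithm, seed=config.seed,
    )
    logger.info("stage re-clustering: %d clusters", labels_second.n_clusters)

    scores = None
    if truth is not None:
        keep = set(counts.cell_ids)
        truth_sub = CellLabelTable(
            cell_ids=[c for c in truth.cell_ids if c in keep],
            labels=[l for c, l in zip(truth.cell_ids, truth.labels) if c in keep],
        )
        rows = [
            score_clustering(labels_first, truth_sub, condition="with_sensitive"),
            score_clustering(labels_second, truth_sub, condition="removed_sensitive"),
        ]
        scores = pd.DataFrame([asdict(r) for r in rows])

    manifest = {
        "config": config.to_dict(),
        "n_cells_input": n_in,
        "n_cells_kept": counts.n_cells,
        "n_genes": counts.n_genes,
        "n_clusters_first": labels_first.n_clusters,
        "n_clusters_second": labels_second.n_clusters,
        "n_candidates": report.params["n_candidates"],
        "n_sensitive": report.params["n_sensitive"],
    }
    result = PipelineResult(
        report=report,
        labels_first=labels_first,
        labels_second=labels_second,
        hvg_first=hvg_first,
        hvg_second=hvg_second,
        scores=scores,
        n_cells_in=n_in,
        n_cells_kept=counts.n_cells,
        manifest=manifest,
    )
    if write:
        _write_outputs(result, config)
    return result


def _write_outputs(result: PipelineResult, config: RunConfig) -> None:
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    sio.write_report(result.report, out / "report.tsv")
    sio.write_cluster_labels(result.labels_first, out / "labels_first.tsv")
    sio.write_cluster_labels(result.labels_second, out / "labels_second.tsv")
    sio.write_gene_list(result.hvg_first, out / "hvg_first.txt")
    sio.write_gene_list(result.hvg_second, out / "hvg_second.txt")
    if result.scores is not None:
        result.scores.to_csv(out / "scores.tsv", sep="\t", index=False, float_format="%.17g")
    with open(out / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(result.manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")


def run_pipeline(config: RunConfig) -> PipelineResult:
    """Load inputs per the config, run the workflow and write all outputs."""
    counts = _load_counts(config)
    truth = sio.read_cell_labels(config.truth_path) if config.truth_path else None
    return run_pipeline_on(counts, config, truth=truth, write=True)
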