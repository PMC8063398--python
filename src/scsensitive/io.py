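"""Readers and writers for count matrices, label tables, gene lists and reports.

Supported inputs are the 10x-style Matrix Market triplet (matrix.mtx[.gz] +
features/genes.tsv[.gz] + barcodes.tsv[.gz]) and dense delimited tables.
Outputs are UTF-8 TSV with a fixed column order, a plain-text gene list (one
id per line) and a JSON sidecar of run parameters, so downstream diffs stay
stable.
"""

from __future__ import annotations

import gzip
import json
from pathlib import Path
from typing import Literal

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

from .containers import CellLabelTable, ClusterLabels, CountMatrix, SensitiveGeneReport, make_unique

__all__ = [
    "read_10x_mtx",
    "read_dense_counts",
    "read_cell_labels",
    "read_cluster_labels",
    "write_cluster_labels",
    "write_10x_mtx",
    "write_report",
    "read_report",
    "write_gene_list",
    "read_gene_list",
    "FormatError",
]

REPORT_BASE_COLUMNS = ["gene_id", "candidate", "n_high_cv_clusters", "entropy", "sensitive"]


class FormatError(ValueError):
    """Raised when an input file violates its declared format."""


def _open_maybe_gzip(path: str | Path, mode: str = "rt"):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


def _read_id_column(path: str | Path) -> tuple[list[str], list[str] | None]:
    """Read a 10x features/barcodes TSV: first column id, second (if any) symbol."""
    df = pd.read_csv(path, sep="\t", header=None, dtype=str)
    ids = df.iloc[:, 0].tolist()
    symbols = df.iloc[:, 1].tolist() if df.shape[1] > 1 else None
    return ids, symbols


def read_10x_mtx(
    matrix_path: str | Path,
    features_path: str | Path,
    barcodes_path: str | Path,
    orientation: Literal["auto", "genes-in-rows", "cells-in-rows"] = "auto",
) -> CountMatrix:
    """Read a 10x-style Matrix Market triplet into a cells x genes CountMatrix.

    The on-disk matrix may be stored genes x cells (the 10x convention) or
    cells x genes; the orientation is detected by matching the MTX dimensions
    against the features/barcodes line counts.  A square matrix with equally
    many genes and barcodes is ambiguous and requires an explicit
    ``orientation`` — guessing would risk a silent transpose.
    """
    with _open_maybe_gzip(matrix_path, "rb") as fh:
        mat = scipy.io.mmread(fh)
    mat = sp.coo_matrix(mat)
    gene_ids, gene_symbols = _read_id_column(features_path)
    barcodes, _ = _read_id_column(barcodes_path)
    n_genes, n_cells = len(gene_ids), len(barcodes)

    shape = mat.shape
    if orientation == "auto":
        genes_in_rows = shape == (n_genes, n_cells)
        cells_in_rows = shape == (n_cells, n_genes)
        if genes_in_rows and cells_in_rows:
            raise FormatError(
                f"matrix is square ({shape[0]}x{shape[1]}) with {n_genes} features and "
                f"{n_cells} barcodes; orientation is ambiguous — pass orientation="
                "'genes-in-rows' or 'cells-in-rows' explicitly"
            )
        if genes_in_rows:
            mat = mat.T
        elif not cells_in_rows:
            raise FormatError(
                f"MTX dimensions {shape[0]}x{shape[1]} match neither "
                f"{n_genes} features x {n_cells} barcodes nor its transpose"
            )
    elif orientation == "genes-in-rows":
        if shape != (n_genes, n_cells):
            raise FormatError(
                f"MTX dimensions {shape} do not match {n_genes} features x {n_cells} barcodes"
            )
        mat = mat.T
    elif orientation == "cells-in-rows":
        if shape != (n_cells, n_genes):
            raise FormatError(
                f"MTX dimensions {shape} do not match {n_cells} barcodes x {n_genes} features"
            )
    else:
        raise ValueError(f"unknown orientation {orientation!r}")

    data = mat.data
    if data.size and (data.min() < 0 or not np.allclose(data, np.round(data))):
        raise FormatError("matrix contains negative or non-integer entries")

    return CountMatrix(
        counts=sp.csr_matrix(mat),
        cell_ids=make_unique(barcodes),
        gene_ids=make_unique(gene_ids),
        gene_symbols=gene_symbols,
    )


def write_10x_mtx(m: CountMatrix, out_dir: str | Path) -> None:
    """Write a CountMatrix as a 10x-style triplet (genes x cells on disk)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    scipy.io.mmwrite(str(out / "matrix.mtx"), sp.coo_matrix(m.counts.T.astype(int)))
    symbols = m.gene_symbols if m.gene_symbols is not None else m.gene_ids
    feats = pd.DataFrame({"id": m.gene_ids, "symbol": symbols})
    feats.to_csv(out / "features.tsv", sep="\t", header=False, index=False)
    pd.Series(m.cell_ids).to_csv(out / "barcodes.tsv", sep="\t", header=False, index=False)


def read_dense_counts(
    path: str | Path,
    orientation: Literal["cells-in-rows", "genes-in-rows"],
    sep: str | None = None,
) -> CountMatrix:
    """Read a dense delimited count table with a header row and id first column."""
    if sep is None:
        sep = "," if str(path).endswith(".csv") else "\t"
    df = pd.read_csv(path, sep=sep, index_col=0)
    body = df.apply(pd.to_numeric, errors="coerce")
    if body.isna().any().any():
        r, c = np.argwhere(body.isna().values)[0]
        raise FormatError(
            f"non-numeric value {df.iat[r, c]!r} at row {df.index[r]!r}, column {df.columns[c]!r}"
        )
    if (body.values < 0).any() or not np.allclose(body.values, np.round(body.values)):
        raise FormatError("count table contains negative or non-integer entries")
    if orientation == "genes-in-rows":
        body = body.T
    elif orientation != "cells-in-rows":
        raise ValueError(f"unknown orientation {orientation!r}")
    return CountMatrix(
        counts=sp.csr_matrix(body.values),
        cell_ids=make_unique([str(i) for i in body.index]),
        gene_ids=make_unique([str(c) for c in body.columns]),
    )


def read_cell_labels(path: str | Path, sep: str = "\t") -> CellLabelTable:
    """Read a two-column (cell_id, label) table; a header row is auto-detected."""
    df = pd.read_csv(path, sep=sep, dtype=str)
    if df.shape[1] < 2:
        raise FormatError("label table needs at least two columns (cell id, label)")
    cols = [c.lower() for c in df.columns]
    if not ({"cell_id", "label"} <= set(cols)):
        # headerless file: first row was data
        df = pd.read_csv(path, sep=sep, dtype=str, header=None)
    else:
        df = df.rename(columns=dict(zip(df.columns, cols)))[["cell_id", "label"]]
        df.columns = [0, 1]
    if df.isna().any().any():
        raise FormatError("label table contains missing values")
    return CellLabelTable(cell_ids=df.iloc[:, 0].tolist(), labels=df.iloc[:, 1].tolist())


def write_cluster_labels(labels: ClusterLabels, path: str | Path) -> None:
    df = pd.DataFrame({"cell_id": labels.cell_ids, "cluster": labels.cluster_of})
    df.to_csv(path, sep="\t", index=False)


def read_cluster_labels(
    path: str | Path, resolution: float = 0.0, algorithm: str = "external", seed: int = 0
) -> ClusterLabels:
    df = pd.read_csv(path, sep="\t", dtype={"cell_id": str, "cluster": int})
    return ClusterLabels(
        cell_ids=df["cell_id"].tolist(),
        cluster_of=df["cluster"].to_numpy(),
        resolution=resolution,
        algorithm=algorithm,
        seed=seed,
    )


def write_gene_list(genes: list[str], path: str | Path) -> None:
    Path(path).write_text("".join(f"{g}\n" for g in genes), encoding="utf-8")


def read_gene_list(path: str | Path) -> list[str]:
    return [line.strip() for line in Path(path).read_text(encoding="utf-8").splitlines() if line.strip()]


def _sidecar_paths(path: Path) -> tuple[Path, Path]:
    stem = path.with_suffix("")
    return Path(f"{stem}.params.json"), Path(f"{stem}.sensitive_genes.txt")


def write_report(report: SensitiveGeneReport, path: str | Path) -> None:
    """Write a SensitiveGeneReport as TSV + JSON parameter sidecar + gene list.

    Column order is fixed: gene_id, candidate, n_high_cv_clusters, entropy,
    sensitive, then cluster_mean_0..cluster_mean_{N-1}.
    """
    path = Path(path)
    if not path.parent.is_dir():
        raise IOError(f"directory {path.parent} does not exist")
    mean_cols = [c for c in report.table.columns if c.startswith("cluster_mean_")]
    mean_cols.sort(key=lambda c: int(c.rsplit("_", 1)[1]))
    out = report.table.reset_index(names="gene_id")[REPORT_BASE_COLUMNS[:1] + REPORT_BASE_COLUMNS[1:] + mean_cols]
    out.to_csv(path, sep="\t", index=False, float_format="%.17g")
    params_path, genes_path = _sidecar_paths(path)
    with open(params_path, "w", encoding="utf-8") as fh:
        json.dump(report.params, fh, indent=2, sort_keys=True)
        fh.write("\n")
    write_gene_list(report.sensitive_genes, genes_path)


def read_report(path: str | Path) -> SensitiveGeneReport:
    path = Path(path)
    table = pd.read_csv(path, sep="\t", dtype={"gene_id": str}).set_index("gene_id")
    for col in ("candidate", "sensitive"):
        table[col] = table[col].astype(bool)
    params_path, _ = _sidecar_paths(path)
    params = json.loads(params_path.read_text(encoding="utf-8")) if params_path.exists() else {}
    return SensitiveGeneReport(table=table, params=params)
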