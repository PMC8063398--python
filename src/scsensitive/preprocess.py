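"""Quality control and depth normalization.

QC keeps cells with at least ``min_genes_per_cell`` detected genes and at most
``max_mito_fraction`` of their counts in mitochondrial genes (symbol prefix
match, case-insensitive).  Boundary semantics follow the removal rules
"< min_genes" and "> max_mito": a cell exactly at either threshold is kept.

Normalization is the LogNormalize convention: each cell's counts are divided
by the cell total, multiplied by a scale factor (default 10,000) and
ln(1 + x)-transformed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable

import numpy as np
import scipy.sparse as sp
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

from .containers import CountMatrix, NormalizedMatrix

__all__ = ["QCParams", "qc_filter", "normalize_log", "exclude_cells", "LogNormalizer"]

logger = logging.getLogger(__name__)

DEFAULT_SCALE_FACTOR = 10_000.0


@dataclass
class QCParams:
    min_genes_per_cell: int = 500
    max_mito_fraction: float | None = 0.20
    mito_prefix: str = "MT-"

    def __post_init__(self) -> None:
        if self.min_genes_per_cell < 0:
            raise ValueError("min_genes_per_cell must be >= 0")
        if self.max_mito_fraction is not None and not (0 <= self.max_mito_fraction <= 1):
            raise ValueError("max_mito_fraction must be in [0, 1] or None")


def _mito_mask(m: CountMatrix, prefix: str) -> np.ndarray:
    names = m.gene_symbols if m.gene_symbols is not None else m.gene_ids
    prefix = prefix.lower()
    return np.array([str(n).lower().startswith(prefix) for n in names], dtype=bool)


def qc_filter(m: CountMatrix, params: QCParams | None = None) -> CountMatrix:
    """Drop low-quality cells; genes and cell order are preserved.

    Cells with fewer than ``min_genes_per_cell`` detected genes, or with a
    mitochondrial count fraction strictly above ``max_mito_fraction``, are
    removed.  The mito test is skipped when ``max_mito_fraction`` is None
    (relaxed mode for shallow data sets).
    """
    params = params or QCParams()
    counts = m.counts
    detected = counts.getnnz(axis=1)
    keep = detected >= params.min_genes_per_cell
    if params.max_mito_fraction is not None:
        mito = _mito_mask(m, params.mito_prefix)
        total = np.asarray(counts.sum(axis=1)).ravel()
        mito_counts = np.asarray(counts[:, mito].sum(axis=1)).ravel() if mito.any() else np.zeros(m.n_cells)
        with np.errstate(invalid="ignore", divide="ignore"):
            frac = np.where(total > 0, mito_counts / np.maximum(total, 1), 0.0)
        keep &= frac <= params.max_mito_fraction
    if not keep.any():
        raise ValueError(
            f"QC removed every cell (min_genes_per_cell={params.min_genes_per_cell}, "
            f"max_mito_fraction={params.max_mito_fraction})"
        )
    logger.info("QC kept %d of %d cells", int(keep.sum()), m.n_cells)
    return m.subset_cells(keep)


def exclude_cells(m: CountMatrix, barcode_list: Iterable[str]) -> CountMatrix:
    """Remove the listed cells (e.g. an externally derived doublet list).

    Unknown barcodes are ignored with a logged warning count.
    """
    excl = set(map(str, barcode_list))
    if not excl:
        return m
    unknown = excl - set(m.cell_ids)
    if unknown:
        logger.warning("%d barcodes in the exclusion list are not in the matrix", len(unknown))
    keep = np.array([c not in excl for c in m.cell_ids], dtype=bool)
    if not keep.any():
        raise ValueError("exclusion list removed every cell")
    return m.subset_cells(keep)


def normalize_log(m: CountMatrix, scale_factor: float = DEFAULT_SCALE_FACTOR) -> NormalizedMatrix:
    """LogNormalize: value[c,g] = ln(1 + scale_factor * counts[c,g] / total[c])."""
    if scale_factor <= 0:
        raise ValueError("scale_factor must be positive")
    totals = np.asarray(m.counts.sum(axis=1)).ravel()
    if (totals == 0).any():
        n = int((totals == 0).sum())
        raise ValueError(f"{n} cells have zero total counts; run qc_filter first")
    x = sp.csr_matrix(m.counts, dtype=float, copy=True)
    # scale each row by scale_factor/total, then log1p the stored values only:
    # zeros map to zeros so the sparsity pattern is preserved exactly.
    row_scale = scale_factor / totals
    x.data *= np.repeat(row_scale, np.diff(x.indptr))
    np.log1p(x.data, out=x.data)
    return NormalizedMatrix(
        values=x, cell_ids=m.cell_ids, gene_ids=m.gene_ids, scale_factor=float(scale_factor)
    )


class LogNormalizer(TransformerMixin, BaseEstimator):
    """Scikit-learn transformer form of LogNormalize for raw arrays.

    Stateless apart from recording ``n_features_in_``; provided so depth
    normalization can sit inside an sklearn ``Pipeline``.
    """

    def __init__(self, scale_factor: float = DEFAULT_SCALE_FACTOR):
        self.scale_factor = scale_factor

    def fit(self, X, y=None):
        X = self._validate(X)
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X):
        check_is_fitted(self)
        X = self._validate(X)
        if X.shape[1] != self.n_features_in_:
            raise ValueError("feature count changed between fit and transform")
        totals = np.asarray(X.sum(axis=1)).ravel()
        if (totals == 0).any():
            raise ValueError("cells with zero total counts; filter them first")
        if sp.issparse(X):
            out = sp.csr_matrix(X, dtype=float, copy=True)
            out.data *= np.repeat(self.scale_factor / totals, np.diff(out.indptr))
            np.log1p(out.data, out=out.data)
            return out
        return np.log1p(self.scale_factor * X / totals[:, None])

    def _validate(self, X):
        if self.scale_factor <= 0:
            raise ValueError("scale_factor must be positive")
        if sp.issparse(X):
            return sp.csr_matrix(X)
        X = np.asarray(X, dtype=float)
        if X.ndim != 2:
            raise ValueError("X must be 2-dimensional")
        if (X < 0).any():
            raise ValueError("counts must be non-negative")
        return X
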