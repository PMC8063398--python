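"""Lightweight in-memory containers for count and expression matrices.

All matrices are oriented cells x genes.  Identifiers are kept alongside the
matrix so that every downstream result (HVG lists, sensitive-gene reports,
cluster labels) can be expressed in terms of stable gene/cell ids rather than
positional indices.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp

__all__ = [
    "CountMatrix",
    "NormalizedMatrix",
    "CellLabelTable",
    "ClusterLabels",
    "SensitiveGeneReport",
    "PerClusterCVRanks",
]


def _check_unique(ids: Sequence[str], what: str) -> None:
    if len(set(ids)) != len(ids):
        dup = pd.Index(ids)
        dup = sorted(dup[dup.duplicated()].unique())
        raise ValueError(f"duplicate {what}: {dup[:5]}{'...' if len(dup) > 5 else ''}")


def make_unique(ids: Sequence[str]) -> list[str]:
    """De-duplicate identifiers by appending '.1', '.2', ... in file order.

    The first occurrence keeps the bare name (R ``make.unique`` convention).
    """
    seen: dict[str, int] = {}
    out = []
    for name in ids:
        if name in seen:
            seen[name] += 1
            out.append(f"{name}.{seen[name]}")
        else:
            seen[name] = 0
            out.append(name)
    return out


@dataclass
class CountMatrix:
    """Sparse cells x genes matrix of non-negative integer counts."""

    counts: sp.csr_matrix
    cell_ids: list[str]
    gene_ids: list[str]
    gene_symbols: list[str] | None = None

    def __post_init__(self) -> None:
        self.counts = sp.csr_matrix(self.counts)
        self.cell_ids = list(map(str, self.cell_ids))
        self.gene_ids = list(map(str, self.gene_ids))
        if self.counts.shape != (len(self.cell_ids), len(self.gene_ids)):
            raise ValueError(
                f"counts shape {self.counts.shape} does not match "
                f"{len(self.cell_ids)} cells x {len(self.gene_ids)} genes"
            )
        _check_unique(self.cell_ids, "cell ids")
        _check_unique(self.gene_ids, "gene ids")
        if self.gene_symbols is not None and len(self.gene_symbols) != len(self.gene_ids):
            raise ValueError("gene_symbols length does not match gene_ids")
        data = self.counts.data
        if data.size:
            if data.min() < 0:
                raise ValueError("counts contain negative entries")
            if not np.allclose(data, np.round(data)):
                raise ValueError("counts contain non-integer entries")

    @property
    def n_cells(self) -> int:
        return self.counts.shape[0]

    @property
    def n_genes(self) -> int:
        return self.counts.shape[1]

    def subset_cells(self, mask: np.ndarray) -> "CountMatrix":
        idx = np.asarray(mask)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        return CountMatrix(
            counts=self.counts[idx],
            cell_ids=[self.cell_ids[i] for i in idx],
            gene_ids=self.gene_ids,
            gene_symbols=self.gene_symbols,
        )


@dataclass
class NormalizedMatrix:
    """Log-normalized expression: value = ln(1 + scale_factor * count / cell_total)."""

    values: sp.csr_matrix
    cell_ids: list[str]
    gene_ids: list[str]
    scale_factor: float = 10_000.0

    def __post_init__(self) -> None:
        self.values = sp.csr_matrix(self.values)
        self.cell_ids = list(map(str, self.cell_ids))
        self.gene_ids = list(map(str, self.gene_ids))
        if self.values.shape != (len(self.cell_ids), len(self.gene_ids)):
            raise ValueError("values shape does not match id lengths")
        if self.scale_factor <= 0:
            raise ValueError("scale_factor must be positive")
        if self.values.data.size and self.values.data.min() < 0:
            raise ValueError("normalized values must be non-negative")

    @property
    def n_cells(self) -> int:
        return self.values.shape[0]

    @property
    def n_genes(self) -> int:
        return self.values.shape[1]

    def gene_indexer(self, gene_ids: Sequence[str]) -> np.ndarray:
        lookup = {g: i for i, g in enumerate(self.gene_ids)}
        missing = [g for g in gene_ids if g not in lookup]
        if missing:
            raise KeyError(f"{len(missing)} gene ids not in matrix, e.g. {missing[:3]}")
        return np.array([lookup[g] for g in gene_ids], dtype=int)


@dataclass
class CellLabelTable:
    """Ground-truth (or any categorical) per-cell labels."""

    cell_ids: list[str]
    labels: list[str]

    def __post_init__(self) -> None:
        self.cell_ids = list(map(str, self.cell_ids))
        self.labels = list(map(str, self.labels))
        if len(self.cell_ids) != len(self.labels):
            raise ValueError("one label per cell id required")
        _check_unique(self.cell_ids, "cell ids")
        if any(lab in ("", "nan", "None") for lab in self.labels):
            raise ValueError("missing labels after loading")

    def as_series(self) -> pd.Series:
        return pd.Series(self.labels, index=self.cell_ids, name="label")


@dataclass
class ClusterLabels:
    """Cluster assignment from one clustering run.

    Labels are integers 0..n_clusters-1, relabeled by decreasing cluster size.
    """

    cell_ids: list[str]
    cluster_of: np.ndarray
    resolution: float
    algorithm: str = "louvain"
    seed: int = 0

    def __post_init__(self) -> None:
        self.cell_ids = list(map(str, self.cell_ids))
        self.cluster_of = np.asarray(self.cluster_of, dtype=int)
        if len(self.cell_ids) != self.cluster_of.size:
            raise ValueError("one cluster label per cell required")
        if self.cluster_of.size == 0:
            raise ValueError("empty clustering")
        uniq = np.unique(self.cluster_of)
        if uniq[0] != 0 or uniq[-1] != uniq.size - 1:
            raise ValueError("cluster labels must be consecutive integers from 0")
        if self.algorithm not in ("louvain", "leiden", "external"):
            raise ValueError(f"unknown algorithm {self.algorithm!r}")

    @property
    def n_clusters(self) -> int:
        return int(self.cluster_of.max()) + 1

    def as_series(self) -> pd.Series:
        return pd.Series(self.cluster_of, index=self.cell_ids, name="cluster")


@dataclass
class PerClusterCVRanks:
    """Per-cluster coefficient-of-variation ranks for every gene.

    ``rank`` holds 1-based descending-CV ranks (1 = most variable); genes with
    zero mean inside a cluster are ineligible there and carry rank 0.
    """

    gene_ids: list[str]
    rank: np.ndarray          # (n_genes, n_clusters) int, 0 = ineligible
    eligible: np.ndarray      # (n_genes, n_clusters) bool
    cv: np.ndarray            # (n_genes, n_clusters) float, NaN if ineligible
    top_k: int

    def __post_init__(self) -> None:
        self.rank = np.asarray(self.rank, dtype=int)
        self.eligible = np.asarray(self.eligible, dtype=bool)

    @property
    def n_clusters(self) -> int:
        return self.rank.shape[1]

    def high_cv(self) -> np.ndarray:
        """Boolean (n_genes, n_clusters): rank within the top_k of that cluster."""
        return self.eligible & (self.rank >= 1) & (self.rank <= self.top_k)

    def n_high_cv_clusters(self) -> np.ndarray:
        return self.high_cv().sum(axis=1)


@dataclass
class SensitiveGeneReport:
    """Per-gene scoring table plus the run parameters that produced it.

    ``table`` is indexed by gene id with columns: candidate (bool),
    n_high_cv_clusters (int), entropy (float), sensitive (bool) and one
    ``cluster_mean_<j>`` column per cluster.
    """

    table: pd.DataFrame
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        required = {"candidate", "n_high_cv_clusters", "entropy", "sensitive"}
        missing = required - set(self.table.columns)
        if missing:
            raise ValueError(f"report table missing columns {sorted(missing)}")
        bad = self.table["sensitive"] & ~self.table["candidate"]
        if bad.any():
            raise ValueError("sensitive genes must be candidates")

    @property
    def sensitive_genes(self) -> list[str]:
        return list(self.table.index[self.table["sensitive"]])

    @property
    def candidate_genes(self) -> list[str]:
        return list(self.table.index[self.table["candidate"]])

    @property
    def n_clusters(self) -> int:
        return int(self.params["n_clusters"])

    def cluster_means(self) -> pd.DataFrame:
        cols = [c for c in self.table.columns if c.startswith("cluster_mean_")]
        return self.table[cols]
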