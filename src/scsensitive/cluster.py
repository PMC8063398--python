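"""PCA embedding, kNN graph construction and modularity community detection.

The first-pass clustering follows the standard scRNA-seq recipe: select the
top-k genes by coefficient of variation (CV = sd/mean, unbiased sd), scale the
selected genes to zero mean / unit variance with clipping, embed with PCA,
build a k-nearest-neighbour graph on the embedding and run Louvain (default)
or Leiden community detection at a given resolution.  Cluster labels are
relabeled 0..N-1 by decreasing cluster size so reports are stable.
"""

from __future__ import annotations

import random
from dataclasses import dataclass
from typing import Sequence

import igraph as ig
import leidenalg
import numpy as np
import pandas as pd
import scipy.sparse as sp
from sklearn.base import BaseEstimator, ClusterMixin
from sklearn.decomposition import PCA
from sklearn.neighbors import NearestNeighbors

from .containers import ClusterLabels, NormalizedMatrix

__all__ = [
    "EmbeddingParams",
    "CVGeneSelector",
    "GraphClusterer",
    "gene_cv",
    "select_hvg",
    "run_clustering",
    "resolution_sweep",
    "DEFAULT_RESOLUTION_SWEEP",
    "FINE_RESOLUTION_SWEEP",
]

#: resolution series used for side-by-side ECA/ECP comparisons
DEFAULT_RESOLUTION_SWEEP: tuple[float, ...] = (0.6, 0.9, 1.0, 1.2, 1.5, 1.8, 2.0)
#: fine-grained series (0.5-2.5 in steps of 0.1)
FINE_RESOLUTION_SWEEP: tuple[float, ...] = tuple(round(0.5 + 0.1 * i, 1) for i in range(21))


@dataclass
class EmbeddingParams:
    n_hvg: int = 2000
    n_pcs: int = 50
    n_neighbors: int = 20
    scale_before_pca: bool = True

    def __post_init__(self) -> None:
        if self.n_pcs < 2:
            raise ValueError("n_pcs must be >= 2")
        if self.n_neighbors < 2:
            raise ValueError("n_neighbors must be >= 2")
        if self.n_hvg < self.n_pcs:
            raise ValueError("n_hvg must be >= n_pcs")


def gene_cv(values: sp.spmatrix | np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-gene mean and CV (unbiased sd / mean) over all rows.

    Genes with zero mean get CV = NaN (ineligible).
    """
    n = values.shape[0]
    if n < 2:
        raise ValueError("CV needs at least 2 cells")
    if sp.issparse(values):
        mean = np.asarray(values.mean(axis=0)).ravel()
        sq = np.asarray(values.multiply(values).mean(axis=0)).ravel()
    else:
        values = np.asarray(values, dtype=float)
        mean = values.mean(axis=0)
        sq = (values**2).mean(axis=0)
    var = np.maximum(sq - mean**2, 0.0) * (n / (n - 1))
    sd = np.sqrt(var)
    with np.errstate(invalid="ignore", divide="ignore"):
        cv = np.where(mean > 0, sd / np.where(mean > 0, mean, 1.0), np.nan)
    return mean, cv


def _rank_by_cv(gene_ids: Sequence[str], cv: np.ndarray) -> pd.DataFrame:
    """Rank eligible genes by descending CV, ties broken by gene id."""
    df = pd.DataFrame({"gene_id": list(gene_ids), "cv": cv})
    df = df[np.isfinite(df["cv"].values)]
    df = df.sort_values(["cv", "gene_id"], ascending=[False, True], kind="mergesort")
    df["rank"] = np.arange(1, len(df) + 1)
    return df


def select_hvg(
    norm: NormalizedMatrix, n_hvg: int = 2000, excluded: Sequence[str] = ()
) -> list[str]:
    """Top ``n_hvg`` gene ids by CV over all cells, in rank order.

    Genes with zero mean are ineligible; ``excluded`` genes (e.g. detected
    sensitive genes) are removed from eligibility before ranking.
    """
    _, cv = gene_cv(norm.values)
    ranked = _rank_by_cv(norm.gene_ids, cv)
    if excluded:
        ranked = ranked[~ranked["gene_id"].isin(set(excluded))]
    if len(ranked) < n_hvg:
        raise ValueError(
            f"only {len(ranked)} eligible genes available, {n_hvg} requested "
            f"(shortfall {n_hvg - len(ranked)})"
        )
    return ranked["gene_id"].head(n_hvg).tolist()


class CVGeneSelector(BaseEstimator):
    """Sklearn-style feature selector: keep the top ``n_genes`` columns by CV.

    Fitted attributes: ``support_`` (boolean column mask), ``ranking_``
    (1-based CV rank per column, 0 for ineligible columns).
    """

    def __init__(self, n_genes: int = 2000):
        self.n_genes = n_genes

    def fit(self, X, y=None):
        n_cols = X.shape[1]
        ids = [f"{i:09d}" for i in range(n_cols)]  # positional ids keep input order on ties
        _, cv = gene_cv(X)
        ranked = _rank_by_cv(ids, cv)
        if len(ranked) < self.n_genes:
            raise ValueError(
                f"only {len(ranked)} eligible columns, {self.n_genes} requested"
            )
        self.ranking_ = np.zeros(n_cols, dtype=int)
        self.ranking_[[int(g) for g in ranked["gene_id"]]] = ranked["rank"].to_numpy()
        self.support_ = (self.ranking_ >= 1) & (self.ranking_ <= self.n_genes)
        self.n_features_in_ = n_cols
        return self

    def transform(self, X):
        if X.shape[1] != self.n_features_in_:
            raise ValueError("feature count changed between fit and transform")
        return X[:, self.support_]

    def fit_transform(self, X, y=None):
        return self.fit(X, y).transform(X)

    def get_support(self) -> np.ndarray:
        return self.support_


def _scale_clip(X: np.ndarray, clip: float) -> np.ndarray:
    mean = X.mean(axis=0)
    sd = X.std(axis=0, ddof=1)
    sd[sd == 0] = 1.0
    Z = (X - mean) / sd
    return np.clip(Z, -clip, clip)


def _embed(X, params: EmbeddingParams, clip: float = 10.0) -> np.ndarray:
    X = np.asarray(X.todense() if sp.issparse(X) else X, dtype=float)
    if params.scale_before_pca:
        X = _scale_clip(X, clip)
    n_pcs = min(params.n_pcs, X.shape[0] - 1, X.shape[1])
    pca = PCA(n_components=n_pcs, svd_solver="full")
    return pca.fit_transform(X)


def _knn_graph(embedding: np.ndarray, n_neighbors: int) -> ig.Graph:
    n = embedding.shape[0]
    if n < n_neighbors + 1:
        raise ValueError(f"need at least n_neighbors+1={n_neighbors + 1} cells, got {n}")
    nn = NearestNeighbors(n_neighbors=n_neighbors + 1).fit(embedding)
    _, idx = nn.kneighbors(embedding)
    src = np.repeat(np.arange(n), n_neighbors)
    dst = idx[:, 1:].ravel()  # drop self-neighbour
    edges = {(min(a, b), max(a, b)) for a, b in zip(src.tolist(), dst.tolist()) if a != b}
    g = ig.Graph(n=n, edges=sorted(edges), directed=False)
    return g


def _community_labels(
    graph: ig.Graph, algorithm: str, resolution: float, seed: int
) -> np.ndarray:
    if resolution <= 0:
        raise ValueError("resolution must be > 0")
    if algorithm == "louvain":
        # python-igraph delegates randomness to Python's random module
        state = random.getstate()
        try:
            random.seed(seed)
            membership = graph.community_multilevel(resolution=resolution).membership
        finally:
            random.setstate(state)
    elif algorithm == "leiden":
        part = leidenalg.find_partition(
            graph,
            leidenalg.RBConfigurationVertexPartition,
            resolution_parameter=resolution,
            seed=int(seed),
            n_iterations=2,
        )
        membership = part.membership
    else:
        raise ValueError(f"unknown algorithm {algorithm!r} (expected louvain or leiden)")
    return _relabel_by_size(np.asarray(membership, dtype=int))


def _relabel_by_size(labels: np.ndarray) -> np.ndarray:
    uniq, counts = np.unique(labels, return_counts=True)
    order = sorted(range(len(uniq)), key=lambda i: (-counts[i], uniq[i]))
    mapping = {int(uniq[i]): new for new, i in enumerate(order)}
    return np.array([mapping[int(l)] for l in labels], dtype=int)


class GraphClusterer(ClusterMixin, BaseEstimator):
    """PCA + kNN-graph + Louvain/Leiden clustering as an sklearn estimator.

    ``fit(X)`` expects the already-normalized, feature-selected expression
    matrix (cells x genes).  Fitted attributes: ``labels_``, ``embedding_``,
    ``graph_``, ``n_clusters_``.
    """

    def __init__(
        self,
        n_pcs: int = 50,
        n_neighbors: int = 20,
        resolution: float = 0.6,
        algorithm: str = "louvain",
        scale_before_pca: bool = True,
        clip_value: float = 10.0,
        random_state: int = 0,
    ):
        self.n_pcs = n_pcs
        self.n_neighbors = n_neighbors
        self.resolution = resolution
        self.algorithm = algorithm
        self.scale_before_pca = scale_before_pca
        self.clip_value = clip_value
        self.random_state = random_state

    def fit(self, X, y=None):
        if X.shape[1] == 0:
            raise ValueError("empty feature set")
        params = EmbeddingParams(
            n_hvg=max(X.shape[1], self.n_pcs),
            n_pcs=self.n_pcs,
            n_neighbors=self.n_neighbors,
            scale_before_pca=self.scale_before_pca,
        )
        self.embedding_ = _embed(X, params, clip=self.clip_value)
        self.graph_ = _knn_graph(self.embedding_, self.n_neighbors)
        self.labels_ = _community_labels(
            self.graph_, self.algorithm, self.resolution, self.random_state
        )
        self.n_clusters_ = int(self.labels_.max()) + 1
        return self

    def fit_predict(self, X, y=None):
        return self.fit(X).labels_


def _subset(norm: NormalizedMatrix, genes: Sequence[str]):
    if len(genes) == 0:
        raise ValueError("empty gene list")
    return norm.values[:, norm.gene_indexer(genes)]


def run_clustering(
    norm: NormalizedMatrix,
    genes: Sequence[str],
    params: EmbeddingParams | None = None,
    resolution: float = 0.6,
    algorithm: str = "louvain",
    seed: int = 0,
) -> ClusterLabels:
    """Cluster cells on the given gene subset of a normalized matrix."""
    params = params or EmbeddingParams()
    est = GraphClusterer(
        n_pcs=params.n_pcs,
        n_neighbors=params.n_neighbors,
        resolution=resolution,
        algorithm=algorithm,
        scale_before_pca=params.scale_before_pca,
        random_state=seed,
    )
    est.fit(_subset(norm, genes))
    return ClusterLabels(
        cell_ids=norm.cell_ids,
        cluster_of=est.labels_,
        resolution=float(resolution),
        algorithm=algorithm,
        seed=int(seed),
    )


def resolution_sweep(
    norm: NormalizedMatrix,
    genes: Sequence[str],
    params: EmbeddingParams | None = None,
    resolutions: Sequence[float] = DEFAULT_RESOLUTION_SWEEP,
    algorithm: str = "louvain",
    seed: int = 0,
) -> list[ClusterLabels]:
    """Cluster at each resolution, reusing one embedding and kNN graph."""
    if len(resolutions) == 0:
        raise ValueError("resolutions must be non-empty")
    params = params or EmbeddingParams()
    emb = _embed(_subset(norm, genes), params)
    graph = _knn_graph(emb, params.n_neighbors)
    out = []
    for res in resolutions:
        labels = _community_labels(graph, algorithm, float(res), seed)
        out.append(
            ClusterLabels(
                cell_ids=norm.cell_ids,
                cluster_of=labels,
                resolution=float(res),
                algorithm=algorithm,
                seed=int(seed),
            )
        )
    return out
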