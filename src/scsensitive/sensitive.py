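"""Sensitive-gene detection: per-cluster CV ranks, candidate retention,
Shannon-entropy scoring and the median cutoff.

"Sensitive" genes are stochastically expressed, typically stress-responsive
genes that fluctuate within every cell type.  They leave two signatures that
this module scores:

1. high coefficient of variation (CV = sd/mean) inside clusters — a gene is a
   *candidate* when its within-cluster CV rank is in the top ``top_k`` in at
   least half of the first-pass clusters (>= ceil(N/2) by default);
2. near-equal average expression across clusters — quantified by the Shannon
   entropy of the gene's normalized cluster means,
   H(x) = -sum_i p_i log p_i with p_i = x_i / sum_j x_j,
   which is maximal (log N) for perfectly even expression and 0 for
   expression confined to one cluster.

A candidate whose entropy is strictly above the median entropy of the
candidate set is flagged sensitive.  Removing the flagged genes from the
highly-variable-gene pool and re-selecting features yields a cleaner basis
for re-clustering.
"""

from __future__ import annotations

import logging
import math
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

from .cluster import _rank_by_cv, gene_cv, select_hvg
from .containers import ClusterLabels, NormalizedMatrix, PerClusterCVRanks, SensitiveGeneReport

__all__ = [
    "per_cluster_cv_ranks",
    "retain_candidates",
    "shannon_entropy",
    "entropy_profile",
    "detect_sensitive_genes",
    "remove_and_reselect",
    "SensitiveGeneDetector",
]

logger = logging.getLogger(__name__)

DEFAULT_TOP_K = 2000


def _candidate_threshold(n_clusters: int, rule: str) -> int:
    """Minimum number of high-CV clusters for candidacy.

    ``ge_half``: count >= ceil(N/2) (the "at least half" reading);
    ``gt_half``: count > N/2 strictly.
    """
    if rule == "ge_half":
        return math.ceil(n_clusters / 2)
    if rule == "gt_half":
        return math.floor(n_clusters / 2) + 1
    raise ValueError(f"unknown candidate rule {rule!r} (expected ge_half or gt_half)")


def per_cluster_cv_ranks(
    norm: NormalizedMatrix, labels: ClusterLabels, top_k: int = DEFAULT_TOP_K
) -> PerClusterCVRanks:
    """CV-based rank list of every gene within each cluster.

    Within cluster j, eligible genes (mean > 0 over that cluster's cells) are
    ranked 1..#eligible by descending CV, ties broken by gene id.  The
    unbiased (n-1) standard deviation is used, so clusters need >= 2 cells;
    clusters with fewer than 3 cells trigger a warning.
    """
    if list(labels.cell_ids) != list(norm.cell_ids):
        a, b = set(labels.cell_ids), set(norm.cell_ids)
        raise ValueError(
            f"cluster labels do not align with the matrix cells "
            f"(symmetric difference of {len(a ^ b)} ids)"
        )
    if top_k < 1:
        raise ValueError("top_k must be >= 1")
    n_clusters = labels.n_clusters
    n_genes = norm.n_genes
    rank = np.zeros((n_genes, n_clusters), dtype=int)
    eligible = np.zeros((n_genes, n_clusters), dtype=bool)
    cv_mat = np.full((n_genes, n_clusters), np.nan)
    values = sp.csr_matrix(norm.values)
    for j in range(n_clusters):
        rows = np.flatnonzero(labels.cluster_of == j)
        if rows.size < 2:
            raise ValueError(f"cluster {j} has {rows.size} cell(s); CV is undefined")
        if rows.size < 3:
            logger.warning("cluster %d has only %d cells; CVs will be noisy", j, rows.size)
        mean, cv = gene_cv(values[rows])
        ok = np.isfinite(cv)
        eligible[:, j] = ok
        cv_mat[:, j] = cv
        ranked = _rank_by_cv(norm.gene_ids, cv)
        pos = {g: r for g, r in zip(ranked["gene_id"], ranked["rank"])}
        rank[:, j] = [pos.get(g, 0) for g in norm.gene_ids]
    return PerClusterCVRanks(
        gene_ids=list(norm.gene_ids), rank=rank, eligible=eligible, cv=cv_mat, top_k=int(top_k)
    )


def retain_candidates(
    ranks: PerClusterCVRanks, n_clusters: int | None = None, rule: str = "ge_half"
) -> list[str]:
    """Genes whose CV rank is within top_k in at least half of the clusters."""
    if n_clusters is None:
        n_clusters = ranks.n_clusters
    elif n_clusters != ranks.n_clusters:
        raise ValueError(
            f"ranks were computed over {ranks.n_clusters} clusters, not {n_clusters}"
        )
    thr = _candidate_threshold(n_clusters, rule)
    counts = ranks.n_high_cv_clusters()
    return [g for g, c in zip(ranks.gene_ids, counts) if c >= thr]


def shannon_entropy(cluster_means: Sequence[float], log_base: float = math.e) -> float:
    """Shannon index of a gene's cluster-mean expression profile.

    Means are normalized to proportions p_i = x_i / sum(x); the entropy
    -sum p_i log p_i is returned with 0 * log(0) treated as 0.
    """
    x = np.asarray(cluster_means, dtype=float)
    if x.ndim != 1 or x.size == 0:
        raise ValueError("cluster_means must be a non-empty 1-D sequence")
    if (x < 0).any():
        raise ValueError("cluster means must be non-negative")
    total = x.sum()
    if total == 0:
        raise ValueError("all cluster means are zero; entropy is undefined")
    p = x[x > 0] / total
    p = p[p > 0]  # guard against underflow of tiny means
    h = float(-(p * np.log(p)).sum())
    if log_base != math.e:
        h /= math.log(log_base)
    return max(h, 0.0)


def entropy_profile(cluster_means: np.ndarray, log_base: float = math.e) -> np.ndarray:
    """Vectorized Shannon entropy for a (genes x clusters) matrix of means.

    Rows that are entirely zero get NaN (undefined entropy).
    """
    x = np.asarray(cluster_means, dtype=float)
    totals = x.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = x / totals[:, None]
        terms = np.where(p > 0, p * np.log(p), 0.0)
    h = -terms.sum(axis=1)
    if log_base != math.e:
        h = h / math.log(log_base)
    h = np.where(totals > 0, np.maximum(h, 0.0), np.nan)
    return h


def _cluster_mean_matrix(values: sp.csr_matrix, cluster_of: np.ndarray, n_clusters: int) -> np.ndarray:
    """(genes x clusters) matrix of average expression per cluster."""
    out = np.empty((values.shape[1], n_clusters))
    for j in range(n_clusters):
        rows = np.flatnonzero(cluster_of == j)
        out[:, j] = np.asarray(values[rows].mean(axis=0)).ravel()
    return out


def detect_sensitive_genes(
    norm: NormalizedMatrix,
    labels: ClusterLabels,
    top_k: int = DEFAULT_TOP_K,
    candidate_rule: str = "ge_half",
    log_base: float = math.e,
    ranks: PerClusterCVRanks | None = None,
) -> SensitiveGeneReport:
    """Run the full detection: CV ranks -> candidates -> entropy -> median cutoff.

    Every gene with a positive total cluster mean is scored (entropy and
    high-CV cluster count), so gene-class comparisons can use non-candidates
    too.  The cutoff is the median entropy of the *candidate* set; a gene is
    sensitive iff it is a candidate and its entropy is strictly above that
    median.
    """
    if ranks is None:
        ranks = per_cluster_cv_ranks(norm, labels, top_k=top_k)
    elif ranks.top_k != top_k:
        raise ValueError("precomputed ranks carry a different top_k")
    n_clusters = labels.n_clusters
    n_high = ranks.n_high_cv_clusters()
    thr = _candidate_threshold(n_clusters, candidate_rule)
    candidate = n_high >= thr

    means = _cluster_mean_matrix(sp.csr_matrix(norm.values), labels.cluster_of, n_clusters)
    entropy = entropy_profile(means, log_base=log_base)
    scored = np.isfinite(entropy)
    n_dropped = int((~scored).sum())
    if n_dropped:
        logger.warning("%d genes with all-zero cluster means dropped from scoring", n_dropped)

    cand_entropies = entropy[candidate & scored]
    if cand_entropies.size == 0:
        logger.warning("no candidate genes retained; sensitive set is empty")
        cutoff = math.nan
        sensitive = np.zeros(norm.n_genes, dtype=bool)
    else:
        cutoff = float(np.median(cand_entropies))
        sensitive = candidate & scored & (entropy > cutoff)

    table = pd.DataFrame(
        {
            "candidate": candidate[scored],
            "n_high_cv_clusters": n_high[scored],
            "entropy": entropy[scored],
            "sensitive": sensitive[scored],
        },
        index=pd.Index(np.array(norm.gene_ids, dtype=object)[scored], name="gene_id"),
    )
    for j in range(n_clusters):
        table[f"cluster_mean_{j}"] = means[scored, j]
    params = {
        "n_clusters": int(n_clusters),
        "top_k": int(top_k),
        "candidate_rule": candidate_rule,
        "cutoff": "median",
        "log_base": "e" if log_base == math.e else log_base,
        "entropy_cutoff": None if math.isnan(cutoff) else cutoff,
        "n_scored": int(scored.sum()),
        "n_candidates": int(candidate.sum()),
        "n_sensitive": int(sensitive.sum()),
        "resolution": float(labels.resolution),
        "clustering_algorithm": labels.algorithm,
        "clustering_seed": int(labels.seed),
    }
    return SensitiveGeneReport(table=table, params=params)


def remove_and_reselect(
    norm: NormalizedMatrix, report: SensitiveGeneReport, n_hvg: int = 2000
) -> list[str]:
    """Re-select the global top-``n_hvg`` HVGs with sensitive genes excluded."""
    return select_hvg(norm, n_hvg=n_hvg, excluded=report.sensitive_genes)


class SensitiveGeneDetector(TransformerMixin, BaseEstimator):
    """Sklearn-style estimator for sensitive-gene detection and removal.

    ``fit(X, y)`` takes log-normalized expression (cells x genes; array,
    sparse matrix or DataFrame — DataFrame column names become gene ids) and
    per-cell cluster labels ``y`` from the first-pass clustering.
    ``transform(X)`` drops the detected sensitive genes' columns.

    Parameters
    ----------
    top_k : within-cluster CV-rank threshold for "high CV" (default 2000,
        mirroring the global HVG count on ~20k-gene data; scale it down for
        small panels).
    candidate_rule : 'ge_half' (>= ceil(N/2) clusters, default) or 'gt_half'.
    log_base : base of the entropy logarithm; the flagged set is invariant to
        it, only the reported entropies change scale.

    Attributes
    ----------
    report_ : SensitiveGeneReport with per-gene scores.
    sensitive_genes_ : list of flagged gene ids.
    support_ : boolean mask of columns kept by ``transform``.
    entropy_cutoff_ : the candidate-median entropy used as the cutoff.
    """

    def __init__(
        self,
        top_k: int = DEFAULT_TOP_K,
        candidate_rule: str = "ge_half",
        log_base: float = math.e,
    ):
        self.top_k = top_k
        self.candidate_rule = candidate_rule
        self.log_base = log_base

    def fit(self, X, y):
        X, gene_ids, cell_ids = self._coerce(X)
        y = np.asarray(y)
        if y.shape[0] != X.shape[0]:
            raise ValueError("y must supply one cluster label per cell")
        codes, _ = pd.factorize(y, sort=True)
        norm = NormalizedMatrix(values=X, cell_ids=cell_ids, gene_ids=gene_ids)
        labels = ClusterLabels(
            cell_ids=cell_ids, cluster_of=codes, resolution=0.0, algorithm="external"
        )
        self.report_ = detect_sensitive_genes(
            norm,
            labels,
            top_k=self.top_k,
            candidate_rule=self.candidate_rule,
            log_base=self.log_base,
        )
        self.gene_ids_ = gene_ids
        self.sensitive_genes_ = self.report_.sensitive_genes
        flagged = set(self.sensitive_genes_)
        self.support_ = np.array([g not in flagged for g in gene_ids], dtype=bool)
        self.entropy_cutoff_ = self.report_.params["entropy_cutoff"]
        self.n_clusters_ = self.report_.n_clusters
        self.n_features_in_ = len(gene_ids)
        return self

    def transform(self, X):
        check_is_fitted(self)
        X, _, _ = self._coerce(X, fitted=True)
        if X.shape[1] != self.n_features_in_:
            raise ValueError("feature count changed between fit and transform")
        return X[:, self.support_]

    def get_feature_names_out(self, input_features=None):
        check_is_fitted(self)
        return np.asarray([g for g, keep in zip(self.gene_ids_, self.support_) if keep])

    def _coerce(self, X, fitted: bool = False):
        if isinstance(X, pd.DataFrame):
            gene_ids = [str(c) for c in X.columns]
            cell_ids = [str(i) for i in X.index]
            mat = sp.csr_matrix(X.values.astype(float))
        else:
            mat = sp.csr_matrix(X, dtype=float)
            width = len(str(mat.shape[1]))
            gene_ids = [f"gene{i:0{width}d}" for i in range(mat.shape[1])]
            cell_ids = [f"cell{i}" for i in range(mat.shape[0])]
        if fitted:
            return mat, self.gene_ids_, cell_ids
        return mat, gene_ids, cell_ids
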