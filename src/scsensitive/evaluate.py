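"""Clustering evaluation (ECA/ECP), cross-sample overlap statistics, marker
calling and the three-way gene-class comparison.

ECA (entropy of cluster accuracy) is the cluster-size-weighted mean Shannon
entropy of the ground-truth label composition inside each predicted cluster:
0 means every cluster is pure.  ECP (entropy of cluster purity) is the
symmetric quantity with predicted clusters and truth groups exchanged: 0
means no truth group is split across clusters.  Good clusterings are low in
both; over-clustering lowers ECA while raising ECP and vice versa.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy import stats

from .containers import CellLabelTable, ClusterLabels, NormalizedMatrix, SensitiveGeneReport

__all__ = [
    "ClusteringScore",
    "GeneClassSummary",
    "eca",
    "ecp",
    "score_clustering",
    "overlap_proportion",
    "call_marker_genes",
    "rank_marker_genes",
    "compare_gene_classes",
    "misidentification_rate",
]

logger = logging.getLogger(__name__)


@dataclass
class ClusteringScore:
    eca: float
    ecp: float
    n_clusters: int
    resolution: float
    condition: str = "with_sensitive"


def _align(pred: ClusterLabels, truth: CellLabelTable) -> tuple[np.ndarray, np.ndarray]:
    pred_ids, truth_ids = set(pred.cell_ids), set(truth.cell_ids)
    if pred_ids != truth_ids:
        raise ValueError(
            f"cell ids differ between prediction and truth "
            f"(symmetric difference of {len(pred_ids ^ truth_ids)} ids)"
        )
    truth_series = truth.as_series().loc[pred.cell_ids]
    return np.asarray(pred.cluster_of), truth_series.to_numpy()


def _cross_entropy_score(
    groups: np.ndarray, composition: np.ndarray, weighting: str = "size_weighted"
) -> float:
    """Mean Shannon entropy (natural log) of ``composition`` within each group."""
    if weighting not in ("size_weighted", "unweighted"):
        raise ValueError(f"unknown weighting {weighting!r}")
    tab = pd.crosstab(pd.Series(groups), pd.Series(composition)).to_numpy(dtype=float)
    totals = tab.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = tab / totals[:, None]
        terms = np.where(p > 0, p * np.log(p), 0.0)
    ent = -terms.sum(axis=1)
    if weighting == "size_weighted":
        return float((ent * totals).sum() / totals.sum())
    return float(ent.mean())


def eca(pred: ClusterLabels, truth: CellLabelTable, weighting: str = "size_weighted") -> float:
    """Entropy of cluster accuracy: truth-label diversity within predicted clusters."""
    p, t = _align(pred, truth)
    return _cross_entropy_score(p, t, weighting)


def ecp(pred: ClusterLabels, truth: CellLabelTable, weighting: str = "size_weighted") -> float:
    """Entropy of cluster purity: predicted-cluster diversity within truth groups."""
    p, t = _align(pred, truth)
    return _cross_entropy_score(t, p, weighting)


def score_clustering(
    pred: ClusterLabels, truth: CellLabelTable, condition: str = "with_sensitive",
    weighting: str = "size_weighted",
) -> ClusteringScore:
    return ClusteringScore(
        eca=eca(pred, truth, weighting),
        ecp=ecp(pred, truth, weighting),
        n_clusters=pred.n_clusters,
        resolution=pred.resolution,
        condition=condition,
    )


def overlap_proportion(
    gene_sets: Sequence[Iterable[str]], thresholds: Sequence[float] = (0.50, 0.75, 1.00)
) -> dict[float, float]:
    """Fraction of the union present in at least t*S of the S sets, per threshold t."""
    sets = [set(s) for s in gene_sets]
    if len(sets) < 2:
        raise ValueError("need at least 2 gene sets")
    union: set[str] = set().union(*sets)
    if not union:
        raise ValueError("union of gene sets is empty")
    counts = pd.Series([sum(g in s for s in sets) for g in union], index=sorted(union))
    n_sets = len(sets)
    out = {}
    for t in thresholds:
        need = t * n_sets - 1e-9  # ">= t of the samples" with float tolerance
        out[float(t)] = float((counts >= need).sum() / len(union))
    return out


def rank_marker_genes(
    norm: NormalizedMatrix, labels: ClusterLabels, min_cells: int = 3
) -> pd.DataFrame:
    """One-vs-rest Wilcoxon rank-sum differential expression per cluster.

    Returns a long table (cluster, gene_id, p_value, p_adj_bh, log_fc, rank)
    where log_fc is the difference of mean log-normalized expression
    (in-cluster minus rest) and rank orders genes by ascending one-sided
    p-value (upregulated in the cluster), ties by descending log_fc then
    gene id.
    """
    if list(labels.cell_ids) != list(norm.cell_ids):
        raise ValueError("cluster labels do not align with the matrix cells")
    if labels.n_clusters < 2:
        raise ValueError("marker calling needs at least 2 clusters")
    X = np.asarray(sp.csr_matrix(norm.values).todense())
    rows = []
    for j in range(labels.n_clusters):
        mask = labels.cluster_of == j
        if mask.sum() < min_cells:
            logger.warning("cluster %d has < %d cells; skipped in marker calling", j, min_cells)
            continue
        x_in, x_out = X[mask], X[~mask]
        res = stats.mannwhitneyu(x_in, x_out, alternative="greater", axis=0)
        pvals = np.asarray(res.pvalue)
        padj = stats.false_discovery_control(pvals, method="bh")
        log_fc = x_in.mean(axis=0) - x_out.mean(axis=0)
        df = pd.DataFrame(
            {
                "cluster": j,
                "gene_id": norm.gene_ids,
                "p_value": pvals,
                "p_adj_bh": padj,
                "log_fc": log_fc,
            }
        )
        df = df.sort_values(
            ["p_value", "log_fc", "gene_id"], ascending=[True, False, True], kind="mergesort"
        )
        df["rank"] = np.arange(1, len(df) + 1)
        rows.append(df)
    if not rows:
        raise ValueError("no cluster large enough for marker calling")
    return pd.concat(rows, ignore_index=True)


def call_marker_genes(
    norm: NormalizedMatrix,
    labels: ClusterLabels,
    n_per_cluster: int = 10,
    per_cluster: bool = False,
):
    """Top differentially expressed genes per cluster, union-deduplicated.

    With ``per_cluster=True`` returns a dict cluster -> ordered gene list
    instead of the flat deduplicated union.
    """
    if n_per_cluster < 0:
        raise ValueError("n_per_cluster must be >= 0")
    if n_per_cluster == 0:
        return {} if per_cluster else []
    table = rank_marker_genes(norm, labels)
    top = table[table["rank"] <= n_per_cluster]
    if per_cluster:
        return {int(j): grp["gene_id"].tolist() for j, grp in top.groupby("cluster")}
    seen: dict[str, None] = {}
    for g in top.sort_values(["cluster", "rank"])["gene_id"]:
        seen.setdefault(g, None)
    return list(seen)


@dataclass
class GeneClassSummary:
    """Entropy and high-CV-cluster-count distributions for gene classes,
    with pairwise Kruskal-Wallis p-values."""

    entropies: dict[str, np.ndarray]
    n_high_cv_clusters: dict[str, np.ndarray]
    pvalues: dict[tuple[str, str], dict[str, float]] = field(default_factory=dict)


def _extract_class(
    report: SensitiveGeneReport, genes: Iterable[str], name: str
) -> pd.DataFrame:
    genes = list(dict.fromkeys(map(str, genes)))
    present = [g for g in genes if g in report.table.index]
    dropped = len(genes) - len(present)
    if dropped:
        logger.warning("%d %s genes absent from the report were dropped", dropped, name)
    if not present:
        raise ValueError(f"no {name} genes present in the scored matrix")
    if len(present) == 1:
        logger.warning("%s class has a single gene; tests will be underpowered", name)
    return report.table.loc[present]


def compare_gene_classes(
    report: SensitiveGeneReport,
    marker_genes: Iterable[str],
    hk_genes: Iterable[str],
) -> GeneClassSummary:
    """Compare sensitive vs marker vs housekeeping genes on entropy and the
    number of high-CV clusters, with pairwise Kruskal-Wallis tests."""
    classes = {
        "sensitive": report.table.loc[report.table["sensitive"]],
        "marker": _extract_class(report, marker_genes, "marker"),
        "housekeeping": _extract_class(report, hk_genes, "housekeeping"),
    }
    if classes["sensitive"].empty:
        raise ValueError("report contains no sensitive genes to compare")
    entropies = {k: v["entropy"].to_numpy() for k, v in classes.items()}
    n_high = {k: v["n_high_cv_clusters"].to_numpy() for k, v in classes.items()}
    pvalues: dict[tuple[str, str], dict[str, float]] = {}
    for other in ("marker", "housekeeping"):
        pair = ("sensitive", other)
        pvalues[pair] = {}
        for measure, data in (("entropy", entropies), ("n_high_cv_clusters", n_high)):
            try:
                stat = stats.kruskal(data["sensitive"], data[other])
                pvalues[pair][measure] = float(stat.pvalue)
            except ValueError:  # all values identical in both groups
                pvalues[pair][measure] = 1.0
    return GeneClassSummary(entropies=entropies, n_high_cv_clusters=n_high, pvalues=pvalues)


def misidentification_rate(report: SensitiveGeneReport, hk_genes: Iterable[str]) -> float:
    """Fraction of the housekeeping genes present in the matrix that were
    (wrongly) flagged sensitive."""
    hk = list(dict.fromkeys(map(str, hk_genes)))
    present = [g for g in hk if g in report.table.index]
    if not present:
        raise ValueError("none of the housekeeping genes are present in the scored matrix")
    flagged = int(report.table.loc[present, "sensitive"].sum())
    return flagged / len(present)
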