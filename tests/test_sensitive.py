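"""The core detection algorithm: per-cluster CV ranks, candidate retention,
Shannon entropy and the median cutoff."""

import math

import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp
from hypothesis import given, settings, strategies as st
from sklearn.base import clone

from scsensitive import (
    ClusterLabels,
    NormalizedMatrix,
    SensitiveGeneDetector,
    detect_sensitive_genes,
    per_cluster_cv_ranks,
    remove_and_reselect,
    retain_candidates,
    select_hvg,
    shannon_entropy,
)
from scsensitive.containers import PerClusterCVRanks


def _norm(values, gene_ids=None):
    values = np.asarray(values, dtype=float)
    n_cells, n_genes = values.shape
    return NormalizedMatrix(
        values=sp.csr_matrix(values),
        cell_ids=[f"c{i}" for i in range(n_cells)],
        gene_ids=gene_ids or [f"g{i}" for i in range(n_genes)],
    )


def _labels(assignment):
    return ClusterLabels(
        cell_ids=[f"c{i}" for i in range(len(assignment))],
        cluster_of=np.asarray(assignment),
        resolution=0.6,
        algorithm="external",
    )


# ---------------------------------------------------------------- CV ranks

def test_per_cluster_cv_ranks_brute_force_oracle():
    """Ranks in a 2-cluster, 6-gene toy equal a naive per-cluster computation."""
    rng = np.random.default_rng(42)
    values = rng.gamma(1.0, 1.0, size=(10, 6)) * (rng.random((10, 6)) > 0.3)
    norm = _norm(values)
    labels = _labels([0] * 5 + [1] * 5)
    ranks = per_cluster_cv_ranks(norm, labels, top_k=3)
    for j in range(2):
        sub = values[labels.cluster_of == j]
        scored = []
        for gi, g in enumerate(norm.gene_ids):
            col = sub[:, gi]
            if col.mean() > 0:
                scored.append((-(col.std(ddof=1) / col.mean()), g))
        order = [g for _, g in sorted(scored)]
        for expected_rank, g in enumerate(order, start=1):
            gi = norm.gene_ids.index(g)
            assert ranks.rank[gi, j] == expected_rank


def test_per_cluster_zero_gene_ineligible():
    values = np.array([[0.0, 1.0], [0.0, 2.0], [3.0, 1.0], [4.0, 3.0]])
    norm = _norm(values)
    ranks = per_cluster_cv_ranks(norm, _labels([0, 0, 1, 1]), top_k=10)
    assert not ranks.eligible[0, 0]
    assert ranks.rank[0, 0] == 0
    assert not ranks.high_cv()[0, 0]
    assert ranks.eligible[0, 1]


def test_per_cluster_top_k_saturation():
    """top_k >= #eligible genes makes every eligible gene high-CV."""
    rng = np.random.default_rng(1)
    norm = _norm(rng.gamma(1.0, 1.0, size=(8, 5)))
    ranks = per_cluster_cv_ranks(norm, _labels([0] * 4 + [1] * 4), top_k=999)
    assert ranks.high_cv().all()


def test_per_cluster_errors():
    norm = _norm(np.ones((3, 2)))
    with pytest.raises(ValueError, match="1 cell"):
        per_cluster_cv_ranks(norm, _labels([0, 0, 1]), top_k=5)
    other = ClusterLabels(
        cell_ids=["x0", "x1", "x2"], cluster_of=np.array([0, 0, 1]),
        resolution=0.6, algorithm="external",
    )
    with pytest.raises(ValueError, match="align"):
        per_cluster_cv_ranks(norm, other, top_k=5)


# ---------------------------------------------------------------- retention

def _ranks_with_counts(counts_per_gene, n_clusters, top_k=1):
    """Build a PerClusterCVRanks where gene i is high-CV in counts_per_gene[i] clusters."""
    n_genes = len(counts_per_gene)
    rank = np.full((n_genes, n_clusters), top_k + 1, dtype=int)
    for i, c in enumerate(counts_per_gene):
        rank[i, :c] = 1
    return PerClusterCVRanks(
        gene_ids=[f"g{i}" for i in range(n_genes)],
        rank=rank,
        eligible=np.ones((n_genes, n_clusters), dtype=bool),
        cv=np.ones((n_genes, n_clusters)),
        top_k=top_k,
    )


@pytest.mark.parametrize(
    "n_clusters,count,rule,expected",
    [
        (4, 2, "ge_half", True),    # >= ceil(4/2)=2
        (4, 1, "ge_half", False),
        (5, 2, "ge_half", False),   # needs ceil(5/2)=3
        (5, 3, "ge_half", True),
        (4, 2, "gt_half", False),   # strict > 2
        (4, 3, "gt_half", True),
        (1, 1, "ge_half", True),    # degenerate single cluster
    ],
)
def test_retain_candidates_rules(n_clusters, count, rule, expected):
    ranks = _ranks_with_counts([count], n_clusters)
    got = retain_candidates(ranks, rule=rule)
    assert (got == ["g0"]) is expected


def test_retain_candidates_cluster_count_check():
    ranks = _ranks_with_counts([1], 4)
    with pytest.raises(ValueError, match="4 clusters"):
        retain_candidates(ranks, n_clusters=5)


# ---------------------------------------------------------------- entropy

def test_shannon_entropy_examples():
    assert shannon_entropy([7.3, 0, 0, 0]) == 0.0
    assert shannon_entropy([2.5] * 4) == pytest.approx(math.log(4), abs=1e-12)
    assert shannon_entropy([2, 1, 1], log_base=2) == pytest.approx(1.5, abs=1e-12)
    assert shannon_entropy([2, 1, 1]) == pytest.approx(1.0397, abs=1e-4)
    with pytest.raises(ValueError, match="undefined"):
        shannon_entropy([0.0, 0.0])
    with pytest.raises(ValueError, match="non-negative"):
        shannon_entropy([1.0, -0.1])


@settings(max_examples=200, deadline=None, derandomize=True)
@given(
    means=st.lists(st.floats(min_value=0, max_value=1e6), min_size=1, max_size=12).filter(
        lambda x: sum(x) > 0
    )
)
def test_shannon_entropy_bounds(means):
    h = shannon_entropy(means)
    assert 0.0 <= h <= math.log(len(means)) + 1e-9


# ---------------------------------------------------------------- detection

def test_median_cutoff_is_strict():
    """All candidates sharing one entropy value -> zero sensitive genes."""
    # two clusters, all genes uniform across cells -> identical cluster means
    values = np.ones((6, 4))
    norm = _norm(values)
    report = detect_sensitive_genes(norm, _labels([0, 0, 0, 1, 1, 1]), top_k=10)
    assert report.table["candidate"].all()
    assert not report.table["sensitive"].any()


def test_detection_median_split_counts():
    """With distinct candidate entropies, strict > flags at most floor(M/2)."""
    rng = np.random.default_rng(5)
    values = rng.gamma(1.0, 1.0, size=(40, 30)) * (rng.random((40, 30)) > 0.5)
    norm = _norm(values)
    report = detect_sensitive_genes(norm, _labels([0] * 20 + [1] * 20), top_k=30)
    m = int(report.table["candidate"].sum())
    assert int(report.table["sensitive"].sum()) <= m // 2


def test_detection_log_base_invariance(small_run):
    """The flagged set is identical under natural log and log base 2."""
    norm, labels = small_run["norm"], small_run["labels"]
    rep_e = small_run["report"]
    rep_2 = detect_sensitive_genes(norm, labels, top_k=60, log_base=2.0)
    assert rep_e.sensitive_genes == rep_2.sensitive_genes
    assert np.allclose(rep_2.table["entropy"] * math.log(2), rep_e.table["entropy"])


def test_detection_entropy_bounds_and_invariants(small_run):
    report = small_run["report"]
    n = report.n_clusters
    assert (report.table["entropy"] >= -1e-12).all()
    assert (report.table["entropy"] <= math.log(n) + 1e-9).all()
    assert (report.table.loc[report.table["sensitive"], "candidate"]).all()
    means = report.cluster_means().to_numpy()
    p = means / means.sum(axis=1, keepdims=True)
    assert np.allclose(p.sum(axis=1), 1.0, atol=1e-9)


def test_detection_planted_recovery(default_runs):
    """Planted sensitive genes are recovered on the default world, 5 seeds."""
    recalls, precisions = [], []
    for run in default_runs:
        planted = set(run["truth"].sensitive_genes)
        flagged = set(run["report"].sensitive_genes)
        tp = len(planted & flagged)
        recalls.append(tp / len(planted))
        precisions.append(tp / max(len(flagged), 1))
    assert np.median(recalls) >= 0.8
    assert np.median(precisions) >= 0.6


def test_gene_class_signatures(default_run):
    """Housekeeping genes are never candidates; planted markers that are
    candidates score below the sensitive genes in entropy."""
    report, truth = default_run["report"], default_run["truth"]
    tab = report.table
    hk = [g for g in truth.housekeeping_genes if g in tab.index]
    assert tab.loc[hk, "candidate"].mean() <= 0.05
    assert tab.loc[hk, "entropy"].median() >= 0.9 * math.log(report.n_clusters)
    markers = [g for g in truth.marker_genes if g in tab.index]
    sens = report.sensitive_genes
    assert tab.loc[markers, "entropy"].median() < tab.loc[sens, "entropy"].median()


# ---------------------------------------------------------------- removal

def test_remove_and_reselect_identity_and_oracle(small_run):
    norm, report = small_run["norm"], small_run["report"]
    n_hvg = 100
    baseline = select_hvg(norm, n_hvg)

    empty = type(report)(table=report.table.assign(sensitive=False), params=dict(report.params))
    assert remove_and_reselect(norm, empty, n_hvg=n_hvg) == baseline

    # flag exactly the current top HVG: the re-selected list excludes it and
    # pulls in the former rank-(n_hvg+1) gene.
    top_gene = baseline[0]
    flag = report.table.index == top_gene
    one = type(report)(
        table=report.table.assign(sensitive=flag, candidate=report.table["candidate"] | flag),
        params=dict(report.params),
    )
    reselected = remove_and_reselect(norm, one, n_hvg=n_hvg)
    full_ranking = select_hvg(norm, norm.n_genes - int((np.asarray(
        norm.values.sum(axis=0)).ravel() == 0).sum()))
    expected = [g for g in full_ranking if g != top_gene][:n_hvg]
    assert reselected == expected
    assert top_gene not in reselected

    # flag the whole current top list: the next n_hvg genes take over
    flag_all = report.table.index.isin(baseline)
    allrep = type(report)(
        table=report.table.assign(
            sensitive=flag_all, candidate=report.table["candidate"] | flag_all
        ),
        params=dict(report.params),
    )
    assert remove_and_reselect(norm, allrep, n_hvg=n_hvg) == [
        g for g in full_ranking if g not in set(baseline)
    ][:n_hvg]


def test_remove_and_reselect_shortfall(small_run):
    norm, report = small_run["norm"], small_run["report"]
    with pytest.raises(ValueError, match="shortfall"):
        remove_and_reselect(norm, report, n_hvg=norm.n_genes)


# ---------------------------------------------------------------- estimator

def test_detector_estimator_api(small_run):
    norm, labels = small_run["norm"], small_run["labels"]
    X = pd.DataFrame(
        norm.values.toarray(), index=norm.cell_ids, columns=norm.gene_ids
    )
    est = SensitiveGeneDetector(top_k=60)
    out = est.fit_transform(X, labels.cluster_of)
    assert est.sensitive_genes_ == small_run["report"].sensitive_genes
    assert out.shape == (norm.n_cells, norm.n_genes - len(est.sensitive_genes_))
    names = est.get_feature_names_out()
    assert len(names) == out.shape[1]
    assert not set(est.sensitive_genes_) & set(names)
    assert clone(est).get_params() == est.get_params()


def test_detector_rejects_misaligned_labels(small_run):
    norm = small_run["norm"]
    est = SensitiveGeneDetector()
    with pytest.raises(ValueError, match="one cluster label per cell"):
        est.fit(norm.values, np.zeros(3))
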