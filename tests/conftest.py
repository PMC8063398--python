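"""Shared fixtures: simulated data sets at two scales and full pipeline runs.

Fixture-scale feature parameters are the paper-scale defaults (top-2000 of
~20k genes, i.e. ~13%) scaled proportionally to the 1500-gene fixture:
top_k=200, n_hvg=500.
"""

from __future__ import annotations

import numpy as np
import pytest
import scipy.sparse as sp

from scsensitive import (
    CellLabelTable,
    ClusterLabels,
    EmbeddingParams,
    NormalizedMatrix,
    SimulationParams,
    detect_sensitive_genes,
    normalize_log,
    remove_and_reselect,
    run_clustering,
    select_hvg,
    simulate_counts,
)

FIXTURE_N_HVG = 500
FIXTURE_TOP_K = 200
FIXTURE_EMBED = EmbeddingParams(n_hvg=FIXTURE_N_HVG, n_pcs=50, n_neighbors=20)

SMALL_N_HVG = 150
SMALL_TOP_K = 60
SMALL_EMBED = EmbeddingParams(n_hvg=SMALL_N_HVG, n_pcs=30, n_neighbors=15)


def small_params(seed: int = 0, **overrides) -> SimulationParams:
    """An 800-cell, 400-gene, 3-type world for fast unit tests."""
    kwargs = dict(
        n_cells=800,
        n_types=3,
        n_genes=400,
        n_markers_per_type=15,
        n_housekeeping=20,
        n_sensitive=40,
        seed=seed,
    )
    kwargs.update(overrides)
    return SimulationParams(**kwargs)


def run_detection(params: SimulationParams, n_hvg: int, top_k: int, embed: EmbeddingParams):
    """Simulate -> normalize -> HVG -> first clustering -> detection."""
    counts, truth = simulate_counts(params)
    norm = normalize_log(counts)
    hvg = select_hvg(norm, n_hvg)
    labels = run_clustering(norm, hvg, embed, resolution=0.6, seed=params.seed)
    report = detect_sensitive_genes(norm, labels, top_k=top_k)
    return {
        "counts": counts,
        "truth": truth,
        "norm": norm,
        "hvg": hvg,
        "labels": labels,
        "report": report,
    }


@pytest.fixture(scope="session")
def default_run():
    """One full default-fixture detection run (2000 cells, 5 types, seed 0)."""
    return run_detection(SimulationParams(seed=0), FIXTURE_N_HVG, FIXTURE_TOP_K, FIXTURE_EMBED)


@pytest.fixture(scope="session")
def default_runs():
    """Detection runs on the default fixture for seeds 0..4."""
    return [
        run_detection(SimulationParams(seed=s), FIXTURE_N_HVG, FIXTURE_TOP_K, FIXTURE_EMBED)
        for s in range(5)
    ]


@pytest.fixture(scope="session")
def small_run():
    """Full detection run on the small fast world (seed 0)."""
    return run_detection(small_params(0), SMALL_N_HVG, SMALL_TOP_K, SMALL_EMBED)


@pytest.fixture(scope="session")
def two_blob():
    """Two well-separated cell populations, for clustering contracts."""
    params = SimulationParams(
        n_cells=1000,
        n_types=2,
        n_genes=150,
        n_markers_per_type=25,
        n_housekeeping=10,
        n_sensitive=0,
        marker_fold=12.0,
        seed=7,
    )
    counts, truth = simulate_counts(params)
    norm = normalize_log(counts)
    return norm, truth


@pytest.fixture()
def tiny_norm():
    """A handcrafted 4-cell x 5-gene normalized matrix with 2 clusters."""
    values = np.array(
        [
            [1.0, 0.0, 2.0, 0.5, 1.0],
            [2.0, 0.0, 1.0, 0.5, 1.0],
            [0.0, 3.0, 0.5, 2.0, 1.0],
            [0.0, 1.0, 1.5, 2.0, 1.0],
        ]
    )
    norm = NormalizedMatrix(
        values=sp.csr_matrix(values),
        cell_ids=[f"c{i}" for i in range(4)],
        gene_ids=[f"g{i}" for i in range(5)],
    )
    labels = ClusterLabels(
        cell_ids=norm.cell_ids,
        cluster_of=np.array([0, 0, 1, 1]),
        resolution=0.6,
        algorithm="external",
    )
    return norm, labels


def make_labels(assignment, prefix: str = "c") -> ClusterLabels:
    return ClusterLabels(
        cell_ids=[f"{prefix}{i}" for i in range(len(assignment))],
        cluster_of=np.asarray(assignment),
        resolution=0.6,
        algorithm="external",
    )


def make_truth(labels, prefix: str = "c") -> CellLabelTable:
    return CellLabelTable(
        cell_ids=[f"{prefix}{i}" for i in range(len(labels))],
        labels=[str(l) for l in labels],
    )
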