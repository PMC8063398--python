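"""Synthetic scRNA-seq counts with planted gene roles.

The generator emulates the minimal structure the detection method relies on:

* several cell types in given proportions, each with its own marker genes
  (negative-binomial mean multiplied by ``marker_fold`` in the home type);
* housekeeping genes at a high constant mean — low CV everywhere, near-equal
  cluster means;
* *sensitive* genes that switch on stochastically in a ``sensitive_on_prob``
  fraction of cells, independently of cell type (or jointly per cell in
  "program mode"), giving a bimodal within-type distribution — high
  within-cluster CV — while cluster means stay near-equal — high entropy;
* background genes whose baseline means are drawn from a lognormal across
  genes, so the expression-mean spectrum (and hence the CV ranking) is
  non-trivial, as in real data.

Counts are gamma-Poisson (negative binomial with variance mu + dispersion *
mu^2) with lognormal per-cell library-size factors.  Everything is a pure
function of the seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import scipy.sparse as sp

from .containers import CellLabelTable, CountMatrix

__all__ = ["SimulationParams", "SyntheticTruth", "simulate_counts", "make_multi_sample"]


@dataclass
class SimulationParams:
    """Generator settings; defaults give the standard 2000-cell test world."""

    n_cells: int = 2000
    n_types: int = 5
    type_proportions: Sequence[float] | None = None
    n_genes: int = 1500
    n_markers_per_type: int = 20
    n_housekeeping: int = 50
    n_sensitive: int = 100
    baseline_mean: float = 1.0       # median of the per-gene lognormal baseline
    baseline_sigma: float = 0.5      # lognormal sigma of baselines across genes
    marker_fold: float = 8.0
    hk_mean: float = 8.0             # constant mean for housekeeping genes
    sensitive_on_prob: float = 0.3
    sensitive_on_fold: float = 8.0
    sensitive_baseline_scale: float = 0.1   # off-state level relative to a typical gene
    marker_baseline_scale: float = 0.3      # marker level outside the home type
    dispersion: float = 0.3          # NB: var = mu + dispersion * mu^2
    depth_mean: float = 1.0
    depth_sigma: float = 0.3
    program_mode: bool = False       # all sensitive genes co-activate per cell
    seed: int = 0

    def __post_init__(self) -> None:
        reserved = self.n_markers_per_type * self.n_types + self.n_housekeeping + self.n_sensitive
        if reserved > self.n_genes:
            raise ValueError(
                f"role counts need {reserved} genes but n_genes={self.n_genes}"
            )
        if self.type_proportions is None:
            self.type_proportions = tuple([1.0 / self.n_types] * self.n_types)
        else:
            self.type_proportions = tuple(float(p) for p in self.type_proportions)
            if len(self.type_proportions) != self.n_types:
                raise ValueError("one proportion per type required")
            if not math.isclose(sum(self.type_proportions), 1.0, abs_tol=1e-8):
                raise ValueError("type_proportions must sum to 1")
        if not (0 < self.sensitive_on_prob < 1):
            raise ValueError("sensitive_on_prob must be in (0, 1)")
        for name in ("baseline_mean", "hk_mean", "dispersion", "depth_mean"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass
class SyntheticTruth:
    """Planted per-cell types and per-gene roles for one simulated data set."""

    cell_type_of: list[str]
    gene_role_of: list[str]          # 'marker:<t>', 'housekeeping', 'sensitive', 'background'
    gene_ids: list[str]
    cell_ids: list[str]
    params: SimulationParams = field(repr=False, default_factory=SimulationParams)

    def genes_with_role(self, role: str) -> list[str]:
        return [g for g, r in zip(self.gene_ids, self.gene_role_of) if r == role]

    @property
    def sensitive_genes(self) -> list[str]:
        return self.genes_with_role("sensitive")

    @property
    def housekeeping_genes(self) -> list[str]:
        return self.genes_with_role("housekeeping")

    @property
    def background_genes(self) -> list[str]:
        return self.genes_with_role("background")

    @property
    def marker_genes(self) -> list[str]:
        return [g for g, r in zip(self.gene_ids, self.gene_role_of) if r.startswith("marker:")]

    def markers_of_type(self, t: int) -> list[str]:
        return self.genes_with_role(f"marker:{t}")

    def truth_labels(self) -> CellLabelTable:
        return CellLabelTable(cell_ids=self.cell_ids, labels=self.cell_type_of)


def _default_roles(params: SimulationParams) -> list[str]:
    roles: list[str] = []
    for t in range(params.n_types):
        roles += [f"marker:{t}"] * params.n_markers_per_type
    roles += ["housekeeping"] * params.n_housekeeping
    roles += ["sensitive"] * params.n_sensitive
    roles += ["background"] * (params.n_genes - len(roles))
    return roles


def _simulate_from_roles(
    params: SimulationParams, roles: list[str], seed: int
) -> tuple[CountMatrix, SyntheticTruth]:
    rng = np.random.default_rng(seed)
    n_cells, n_genes = params.n_cells, params.n_genes
    roles_arr = np.asarray(roles, dtype=object)

    cell_types = rng.choice(params.n_types, size=n_cells, p=params.type_proportions)
    depth = rng.lognormal(mean=math.log(params.depth_mean), sigma=params.depth_sigma, size=n_cells)

    base = rng.lognormal(mean=math.log(params.baseline_mean), sigma=params.baseline_sigma, size=n_genes)
    is_hk = roles_arr == "housekeeping"
    is_sens = roles_arr == "sensitive"
    is_marker = np.array([r.startswith("marker:") for r in roles_arr], dtype=bool)
    base[is_hk] = params.hk_mean
    # stress-program genes are near-silent at rest and strongly induced: the
    # off-state sits uniformly in the low-expression range (half the spread of
    # ordinary genes) so activation is bimodal for every program member.
    n_sens_total = int(is_sens.sum())
    base[is_sens] = rng.lognormal(
        mean=math.log(params.sensitive_baseline_scale * params.baseline_mean),
        sigma=params.baseline_sigma / 2,
        size=n_sens_total,
    )
    # lineage markers are close to silent outside their home type: cap the
    # baseline at the typical gene level and scale it down before the
    # home-type fold is applied.
    base[is_marker] = params.marker_baseline_scale * np.minimum(
        base[is_marker], params.baseline_mean
    )

    mu = depth[:, None] * base[None, :]
    for t in range(params.n_types):
        gmask = roles_arr == f"marker:{t}"
        if gmask.any():
            cmask = cell_types == t
            mu[np.ix_(cmask, gmask)] *= params.marker_fold
    n_sens = int(is_sens.sum())
    if n_sens:
        if params.program_mode:
            on_cells = rng.random(n_cells) < params.sensitive_on_prob
            activation = np.repeat(on_cells[:, None], n_sens, axis=1)
        else:
            activation = rng.random((n_cells, n_sens)) < params.sensitive_on_prob
        cols = np.flatnonzero(is_sens)
        mu[:, cols] = np.where(activation, mu[:, cols] * params.sensitive_on_fold, mu[:, cols])

    lam = rng.gamma(shape=1.0 / params.dispersion, scale=params.dispersion * mu)
    counts = rng.poisson(lam).astype(np.int64)

    gw, cw = len(str(n_genes - 1)), len(str(n_cells - 1))
    gene_ids = [f"G{i:0{gw}d}" for i in range(n_genes)]
    cell_ids = [f"C{i:0{cw}d}" for i in range(n_cells)]
    matrix = CountMatrix(counts=sp.csr_matrix(counts), cell_ids=cell_ids, gene_ids=gene_ids)
    truth = SyntheticTruth(
        cell_type_of=[f"type{t}" for t in cell_types],
        gene_role_of=list(roles),
        gene_ids=gene_ids,
        cell_ids=cell_ids,
        params=params,
    )
    return matrix, truth


def simulate_counts(params: SimulationParams | None = None) -> tuple[CountMatrix, SyntheticTruth]:
    """Draw one data set with the default role layout, determined by ``params.seed``."""
    params = params or SimulationParams()
    return _simulate_from_roles(params, _default_roles(params), params.seed)


def make_multi_sample(
    params: SimulationParams | None = None,
    n_samples: int = 4,
    shared_sensitive_fraction: float = 0.5,
) -> list[tuple[CountMatrix, SyntheticTruth]]:
    """Simulate ``n_samples`` data sets sharing a fraction of their sensitive genes.

    A ``shared_sensitive_fraction`` of the sensitive-gene identities is common
    to every sample; each sample's remaining sensitive slots are taken from
    disjoint parts of the background pool, so planted overlap statistics have
    closed forms.  Per-sample seeds are derived from ``params.seed``.
    """
    params = params or SimulationParams()
    if not (0 <= shared_sensitive_fraction <= 1):
        raise ValueError("shared_sensitive_fraction must be in [0, 1]")
    if n_samples < 2:
        raise ValueError("need at least 2 samples")
    base_roles = _default_roles(params)
    sens_idx = [i for i, r in enumerate(base_roles) if r == "sensitive"]
    bg_idx = [i for i, r in enumerate(base_roles) if r == "background"]
    n_shared = round(shared_sensitive_fraction * params.n_sensitive)
    n_private = params.n_sensitive - n_shared
    if n_samples * n_private > len(bg_idx) + n_private:
        raise ValueError(
            f"not enough background genes for {n_samples} samples with "
            f"{n_private} private sensitive genes each"
        )
    out = []
    for s in range(n_samples):
        roles = list(base_roles)
        # non-shared sensitive slots revert to background ...
        for i in sens_idx[n_shared:]:
            roles[i] = "background"
        # ... and each sample gets its own disjoint block of private sensitive genes.
        if s == 0:
            private = sens_idx[n_shared:]
        else:
            lo = (s - 1) * n_private
            private = bg_idx[lo : lo + n_private]
        for i in private:
            roles[i] = "sensitive"
        seed = (params.seed + 1 + s) % (2**31)
        out.append(_simulate_from_roles(replace(params, seed=seed), roles, seed))
    return out
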