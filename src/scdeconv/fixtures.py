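"""Fully synthetic annotated scRNA-seq datasets with known ZINB ground truth.

These generators stand in for a real tumor single-cell experiment (a genes x
cells matrix plus per-cell type labels): every gene gets a base NB mean
drawn log-uniformly, a dispersion and a dropout probability drawn uniformly,
and each cell type owns a block of marker genes whose mean is multiplied by
``marker_fold`` in that type. Cells are then drawn from the ZINB simulator
against these parameters, so estimator- and pipeline-recovery tests have an
exact truth to compare against.

What this emulates: type-specific mean structure, overdispersion, dropout,
and marker genes. What it does not: batch effects, doublets, ambient RNA, or
library-size variation — conclusions from these fixtures are about the
method's machinery, not about robustness to those artifacts.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import ExpressionMatrix
from .zinb import ZINBModelSet, simulate_cells

__all__ = ["FixtureSpec", "make_ground_truth", "make_separable_toy"]


@dataclass
class FixtureSpec:
    """Parameters of the synthetic single-cell dataset."""

    n_types: int = 5
    n_genes: int = 500
    n_cells_per_type: int = 600
    n_markers_per_type: int = 10
    marker_fold: float = 8.0
    base_mu_range: tuple[float, float] = (0.5, 50.0)
    theta_range: tuple[float, float] = (0.5, 4.0)
    pi_range: tuple[float, float] = (0.1, 0.6)
    seed: int = 0

    def __post_init__(self):
        if self.n_markers_per_type * self.n_types > self.n_genes:
            raise ValueError(
                f"{self.n_types} types x {self.n_markers_per_type} markers "
                f"exceed {self.n_genes} genes"
            )
        for lo, hi in (self.base_mu_range, self.theta_range, self.pi_range):
            if not 0 <= lo <= hi:
                raise ValueError("ranges must be positive and ordered")
        if self.marker_fold <= 0:
            raise ValueError("marker_fold must be positive")


def make_ground_truth(
    spec: FixtureSpec,
) -> tuple[ExpressionMatrix, pd.DataFrame, ZINBModelSet]:
    """Build a dataset plus the exact ZINB parameters it was drawn from.

    Deterministic under ``spec.seed``. Cell type ``typeK`` owns marker genes
    ``g{K*m}..g{K*m+m-1}``; its annotation marks all cells origin='real' so
    the fixture can play the role of a real experiment in the pipeline.
    """
    rng = np.random.default_rng(spec.seed)
    k, g = spec.n_types, spec.n_genes
    gene_ids = [f"g{i:05d}" for i in range(g)]
    cell_types = [f"type{i}" for i in range(k)]

    lo, hi = spec.base_mu_range
    base_mu = np.exp(rng.uniform(np.log(lo), np.log(hi), size=g))
    theta = rng.uniform(*spec.theta_range, size=g)
    pi = rng.uniform(*spec.pi_range, size=g)

    mu = np.tile(base_mu[:, None], (1, k))
    for t in range(k):
        block = slice(t * spec.n_markers_per_type,
                      (t + 1) * spec.n_markers_per_type)
        mu[block, t] *= spec.marker_fold

    truth = ZINBModelSet(
        design=["cell_type"],
        mu_groups=[(t,) for t in cell_types],
        cell_types=cell_types,
        gene_ids=gene_ids,
        mu=mu,
        theta=theta,
        pi=np.tile(pi[:, None], (1, k)),
    )

    blocks, anns = [], []
    for t in cell_types:
        em, ann = simulate_cells(truth, t, spec.n_cells_per_type, rng=rng,
                                 id_prefix="cell")
        blocks.append(em.values)
        ann = ann.copy()
        ann["origin"] = "real"  # plays the part of observed data
        anns.append(ann)
    values = np.hstack(blocks)
    ann = pd.concat(anns, ignore_index=True)
    em = ExpressionMatrix(values, gene_ids, list(ann["cell_id"]), "counts")
    return em, ann, truth


def make_separable_toy(
    n_cells_per_type: int = 50, seed: int = 0
) -> tuple[ExpressionMatrix, pd.DataFrame, ZINBModelSet]:
    """Tiny 2-type dataset with disjoint marker support for exact-direction tests.

    20 genes, 50 cells per type: typeA expresses genes 0-9 only, typeB genes
    10-19 only (dropout 0 on own markers, 1 elsewhere), so any sensible
    classifier must separate them perfectly in expectation.
    """
    gene_ids = [f"g{i:02d}" for i in range(20)]
    cell_types = ["typeA", "typeB"]
    mu = np.zeros((20, 2))
    pi = np.ones((20, 2)) * (1 - 1e-9)
    mu[:10, 0] = 30.0
    mu[10:, 1] = 30.0
    pi[:10, 0] = 0.0
    pi[10:, 1] = 0.0
    truth = ZINBModelSet(
        design=["cell_type"],
        mu_groups=[("typeA",), ("typeB",)],
        cell_types=cell_types,
        gene_ids=gene_ids,
        mu=mu,
        theta=np.full(20, 10.0),
        pi=pi,
    )
    rng = np.random.default_rng(seed)
    blocks, anns = [], []
    for t in cell_types:
        em, ann = simulate_cells(truth, t, n_cells_per_type, rng=rng,
                                 id_prefix="toy")
        blocks.append(em.values)
        ann = ann.copy()
        ann["origin"] = "real"
        anns.append(ann)
    ann = pd.concat(anns, ignore_index=True)
    em = ExpressionMatrix(np.hstack(blocks), gene_ids, list(ann["cell_id"]),
                          "counts")
    return em, ann, truth
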