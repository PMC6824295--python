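"""Pseudo-bulk construction: train/test splitting of single cells, mixture
proportion sampling, and synthetic bulk assembly.

A synthetic bulk sample is built by mixing a fixed number of single-cell
profiles (default 100) drawn according to a sampled composition vector
(w_1, ..., w_k), sum_k w_k = 100. Five sampling schemes are provided:

* ``DS1_uniform``        — truncated uniform per type within a-priori limits,
                           rows renormalized to 100;
* ``DS2_uniform_permuted`` — DS1 rows with cell-type labels permuted per row;
* ``DS3_norep``          — DS1 with duplicate composition vectors (after
                           rounding to 0.1) rejected;
* ``DS4_norep_permuted`` — DS3 permuted;
* ``DS5_dirichlet``      — rows ~ Dirichlet(alpha) x 100.

The recorded truth of each bulk sample is its *realized* composition (the
integer cell counts actually mixed), not the pre-rounding weights.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import ExpressionMatrix, tpm_normalize

__all__ = [
    "ProportionSet",
    "PseudoBulkSet",
    "split_cells",
    "default_uniform_limits",
    "gen_proportions",
    "build_bulk",
    "onehot_singlecell_samples",
    "concat_pseudobulk",
    "assemble_training_sets",
]

SCHEMES = (
    "DS1_uniform",
    "DS2_uniform_permuted",
    "DS3_norep",
    "DS4_norep_permuted",
    "DS5_dirichlet",
)


@dataclass
class ProportionSet:
    """Samples x cell-types composition matrix; every row sums to 100."""

    weights: np.ndarray
    cell_types: list[str]
    sample_ids: list[str]
    scheme: str = "manual"
    limits: np.ndarray | None = None

    def __post_init__(self):
        self.weights = np.asarray(self.weights, float)
        if self.weights.ndim != 2 or self.weights.shape[1] != len(self.cell_types):
            raise ValueError("weights must be samples x cell_types")
        if len(self.sample_ids) != self.weights.shape[0]:
            raise ValueError("sample_ids length mismatch")
        if np.any(self.weights < 0):
            raise ValueError("negative proportions")
        sums = self.weights.sum(axis=1)
        if not np.allclose(sums, 100.0, atol=1e-9):
            bad = int(np.argmax(np.abs(sums - 100)))
            raise ValueError(
                f"row {self.sample_ids[bad]} sums to {sums[bad]!r}, expected 100"
            )

    @property
    def n_samples(self) -> int:
        return self.weights.shape[0]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.weights, index=self.sample_ids,
                            columns=self.cell_types)


@dataclass
class PseudoBulkSet:
    """Synthetic bulk expression with per-sample ground-truth composition."""

    expr: ExpressionMatrix
    truth: ProportionSet
    cells_per_sample: int
    cell_manifest: list[list[str]] = field(default_factory=list)

    def __post_init__(self):
        if self.truth.n_samples != self.expr.n_obs:
            raise ValueError("truth rows do not align with expression columns")
        if self.truth.sample_ids != self.expr.obs_ids:
            raise ValueError("truth sample ids do not match expression columns")
        if self.cell_manifest and len(self.cell_manifest) != self.expr.n_obs:
            raise ValueError("manifest length mismatch")

    @property
    def n_samples(self) -> int:
        return self.expr.n_obs


def split_cells(
    ann: pd.DataFrame, train_frac: float = 0.65, seed: int | None = None
) -> pd.Series:
    """Stratified train/test split of cells by cell type.

    Per type, round(n_type * train_frac) cells go to train. Returns a Series
    mapping cell_id -> 'train' | 'test'. Deterministic under ``seed``.
    """
    if not 0 < train_frac < 1:
        raise ValueError("train_frac must be in (0, 1)")
    rng = np.random.default_rng(seed)
    parts = {}
    for t, grp in ann.groupby("cell_type", sort=True):
        ids = grp["cell_id"].to_numpy()
        if len(ids) < 2:
            raise ValueError(
                f"cell type {t!r} has a single cell; oversample before splitting"
            )
        perm = rng.permutation(len(ids))
        n_train = int(np.floor(len(ids) * train_frac + 0.5))
        n_train = min(max(n_train, 1), len(ids) - 1)  # both partitions non-empty
        for i, j in enumerate(perm):
            parts[ids[j]] = "train" if i < n_train else "test"
    return pd.Series(parts, name="partition").loc[ann["cell_id"]].copy()


def default_uniform_limits(ann: pd.DataFrame, cell_types: list[str]) -> np.ndarray:
    """Per-type (lo, hi) limits from observed frequencies: (0, 2 * freq * 100),
    capped at 100 — the a-priori abundance knowledge from the data itself."""
    freq = ann["cell_type"].value_counts(normalize=True)
    hi = np.array([min(100.0, 2.0 * 100.0 * freq.get(t, 0.0)) for t in cell_types])
    hi = np.maximum(hi, 1.0)  # every requested type must be reachable
    return np.column_stack([np.zeros_like(hi), hi])


def _uniform_rows(rng, n, limits):
    lo, hi = limits[:, 0], limits[:, 1]
    raw = rng.uniform(lo, hi, size=(n, len(lo)))
    sums = raw.sum(axis=1)
    while np.any(sums <= 0):  # pragma: no cover - requires all-zero draw
        redo = sums <= 0
        raw[redo] = rng.uniform(lo, hi, size=(int(redo.sum()), len(lo)))
        sums = raw.sum(axis=1)
    return raw / sums[:, None] * 100.0


def _permute_rows(rng, w):
    out = w.copy()
    for i in range(out.shape[0]):
        out[i] = out[i, rng.permutation(out.shape[1])]
    return out


def gen_proportions(
    cell_types: list[str],
    n_samples: int,
    scheme: str,
    limits: np.ndarray | None = None,
    alpha: np.ndarray | float | None = None,
    seed: int | None = None,
    max_attempts: int = 1000,
) -> ProportionSet:
    """Sample an n_samples x k composition matrix under one of the five schemes."""
    if scheme not in SCHEMES:
        raise ValueError(f"unknown scheme {scheme!r}; expected one of {SCHEMES}")
    k = len(cell_types)
    rng = np.random.default_rng(seed)

    if scheme == "DS5_dirichlet":
        if alpha is None:
            alpha = 1.0
        alpha = np.broadcast_to(np.asarray(alpha, float), (k,))
        if np.any(alpha <= 0):
            raise ValueError("Dirichlet alpha must be positive")
        w = rng.dirichlet(alpha, size=n_samples) * 100.0
    else:
        if limits is None:
            limits = np.column_stack([np.zeros(k), np.full(k, 100.0)])
        limits = np.asarray(limits, float)
        if limits.shape != (k, 2):
            raise ValueError("limits must be k x 2 (lo, hi)")
        if np.any(limits < 0) or np.any(limits[:, 0] > limits[:, 1]) \
                or np.any(limits > 100):
            raise ValueError("limits must satisfy 0 <= lo <= hi <= 100")
        if np.all(limits[:, 1] == 0):
            raise ValueError("infeasible limits: all upper bounds are zero")
        if scheme in ("DS1_uniform", "DS2_uniform_permuted"):
            w = _uniform_rows(rng, n_samples, limits)
            if scheme == "DS2_uniform_permuted":
                w = _permute_rows(rng, w)
        elif k == 1:
            # single type: the only composition is (100); dedup is vacuous
            w = np.full((n_samples, 1), 100.0)
        else:  # DS3 / DS4: reject duplicate vectors (rounded to 0.1)
            seen: set[tuple] = set()
            rows = []
            attempts = 0
            while len(rows) < n_samples:
                cand = _uniform_rows(rng, n_samples - len(rows), limits)
                for r in cand:
                    key = tuple(np.round(r, 1))
                    if key not in seen:
                        seen.add(key)
                        rows.append(r)
                attempts += 1
                if attempts > max_attempts:
                    raise RuntimeError(
                        "could not draw enough distinct composition vectors"
                    )
            w = np.array(rows)
            if scheme == "DS4_norep_permuted":
                w = _permute_rows(rng, w)

    # exact row normalization (guards float drift from the 0-100 rescale)
    w = w / w.sum(axis=1)[:, None] * 100.0
    ids = [f"{scheme}_s{i}" for i in range(n_samples)]
    return ProportionSet(w, list(cell_types), ids, scheme=scheme,
                         limits=None if scheme == "DS5_dirichlet" else limits)


def _largest_remainder(weights: np.ndarray, total: int) -> np.ndarray:
    """Round weights (summing to 100) to integer counts summing to ``total``."""
    quota = weights / 100.0 * total
    base = np.floor(quota).astype(int)
    short = total - int(base.sum())
    if short > 0:
        frac = quota - base
        # ties broken by lower index for determinism
        order = np.lexsort((np.arange(len(frac)), -frac))
        base[order[:short]] += 1
    return base


def build_bulk(
    sc: ExpressionMatrix,
    ann: pd.DataFrame,
    split: pd.Series,
    partition: str,
    props: ProportionSet,
    cells_per_sample: int = 100,
    seed: int | None = None,
) -> PseudoBulkSet:
    """Mix single-cell profiles into pseudo-bulk samples.

    Per sample the requested weights are converted to integer per-type cell
    counts summing to ``cells_per_sample`` (largest-remainder rounding), that
    many cells are drawn uniformly *with replacement* from the requested
    partition, and the bulk column is the per-gene mean of the drawn
    profiles, TPM-renormalized. The recorded truth is the realized integer
    composition.
    """
    rng = np.random.default_rng(seed)
    part_ids = set(split.index[split == partition])
    col_of = {c: i for i, c in enumerate(sc.obs_ids)}
    pool: dict[str, np.ndarray] = {}
    for t in props.cell_types:
        ids = ann.loc[
            (ann["cell_type"].astype(str) == t) & (ann["cell_id"].isin(part_ids)),
            "cell_id",
        ]
        cols = np.array([col_of[c] for c in ids], dtype=int)
        if cols.size == 0:
            raise ValueError(
                f"cell type {t!r} has no cells in partition {partition!r}"
            )
        pool[t] = cols

    n = props.n_samples
    values = np.empty((sc.n_genes, n))
    realized = np.empty((n, len(props.cell_types)))
    manifest: list[list[str]] = []
    for s in range(n):
        counts = _largest_remainder(props.weights[s], cells_per_sample)
        chosen: list[int] = []
        for t_i, t in enumerate(props.cell_types):
            if counts[t_i] > 0:
                chosen.extend(rng.choice(pool[t], size=counts[t_i], replace=True))
        values[:, s] = sc.values[:, chosen].mean(axis=1)
        realized[s] = counts / cells_per_sample * 100.0
        manifest.append([sc.obs_ids[i] for i in chosen])

    ids = [f"{partition}_{props.scheme}_b{i}" for i in range(n)]
    expr = tpm_normalize(ExpressionMatrix(values, list(sc.gene_ids), ids, sc.unit))
    truth = ProportionSet(realized, list(props.cell_types), ids,
                          scheme=props.scheme)
    return PseudoBulkSet(expr, truth, cells_per_sample, manifest)


def onehot_singlecell_samples(
    sc: ExpressionMatrix,
    ann: pd.DataFrame,
    split: pd.Series,
    partition: str,
    cell_types: list[str] | None = None,
) -> PseudoBulkSet:
    """Expose each single cell of a partition as its own 'bulk' sample with a
    one-hot truth row (100 on its type)."""
    ids = [c for c in sc.obs_ids if split.get(c) == partition]
    if not ids:
        raise ValueError(f"partition {partition!r} is empty")
    col_of = {c: i for i, c in enumerate(sc.obs_ids)}
    cols = [col_of[c] for c in ids]
    type_of = dict(zip(ann["cell_id"], ann["cell_type"].astype(str)))
    if cell_types is None:
        cell_types = sorted(ann["cell_type"].astype(str).unique())
    expr = tpm_normalize(sc.select_obs(cols))
    w = np.zeros((len(ids), len(cell_types)))
    for i, c in enumerate(ids):
        w[i, cell_types.index(type_of[c])] = 100.0
    truth = ProportionSet(w, list(cell_types), list(ids), scheme="onehot_sc")
    return PseudoBulkSet(expr, truth, 1, [[c] for c in ids])


def concat_pseudobulk(sets: list[PseudoBulkSet]) -> PseudoBulkSet:
    """Column-concatenate pseudo-bulk sets sharing genes and cell types."""
    first = sets[0]
    for s in sets[1:]:
        if s.expr.gene_ids != first.expr.gene_ids:
            raise ValueError("gene lists differ between sets")
        if s.truth.cell_types != first.truth.cell_types:
            raise ValueError("cell-type columns differ between sets")
    expr = ExpressionMatrix(
        np.hstack([s.expr.values for s in sets]),
        list(first.expr.gene_ids),
        [o for s in sets for o in s.expr.obs_ids],
        first.expr.unit,
    )
    truth = ProportionSet(
        np.vstack([s.truth.weights for s in sets]),
        list(first.truth.cell_types),
        list(expr.obs_ids),
        scheme="mixed",
    )
    manifest = [m for s in sets for m in s.cell_manifest]
    return PseudoBulkSet(expr, truth, first.cells_per_sample, manifest)


def _shuffle_set(ps: PseudoBulkSet, rng: np.random.Generator) -> PseudoBulkSet:
    perm = rng.permutation(ps.n_samples)
    expr = ps.expr.select_obs(perm)
    truth = ProportionSet(ps.truth.weights[perm],
                          list(ps.truth.cell_types),
                          [ps.truth.sample_ids[i] for i in perm],
                          scheme=ps.truth.scheme)
    manifest = [ps.cell_manifest[i] for i in perm]
    return PseudoBulkSet(expr, truth, ps.cells_per_sample, manifest)


def assemble_training_sets(
    sc: ExpressionMatrix,
    ann: pd.DataFrame,
    split: pd.Series,
    n_train: int = 2000,
    n_test: int = 700,
    schemes: list[str] = SCHEMES,
    limits: np.ndarray | None = None,
    alpha: np.ndarray | float | None = None,
    cells_per_sample: int = 100,
    include_onehot: bool = True,
    seed: int | None = None,
) -> dict[str, PseudoBulkSet]:
    """Build the full train/test pseudo-bulk collections.

    Per scheme, ``n_train`` bulk samples are mixed from train-partition cells
    and ``n_test`` from test-partition cells; the single-cell profiles of each
    partition are appended as one-hot samples; sample order is shuffled so
    single cells do not concentrate in one training batch. Train and test
    manifests never share a cell (leakage is asserted).
    """
    rng = np.random.default_rng(seed)
    cell_types = sorted(ann["cell_type"].astype(str).unique())
    if limits is None:
        limits = default_uniform_limits(ann, cell_types)
    out = {}
    for partition, n_bulk in (("train", n_train), ("test", n_test)):
        parts = []
        for scheme in schemes:
            props = gen_proportions(
                cell_types, n_bulk, scheme, limits=limits, alpha=alpha,
                seed=int(rng.integers(2**31)),
            )
            parts.append(build_bulk(sc, ann, split, partition, props,
                                    cells_per_sample,
                                    seed=int(rng.integers(2**31))))
        if include_onehot:
            parts.append(onehot_singlecell_samples(sc, ann, split, partition,
                                                   cell_types))
        out[partition] = _shuffle_set(concat_pseudobulk(parts), rng)

    train_cells = {c for m in out["train"].cell_manifest for c in m}
    test_cells = {c for m in out["test"].cell_manifest for c in m}
    leaked = train_cells & test_cells
    if leaked:
        raise AssertionError(
            f"train/test leakage: {len(leaked)} shared cells, e.g. "
            f"{sorted(leaked)[:5]}"
        )
    return out
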