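"""Expression-matrix and cell-metadata input/output.

Conventions used throughout the package:

* genes are rows, observations (cells or bulk samples) are columns;
* all indices are 0-based;
* gene matching between matrices is exact-string (no symbol/Ensembl
  translation);
* TPM matrices have columns summing to 1e6, and TPM renormalization is
  re-applied after any gene subsetting so that the model always consumes
  within-gene-list TPM.

Supported on-disk formats: TSV (header row = observation ids, first column =
gene ids) and Matrix Market triplet (.mtx) with sidecar ``features.tsv`` /
``barcodes.tsv`` one-id-per-line files.
"""

from __future__ import annotations

import os
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

__all__ = [
    "ExpressionMatrix",
    "read_expression",
    "write_expression",
    "read_annotation",
    "write_annotation",
    "validate_annotation",
    "tpm_normalize",
    "fpkm_to_tpm",
    "filter_genes",
    "align_to_gene_list",
]

UNITS = ("counts", "TPM", "FPKM")


@dataclass
class ExpressionMatrix:
    """A genes x observations expression matrix with identifiers and a unit tag.

    Parameters
    ----------
    values
        Non-negative float matrix, genes in rows, observations in columns.
    gene_ids, obs_ids
        Unique string identifiers for rows and columns.
    unit
        One of ``counts``, ``TPM``, ``FPKM``.
    """

    values: np.ndarray
    gene_ids: list[str]
    obs_ids: list[str]
    unit: str = "counts"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        self.gene_ids = [str(g) for g in self.gene_ids]
        self.obs_ids = [str(o) for o in self.obs_ids]
        if self.values.ndim != 2:
            raise ValueError(f"expected a 2-D matrix, got shape {self.values.shape}")
        if self.values.shape != (len(self.gene_ids), len(self.obs_ids)):
            raise ValueError(
                f"shape {self.values.shape} does not match "
                f"{len(self.gene_ids)} gene ids x {len(self.obs_ids)} obs ids"
            )
        if np.any(self.values < 0):
            raise ValueError("expression values must be non-negative")
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ValueError("duplicate gene ids")
        if len(set(self.obs_ids)) != len(self.obs_ids):
            raise ValueError("duplicate observation ids")
        if self.unit not in UNITS:
            raise ValueError(f"unknown unit {self.unit!r}; expected one of {UNITS}")

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_obs(self) -> int:
        return self.values.shape[1]

    def copy(self) -> "ExpressionMatrix":
        return ExpressionMatrix(
            self.values.copy(), list(self.gene_ids), list(self.obs_ids), self.unit
        )

    def select_obs(self, idx) -> "ExpressionMatrix":
        idx = np.asarray(idx)
        return ExpressionMatrix(
            self.values[:, idx],
            list(self.gene_ids),
            [self.obs_ids[i] for i in idx],
            self.unit,
        )

    def select_genes(self, idx) -> "ExpressionMatrix":
        idx = np.asarray(idx)
        return ExpressionMatrix(
            self.values[idx, :],
            [self.gene_ids[i] for i in idx],
            list(self.obs_ids),
            self.unit,
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.obs_ids)


def _mtx_sidecars(path: str, genes_path: str | None, obs_path: str | None):
    d = os.path.dirname(os.path.abspath(path))
    if genes_path is None:
        genes_path = os.path.join(d, "features.tsv")
    if obs_path is None:
        obs_path = os.path.join(d, "barcodes.tsv")
    return genes_path, obs_path


def _read_ids(path: str) -> list[str]:
    with open(path) as fh:
        # first whitespace-separated token per line (10x-style files carry
        # extra columns after the id)
        return [line.split("\t")[0].strip() for line in fh if line.strip()]


def read_expression(
    path: str,
    format: str = "tsv",
    unit: str = "counts",
    genes_path: str | None = None,
    obs_path: str | None = None,
) -> ExpressionMatrix:
    """Read an expression matrix from TSV or Matrix Market triplet format.

    For ``mtx_triplet``, companion id files default to ``features.tsv`` and
    ``barcodes.tsv`` next to the ``.mtx`` file.
    """
    if format == "tsv":
        df = pd.read_csv(path, sep="\t", index_col=0)
        if df.index.has_duplicates:
            dups = df.index[df.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate gene ids in {path}: {dups[:5]}")
        values = df.to_numpy(dtype=np.float64)
        return ExpressionMatrix(values, list(df.index.astype(str)),
                                list(df.columns.astype(str)), unit)
    if format == "mtx_triplet":
        genes_path, obs_path = _mtx_sidecars(path, genes_path, obs_path)
        for p in (genes_path, obs_path):
            if not os.path.exists(p):
                raise FileNotFoundError(f"missing sidecar id file {p}")
        mat = scipy.io.mmread(path)
        gene_ids = _read_ids(genes_path)
        obs_ids = _read_ids(obs_path)
        dense = np.asarray(mat.todense() if scipy.sparse.issparse(mat) else mat,
                           dtype=np.float64)
        if dense.shape != (len(gene_ids), len(obs_ids)):
            raise ValueError(
                f"matrix dimensions {dense.shape} do not match id files "
                f"({len(gene_ids)} genes, {len(obs_ids)} observations)"
            )
        return ExpressionMatrix(dense, gene_ids, obs_ids, unit)
    raise ValueError(f"unknown format {format!r}; expected 'tsv' or 'mtx_triplet'")


def write_expression(
    m: ExpressionMatrix,
    path: str,
    format: str = "tsv",
    genes_path: str | None = None,
    obs_path: str | None = None,
) -> None:
    """Write an expression matrix; inverse of :func:`read_expression`."""
    if format == "tsv":
        m.to_frame().to_csv(path, sep="\t", float_format="%.10g")
    elif format == "mtx_triplet":
        genes_path, obs_path = _mtx_sidecars(path, genes_path, obs_path)
        scipy.io.mmwrite(path, scipy.sparse.coo_matrix(m.values))
        with open(genes_path, "w") as fh:
            fh.write("\n".join(m.gene_ids) + "\n")
        with open(obs_path, "w") as fh:
            fh.write("\n".join(m.obs_ids) + "\n")
    else:
        raise ValueError(f"unknown format {format!r}")


def read_annotation(path: str) -> pd.DataFrame:
    """Read cell metadata (TSV; mandatory columns ``cell_id``, ``cell_type``).

    An ``origin`` column (real | simulated) is added, defaulting to ``real``.
    Any additional columns are carried along as covariates.
    """
    ann = pd.read_csv(path, sep="\t", dtype=str)
    for col in ("cell_id", "cell_type"):
        if col not in ann.columns:
            raise ValueError(f"metadata {path} lacks mandatory column {col!r}")
    if "origin" not in ann.columns:
        ann["origin"] = "real"
    return ann.reset_index(drop=True)


def write_annotation(ann: pd.DataFrame, path: str) -> None:
    ann.to_csv(path, sep="\t", index=False)


def validate_annotation(ann: pd.DataFrame, m: ExpressionMatrix) -> None:
    """Check that every annotated cell is a column of the companion matrix."""
    missing = set(ann["cell_id"]) - set(m.obs_ids)
    if missing:
        raise ValueError(
            f"{len(missing)} annotated cell ids absent from the expression "
            f"matrix, e.g. {sorted(missing)[:5]}"
        )
    if ann["cell_id"].duplicated().any():
        raise ValueError("duplicate cell_id entries in annotation")


def tpm_normalize(m: ExpressionMatrix) -> ExpressionMatrix:
    """Rescale every column to sum to 1e6 and tag the result as TPM."""
    colsums = m.values.sum(axis=0)
    zero = np.flatnonzero(colsums == 0)
    if zero.size:
        names = [m.obs_ids[i] for i in zero[:5]]
        raise ValueError(f"cannot TPM-normalize all-zero column(s): {names}")
    values = m.values / colsums * 1e6
    return ExpressionMatrix(values, list(m.gene_ids), list(m.obs_ids), "TPM")


def fpkm_to_tpm(m: ExpressionMatrix) -> ExpressionMatrix:
    """Convert FPKM to TPM: TPM_gj = FPKM_gj / sum_g FPKM_gj * 1e6."""
    if m.unit != "FPKM":
        raise ValueError(f"fpkm_to_tpm expects unit FPKM, got {m.unit}")
    return tpm_normalize(m)


def filter_genes(
    m: ExpressionMatrix, min_total: float = 0.0, min_obs_expressing: int = 0
) -> ExpressionMatrix:
    """Keep genes with total expression >= min_total and expressed (>0) in at
    least ``min_obs_expressing`` observations; row order is preserved."""
    if min_total < 0 or min_obs_expressing < 0:
        raise ValueError("filter thresholds must be non-negative")
    totals = m.values.sum(axis=1)
    n_expr = (m.values > 0).sum(axis=1)
    keep = np.flatnonzero((totals >= min_total) & (n_expr >= min_obs_expressing))
    if keep.size == 0:
        raise ValueError("gene filter removed every gene")
    out = m.select_genes(keep)
    if m.unit == "TPM":
        out = tpm_normalize(out)
    return out


def align_to_gene_list(
    bulk: ExpressionMatrix,
    gene_list: list[str],
    hard_fail_missing_frac: float = 0.9,
) -> tuple[ExpressionMatrix, dict]:
    """Reorder/subset ``bulk`` rows to exactly ``gene_list``.

    Genes absent from ``bulk`` are filled with zeros. Returns the aligned
    matrix together with a report of the missing fraction; more than 50%
    missing raises a warning flag in the report, and a fraction above
    ``hard_fail_missing_frac`` is a hard error.
    """
    gene_list = list(gene_list)
    if not gene_list:
        raise ValueError("gene_list is empty")
    pos = {g: i for i, g in enumerate(bulk.gene_ids)}
    values = np.zeros((len(gene_list), bulk.n_obs))
    missing = []
    for i, g in enumerate(gene_list):
        j = pos.get(g)
        if j is None:
            missing.append(g)
        else:
            values[i] = bulk.values[j]
    frac = len(missing) / len(gene_list)
    report = {
        "n_genes": len(gene_list),
        "n_missing": len(missing),
        "missing_fraction": frac,
        "missing_genes": missing[:50],
        "warning": frac > 0.5,
    }
    if frac > hard_fail_missing_frac:
        raise ValueError(
            f"{frac:.0%} of the model gene list is missing from the input "
            f"(hard-fail threshold {hard_fail_missing_frac:.0%}); gene "
            "identifiers are matched as exact strings — check annotation style"
        )
    out = ExpressionMatrix(values, gene_list, list(bulk.obs_ids), bulk.unit)
    return out, report
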