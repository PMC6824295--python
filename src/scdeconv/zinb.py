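"""Per-gene zero-inflated negative binomial (ZINB) models for scRNA-seq.

The ZINB is the standard model for single-cell count data: a negative
binomial NB(mean mu, size theta) — variance mu + mu^2/theta — mixed with a
point mass at zero of probability pi that represents technical dropout.

Models are fit per gene over a design of categorical covariates whose first
term is the cell type: the NB mean mu varies over the full design
(cell type x extra covariates), the dropout probability pi varies over cell
type only, and a single dispersion theta is shared by all groups of a gene.
Fits are maximum likelihood (L-BFGS-B on log mu / log theta / logit pi)
initialized by a method-of-moments estimate; genes whose likelihood
optimization fails keep the moment estimate and are flagged.

Because expression is handled as TPM throughout the pipeline, values are
rounded to the nearest integer for fitting and simulated draws are
TPM-scale pseudo-counts (the simulator output itself is integer; profiles
are TPM-renormalized downstream where they are consumed).
"""

from __future__ import annotations

import json
import logging
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.optimize
import scipy.special
from scipy.special import gammaln

from .io import ExpressionMatrix

__all__ = ["ZINBModelSet", "estimate_zinb", "simulate_cells", "oversample",
           "save_models", "load_models", "nb_zero_prob", "zinb_mean", "zinb_var"]

logger = logging.getLogger(__name__)

_LOG_MU_BOUNDS = (np.log(1e-8), np.log(1e8))
_LOG_THETA_BOUNDS = (np.log(1e-3), np.log(1e6))
# pi in [1e-6, 1 - 1e-6] on the logit scale
_LOGIT_PI_BOUNDS = (scipy.special.logit(1e-6), scipy.special.logit(1 - 1e-6))


def nb_zero_prob(mu: np.ndarray, theta: np.ndarray) -> np.ndarray:
    """P(NB(mu, theta) = 0) = (theta / (theta + mu))^theta."""
    mu, theta = np.asarray(mu, float), np.asarray(theta, float)
    return np.exp(theta * (np.log(theta) - np.log(theta + mu)))


def zinb_mean(mu, theta, pi):
    """Mean of the ZINB: (1 - pi) * mu."""
    return (1.0 - np.asarray(pi, float)) * np.asarray(mu, float)


def zinb_var(mu, theta, pi):
    """Variance of the ZINB: (1-pi)(mu + mu^2/theta) + pi(1-pi) mu^2."""
    mu, theta, pi = (np.asarray(a, float) for a in (mu, theta, pi))
    return (1 - pi) * (mu + mu**2 / theta) + pi * (1 - pi) * mu**2


@dataclass
class ZINBModelSet:
    """Fitted per-gene ZINB parameters over a covariate design.

    Attributes
    ----------
    design
        Covariate column names; the first is always ``cell_type``.
    mu_groups
        Labels (tuples of covariate levels) of the full-design groups; the
        columns of ``mu``.
    cell_types
        Dropout groups; the columns of ``pi``.
    mu, theta, pi
        Arrays of shape (genes, n_mu_groups), (genes,), (genes, n_cell_types).
    covariate_sampler
        Per cell type, the empirical distribution of full-design groups among
        that type's real cells — used to pick covariate levels when simulating.
    fallback
        Boolean flag per gene: True where the MLE failed and the moment
        estimate was kept.
    """

    design: list[str]
    mu_groups: list[tuple]
    cell_types: list[str]
    gene_ids: list[str]
    mu: np.ndarray
    theta: np.ndarray
    pi: np.ndarray
    covariate_sampler: dict[str, tuple[list[int], list[float]]] = field(
        default_factory=dict
    )
    fallback: np.ndarray | None = None

    def __post_init__(self):
        self.mu = np.asarray(self.mu, float)
        self.theta = np.asarray(self.theta, float)
        self.pi = np.asarray(self.pi, float)
        g = len(self.gene_ids)
        if self.mu.shape != (g, len(self.mu_groups)):
            raise ValueError("mu shape does not match gene/group counts")
        if self.theta.shape != (g,):
            raise ValueError("theta must be one value per gene")
        if self.pi.shape != (g, len(self.cell_types)):
            raise ValueError("pi shape does not match gene/cell-type counts")
        if np.any(self.theta <= 0):
            raise ValueError("theta must be positive")
        if np.any((self.pi < 0) | (self.pi > 1)):
            raise ValueError("pi must lie in [0, 1]")
        if np.any(self.mu < 0):
            raise ValueError("mu must be non-negative")
        if self.fallback is None:
            self.fallback = np.zeros(g, dtype=bool)
        if not self.covariate_sampler:
            # default: each cell type maps to the mu group of the same name
            self.covariate_sampler = {
                ct: ([self.mu_groups.index((ct,))], [1.0])
                for ct in self.cell_types
                if (ct,) in self.mu_groups
            }

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)


def _nll_factory(y_pos, combo_pos, zero_counts, mu_map, pi_map, n_mu, n_pi):
    """Build the per-gene ZINB negative log-likelihood.

    Observations are compressed: zeros contribute only through per-combo
    counts; positive values keep their combo index. ``mu_map``/``pi_map``
    map a combo index to its mu column / pi column.
    """

    def nll(params):
        log_mu = params[:n_mu]
        log_theta = params[n_mu]
        logit_pi = params[n_mu + 1:]
        theta = np.exp(log_theta)
        mu_c = np.exp(log_mu)[mu_map]          # per combo
        log_pi = -np.logaddexp(0.0, -logit_pi)           # log sigmoid
        log_1mpi = -np.logaddexp(0.0, logit_pi)
        log_pi_c = log_pi[pi_map]
        log_1mpi_c = log_1mpi[pi_map]
        # zero part: log(pi + (1-pi) * NB0)
        log_nb0 = theta * (log_theta - np.log(theta + mu_c))
        ll_zero = np.logaddexp(log_pi_c, log_1mpi_c + log_nb0)
        total = float(np.dot(zero_counts, ll_zero))
        if y_pos.size:
            mu_i = mu_c[combo_pos]
            log_mu_i = np.log(mu_i)
            ll_pos = (
                gammaln(y_pos + theta) - gammaln(theta) - gammaln(y_pos + 1)
                + theta * (log_theta - np.log(theta + mu_i))
                + y_pos * (log_mu_i - np.log(theta + mu_i))
            )
            total += float(np.sum(log_1mpi_c[combo_pos] + ll_pos))
        return -total

    return nll


def _moment_init(y, combo, mu_map, pi_map, n_mu, n_pi):
    """Method-of-moments starting values (also the fallback estimate)."""
    mu0 = np.full(n_mu, 1e-8)
    pi0 = np.full(n_pi, 0.5)
    for p in range(n_pi):
        sel = pi_map[combo] == p
        if sel.any():
            pi0[p] = np.clip((y[sel] == 0).mean() * 0.5, 1e-4, 0.95)
    for g in range(n_mu):
        sel = mu_map[combo] == g
        if sel.any():
            m = y[sel].mean()
            pbar = pi0[pi_map[np.flatnonzero(mu_map == g)[0]]] if n_pi else 0.0
            mu0[g] = max(m / max(1 - pbar, 0.05), 1e-8)
    m_all = y.mean()
    v_all = y.var()
    theta0 = np.clip(m_all**2 / max(v_all - m_all, 1e-6), 1e-3, 1e6) \
        if m_all > 0 else 1.0
    return mu0, theta0, pi0


def estimate_zinb(
    sc: ExpressionMatrix,
    ann: pd.DataFrame,
    design: list[str] = ("cell_type",),
    maxiter: int = 200,
    tol: float = 1e-8,
) -> ZINBModelSet:
    """Fit per-gene ZINB models over a ``cell_type`` (+ covariates) design.

    The NB mean uses the full design; dropout uses cell type only, which
    keeps small groups stable. Expression is rounded to integers before
    fitting. Genes whose MLE does not converge fall back to the moment
    estimator and are flagged in ``fallback``.
    """
    design = list(design)
    if not design or design[0] != "cell_type":
        design = ["cell_type"] + [d for d in design if d != "cell_type"]
    for cov in design:
        if cov not in ann.columns:
            raise ValueError(f"design covariate {cov!r} absent from annotation")

    order = {c: i for i, c in enumerate(sc.obs_ids)}
    ann = ann.set_index("cell_id").loc[sc.obs_ids].reset_index()
    y_all = np.rint(sc.values).astype(np.int64)

    combos = ann[design].astype(str).apply(tuple, axis=1)
    mu_groups = sorted(combos.unique())
    mu_group_idx = {g: i for i, g in enumerate(mu_groups)}
    cell_types = sorted(ann["cell_type"].astype(str).unique())
    ct_idx = {c: i for i, c in enumerate(cell_types)}

    combo_of_cell = combos.map(mu_group_idx).to_numpy()
    mu_map = np.arange(len(mu_groups))
    pi_map = np.array([ct_idx[g[0]] for g in mu_groups])

    counts = np.bincount(combo_of_cell, minlength=len(mu_groups))
    small = [mu_groups[i] for i in np.flatnonzero(counts < 2)]
    if small:
        raise ValueError(f"design groups with fewer than 2 cells: {small[:5]}")

    n_mu, n_pi = len(mu_groups), len(cell_types)
    n_genes = sc.n_genes
    mu = np.zeros((n_genes, n_mu))
    theta = np.ones(n_genes)
    pi = np.zeros((n_genes, n_pi))
    fallback = np.zeros(n_genes, dtype=bool)

    bounds = (
        [_LOG_MU_BOUNDS] * n_mu + [_LOG_THETA_BOUNDS] + [_LOGIT_PI_BOUNDS] * n_pi
    )

    for gi in range(n_genes):
        y = y_all[gi]
        if not y.any():
            # all-zero gene: expression floor, dropout near certainty
            mu[gi] = 1e-8
            theta[gi] = 1.0
            pi[gi] = 1 - 1e-6
            continue
        zero = y == 0
        zero_counts = np.bincount(combo_of_cell[zero], minlength=n_mu).astype(float)
        y_pos = y[~zero].astype(float)
        combo_pos = combo_of_cell[~zero]
        mu0, theta0, pi0 = _moment_init(y, combo_of_cell, mu_map, pi_map, n_mu, n_pi)
        x0 = np.concatenate([
            np.log(np.clip(mu0, 1e-8, 1e8)),
            [np.log(np.clip(theta0, 1e-3, 1e6))],
            scipy.special.logit(np.clip(pi0, 1e-6, 1 - 1e-6)),
        ])
        nll = _nll_factory(y_pos, combo_pos, zero_counts, mu_map, pi_map, n_mu, n_pi)
        try:
            res = scipy.optimize.minimize(
                nll, x0, method="L-BFGS-B", bounds=bounds,
                options={"maxiter": maxiter, "ftol": tol},
            )
            ok = res.success and np.all(np.isfinite(res.x))
        except (FloatingPointError, ValueError):  # pragma: no cover - rare
            ok = False
        if ok:
            mu[gi] = np.exp(res.x[:n_mu])
            theta[gi] = np.exp(res.x[n_mu])
            pi[gi] = scipy.special.expit(res.x[n_mu + 1:])
        else:
            mu[gi], theta[gi], pi[gi] = mu0, theta0, pi0
            fallback[gi] = True
            logger.info("gene %s: MLE failed, keeping moment estimate",
                        sc.gene_ids[gi])
        # groups where the gene is entirely zero: floor mean, dropout ~1
        for g in range(n_mu):
            if counts[g] > 0 and zero_counts[g] == counts[g] and mu[gi, g] < 1e-6:
                mu[gi, g] = 1e-8

    if fallback.any():
        logger.info("%d/%d genes used the moment fallback", fallback.sum(), n_genes)

    sampler: dict[str, tuple[list[int], list[float]]] = {}
    for ct in cell_types:
        sel = ann["cell_type"].astype(str) == ct
        sub = combos[sel].map(mu_group_idx)
        freq = sub.value_counts(normalize=True).sort_index()
        sampler[ct] = (list(freq.index), list(freq.to_numpy()))

    return ZINBModelSet(
        design=design, mu_groups=list(mu_groups), cell_types=cell_types,
        gene_ids=list(sc.gene_ids), mu=mu, theta=theta, pi=pi,
        covariate_sampler=sampler, fallback=fallback,
    )


def simulate_cells(
    models: ZINBModelSet,
    cell_type: str,
    n: int,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
    covariate_levels: dict[str, str] | None = None,
    id_prefix: str = "sim",
) -> tuple[ExpressionMatrix, pd.DataFrame]:
    """Draw ``n`` synthetic cells of ``cell_type`` from the fitted ZINB models.

    Per gene and cell, a count y ~ NB(mu, theta) is drawn and then zeroed
    with probability pi (independent Bernoulli dropout). Output values are
    integers; the annotation marks origin ``simulated``. Deterministic given
    ``seed`` (or an explicit generator).
    """
    if cell_type not in models.cell_types:
        raise ValueError(
            f"unknown cell type {cell_type!r}; known: {models.cell_types}"
        )
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = rng if rng is not None else np.random.default_rng(seed)
    ct_col = models.cell_types.index(cell_type)

    if covariate_levels is not None:
        key = tuple([cell_type] + [covariate_levels[c] for c in models.design[1:]])
        if key not in models.mu_groups:
            raise ValueError(f"design group {key} not present in models")
        combo_idx = np.full(n, models.mu_groups.index(key))
    else:
        groups, probs = models.covariate_sampler[cell_type]
        combo_idx = rng.choice(np.array(groups), size=n, p=np.array(probs))

    theta = models.theta[:, None]
    mu = models.mu[:, combo_idx]  # genes x n
    p = theta / (theta + mu)
    y = rng.negative_binomial(np.broadcast_to(theta, mu.shape), p)
    drop = rng.random(mu.shape) < models.pi[:, ct_col][:, None]
    y = np.where(drop, 0, y).astype(np.float64)

    obs_ids = [f"{id_prefix}_{cell_type}_{i}" for i in range(n)]
    em = ExpressionMatrix(y, list(models.gene_ids), obs_ids, "counts")
    rows = []
    for i in range(n):
        combo = models.mu_groups[combo_idx[i]]
        rec = {"cell_id": obs_ids[i], "cell_type": cell_type, "origin": "simulated"}
        rec.update({cov: lvl for cov, lvl in zip(models.design[1:], combo[1:])})
        rows.append(rec)
    ann = pd.DataFrame(rows)
    return em, ann


def oversample(
    sc: ExpressionMatrix,
    ann: pd.DataFrame,
    models: ZINBModelSet,
    target_per_type: int = 1000,
    mode: str = "fixed",
    seed: int | None = None,
) -> tuple[ExpressionMatrix, pd.DataFrame]:
    """Augment a single-cell dataset with simulated profiles per cell type.

    mode='fixed' (default): exactly ``target_per_type`` simulated cells are
    appended for every annotated type, regardless of its real count.
    mode='fill': only max(0, target_per_type - n_real) are appended, so each
    type reaches at least the target. Real cells are always retained.
    """
    if mode not in ("fixed", "fill"):
        raise ValueError(f"unknown oversample mode {mode!r}")
    rng = np.random.default_rng(seed)
    types = sorted(ann["cell_type"].astype(str).unique())
    unknown = [t for t in types if t not in models.cell_types]
    if unknown:
        raise ValueError(
            f"annotated types absent from models: {unknown}; "
            f"known: {models.cell_types}"
        )
    blocks = [sc.values]
    ann_blocks = [ann.copy()]
    for t in types:
        n_real = int((ann["cell_type"].astype(str) == t).sum())
        n_sim = target_per_type if mode == "fixed" else max(0, target_per_type - n_real)
        if n_sim == 0:
            continue
        em, sim_ann = simulate_cells(models, t, n_sim, rng=rng,
                                     id_prefix=f"sim{len(ann_blocks)}")
        blocks.append(em.values)
        ann_blocks.append(sim_ann)
    values = np.hstack(blocks)
    out_ann = pd.concat(ann_blocks, ignore_index=True)
    out = ExpressionMatrix(values, list(sc.gene_ids),
                           list(out_ann["cell_id"]), sc.unit)
    return out, out_ann


def save_models(models: ZINBModelSet, dirpath: str) -> None:
    """Serialize a model set: JSON manifest + one array file per parameter."""
    os.makedirs(dirpath, exist_ok=True)
    manifest = {
        "format_version": 1,
        "design": models.design,
        "mu_groups": [list(g) for g in models.mu_groups],
        "cell_types": models.cell_types,
        "gene_ids": models.gene_ids,
        "covariate_sampler": {
            k: [list(v[0]), list(v[1])] for k, v in models.covariate_sampler.items()
        },
    }
    with open(os.path.join(dirpath, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=1)
    np.save(os.path.join(dirpath, "mu.npy"), models.mu)
    np.save(os.path.join(dirpath, "theta.npy"), models.theta)
    np.save(os.path.join(dirpath, "pi.npy"), models.pi)
    np.save(os.path.join(dirpath, "fallback.npy"), models.fallback)


def load_models(dirpath: str) -> ZINBModelSet:
    with open(os.path.join(dirpath, "manifest.json")) as fh:
        manifest = json.load(fh)
    if manifest.get("format_version") != 1:
        raise ValueError(
            f"model format version {manifest.get('format_version')} != 1"
        )
    return ZINBModelSet(
        design=manifest["design"],
        mu_groups=[tuple(g) for g in manifest["mu_groups"]],
        cell_types=manifest["cell_types"],
        gene_ids=manifest["gene_ids"],
        mu=np.load(os.path.join(dirpath, "mu.npy")),
        theta=np.load(os.path.join(dirpath, "theta.npy")),
        pi=np.load(os.path.join(dirpath, "pi.npy")),
        covariate_sampler={
            k: (list(map(int, v[0])), list(map(float, v[1])))
            for k, v in manifest["covariate_sampler"].items()
        },
        fallback=np.load(os.path.join(dirpath, "fallback.npy")),
    )
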