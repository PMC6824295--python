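"""Proportion-regression neural network.

A fully connected network maps a bulk expression profile (log2(TPM+1),
per-gene min-max scaled to [0,1]) to a composition vector on the simplex:

    input -> [dense(h) -> batchnorm -> ReLU -> dropout]*L -> dense(k) -> softmax

trained with Adam on the Kullback-Leibler divergence between true and
predicted compositions (MAE and MSE are available as alternatives). The
defaults — two hidden layers of 200 units, dropout 0.25, 50 epochs, batches
of 100 — are the configuration that a grid search over losses, depths,
widths, dropout rates and epoch counts selects for this problem; the
:func:`grid_search` harness reproduces such a search on any space.

Truth compositions enter on the 0-100 scale, are divided by 100 for the
loss, and predictions are returned multiplied by 100.

The implementation is plain NumPy: forward/backward passes, batch
normalization with running statistics for inference, inverted dropout, and
Adam are written out explicitly, which keeps the trained model a small,
dependency-light artifact (JSON manifest + weight arrays).
"""

from __future__ import annotations

import itertools
import json
import os
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .io import ExpressionMatrix, align_to_gene_list, tpm_normalize
from .mixtures import ProportionSet, PseudoBulkSet

__all__ = [
    "ModelConfig",
    "FeatureScaler",
    "TrainedModel",
    "preprocess_features",
    "kld_loss",
    "train",
    "predict",
    "calibrate_sqrt",
    "grid_search",
    "save_model",
    "load_model",
]

_PRED_CLIP = 1e-7  # floor for predicted probabilities inside the KLD only


@dataclass
class ModelConfig:
    """Architecture and training hyperparameters."""

    hidden_sizes: list[int] = field(default_factory=lambda: [200, 200])
    dropout_rate: float = 0.25
    activation: str = "relu"
    loss: str = "kld"
    epochs: int = 50
    batch_size: int = 100
    batch_norm: bool = True
    learning_rate: float = 1e-3
    seed: int = 0

    def __post_init__(self):
        if not self.hidden_sizes:
            raise ValueError("hidden_sizes must be non-empty")
        if not 0 <= self.dropout_rate < 1:
            raise ValueError("dropout_rate must be in [0, 1)")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.loss not in ("kld", "mae", "mse"):
            raise ValueError(f"unknown loss {self.loss!r}")
        if self.activation != "relu":
            raise ValueError("only relu activation is supported")


@dataclass
class FeatureScaler:
    """log2(x+1) then per-gene min-max to [0,1]; parameters fit on training data."""

    min_: np.ndarray
    max_: np.ndarray

    def transform(self, X: np.ndarray, clip: bool = True) -> np.ndarray:
        span = self.max_ - self.min_
        span = np.where(span > 0, span, 1.0)
        Z = (np.log2(X + 1.0) - self.min_) / span
        # constant features (span 0) carry no information; pin them to 0
        Z[:, (self.max_ - self.min_) <= 0] = 0.0
        if clip:
            Z = np.clip(Z, 0.0, 1.0)
        return Z

    @classmethod
    def fit(cls, X: np.ndarray) -> "FeatureScaler":
        L = np.log2(X + 1.0)
        return cls(L.min(axis=0), L.max(axis=0))


class _MLP:
    """Bare fully-connected net; samples in rows."""

    def __init__(self, in_dim: int, hidden: list[int], out_dim: int,
                 batch_norm: bool, dropout: float, rng: np.random.Generator):
        self.hidden = list(hidden)
        self.batch_norm = batch_norm
        self.dropout = dropout
        dims = [in_dim] + self.hidden + [out_dim]
        self.W = [rng.normal(0, np.sqrt(2.0 / dims[i]),
                             size=(dims[i], dims[i + 1]))
                  for i in range(len(dims) - 1)]
        self.b = [np.zeros(d) for d in dims[1:]]
        if batch_norm:
            self.gamma = [np.ones(h) for h in self.hidden]
            self.beta = [np.zeros(h) for h in self.hidden]
            self.run_mean = [np.zeros(h) for h in self.hidden]
            self.run_var = [np.ones(h) for h in self.hidden]
        self._bn_momentum = 0.9
        self._bn_eps = 1e-5

    # ---- forward -----------------------------------------------------
    def forward(self, X, training=False, rng=None):
        cache = {"a": [X], "bn": [], "mask": []}
        h = X
        for li in range(len(self.hidden)):
            z = h @ self.W[li] + self.b[li]
            if self.batch_norm:
                if training:
                    mean = z.mean(axis=0)
                    var = z.var(axis=0)
                    self.run_mean[li] = (self._bn_momentum * self.run_mean[li]
                                         + (1 - self._bn_momentum) * mean)
                    self.run_var[li] = (self._bn_momentum * self.run_var[li]
                                        + (1 - self._bn_momentum) * var)
                else:
                    mean, var = self.run_mean[li], self.run_var[li]
                inv_std = 1.0 / np.sqrt(var + self._bn_eps)
                zhat = (z - mean) * inv_std
                zbn = self.gamma[li] * zhat + self.beta[li]
                cache["bn"].append((zhat, inv_std))
            else:
                zbn = z
                cache["bn"].append(None)
            a = np.maximum(zbn, 0.0)
            if training and self.dropout > 0:
                mask = (rng.random(a.shape) >= self.dropout) / (1 - self.dropout)
                a = a * mask
            else:
                mask = None
            cache["mask"].append(mask)
            cache["a"].append(a)
            h = a
        logits = h @ self.W[-1] + self.b[-1]
        logits -= logits.max(axis=1, keepdims=True)
        e = np.exp(logits)
        p = e / e.sum(axis=1, keepdims=True)
        cache["p"] = p
        return p, cache

    # ---- backward ----------------------------------------------------
    def backward(self, cache, dlogits):
        """Gradients for all parameters given dL/dlogits (pre-softmax)."""
        grads = {"W": [None] * len(self.W), "b": [None] * len(self.b),
                 "gamma": [None] * len(self.hidden),
                 "beta": [None] * len(self.hidden)}
        a_last = cache["a"][-1]
        grads["W"][-1] = a_last.T @ dlogits
        grads["b"][-1] = dlogits.sum(axis=0)
        da = dlogits @ self.W[-1].T
        for li in reversed(range(len(self.hidden))):
            mask = cache["mask"][li]
            if mask is not None:
                da = da * mask
            # relu derivative; masked-out units already have zero upstream grad
            dzbn = da * (cache["a"][li + 1] > 0)
            if self.batch_norm:
                zhat, inv_std = cache["bn"][li]
                B = zhat.shape[0]
                grads["gamma"][li] = (dzbn * zhat).sum(axis=0)
                grads["beta"][li] = dzbn.sum(axis=0)
                dzhat = dzbn * self.gamma[li]
                dz = (inv_std / B) * (
                    B * dzhat - dzhat.sum(axis=0)
                    - zhat * (dzhat * zhat).sum(axis=0)
                )
            else:
                dz = dzbn
            a_prev = cache["a"][li]
            grads["W"][li] = a_prev.T @ dz
            grads["b"][li] = dz.sum(axis=0)
            if li > 0:
                da = dz @ self.W[li].T
        return grads

    def params(self):
        out = {"W": self.W, "b": self.b}
        if self.batch_norm:
            out["gamma"] = self.gamma
            out["beta"] = self.beta
        return out


@dataclass
class TrainedModel:
    """A trained deconvolution network plus everything needed to apply it."""

    config: ModelConfig
    gene_list: list[str]
    cell_types: list[str]
    net: _MLP
    scaler: FeatureScaler
    history: pd.DataFrame


def preprocess_features(
    expr: ExpressionMatrix, scaler: FeatureScaler | None = None
) -> tuple[np.ndarray, FeatureScaler]:
    """Samples x genes feature matrix: log2(TPM+1), per-gene min-max to [0,1].

    On first use (``scaler=None``) the scaler is fit and returned; at predict
    time the stored scaler is applied and values are clipped to [0,1].
    """
    X = expr.values.T
    if scaler is None:
        scaler = FeatureScaler.fit(X)
        return scaler.transform(X, clip=False), scaler
    return scaler.transform(X, clip=True), scaler


def _as_rows(a) -> np.ndarray:
    a = np.asarray(a, float)
    return a[None, :] if a.ndim == 1 else a


def kld_loss(true_props, pred_props) -> float:
    """Mean Kullback-Leibler divergence sum_k t_k log(t_k / p_k) over samples.

    Rows are renormalized to the simplex (so sum-100 weight rows are
    accepted); predictions are floored at 1e-7; 0*log(0/.) = 0.
    """
    t = _as_rows(true_props)
    p = _as_rows(pred_props)
    if t.shape != p.shape:
        raise ValueError(f"shape mismatch: {t.shape} vs {p.shape}")
    t = t / t.sum(axis=1, keepdims=True)
    p = p / p.sum(axis=1, keepdims=True)
    p = np.clip(p, _PRED_CLIP, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(t > 0, t * (np.log(t) - np.log(p)), 0.0)
    return float(terms.sum(axis=1).mean())


def _loss_and_dlogits(loss: str, p: np.ndarray, t: np.ndarray):
    """Batch loss value and gradient w.r.t. the pre-softmax logits."""
    B = p.shape[0]
    if loss == "kld":
        pc = np.clip(p, _PRED_CLIP, 1.0)
        with np.errstate(divide="ignore", invalid="ignore"):
            val = float(np.where(t > 0, t * (np.log(t) - np.log(pc)), 0.0)
                        .sum(axis=1).mean())
        dlogits = (p - t) / B
        return val, dlogits
    if loss == "mse":
        d = p - t
        val = float((d**2).mean())
        dp = 2.0 * d / d.size
    else:  # mae
        d = p - t
        val = float(np.abs(d).mean())
        dp = np.sign(d) / d.size
    # softmax jacobian: dz_j = p_j (dp_j - sum_k dp_k p_k)
    dlogits = p * (dp - (dp * p).sum(axis=1, keepdims=True))
    return val, dlogits


class _Adam:
    def __init__(self, lr=1e-3, beta1=0.9, beta2=0.999, eps=1e-8):
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m, self.v, self.t = {}, {}, 0

    def step(self, params: dict, grads: dict):
        self.t += 1
        for key, plist in params.items():
            for i, p in enumerate(plist):
                g = grads[key][i]
                if g is None:
                    continue
                k = (key, i)
                self.m[k] = self.b1 * self.m.get(k, 0.0) + (1 - self.b1) * g
                self.v[k] = self.b2 * self.v.get(k, 0.0) + (1 - self.b2) * g**2
                mhat = self.m[k] / (1 - self.b1**self.t)
                vhat = self.v[k] / (1 - self.b2**self.t)
                p -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


def _error_metrics(p: np.ndarray, t: np.ndarray, eps: float = 0.001):
    """Max absolute and max proportional error on the simplex scale."""
    abs_err = np.abs(p - t)
    prop_err = abs_err / np.maximum(t, eps)
    return float(abs_err.max()), float(prop_err.max())


def train(
    config: ModelConfig,
    train_set: PseudoBulkSet,
    val_frac: float = 0.0,
    verbose: bool = False,
) -> TrainedModel:
    """Train the deconvolution network on a pseudo-bulk training set.

    Sample order is reshuffled every epoch. History records per-epoch mean
    training loss plus max absolute / max proportional error; with
    ``val_frac > 0`` a trailing fraction of samples is held out and its loss
    tracked as ``val_loss``.
    """
    rng = np.random.default_rng(config.seed)
    gene_list = list(train_set.expr.gene_ids)
    cell_types = list(train_set.truth.cell_types)
    X, scaler = preprocess_features(train_set.expr)
    T = train_set.truth.weights / 100.0

    n = X.shape[0]
    if val_frac > 0:
        n_val = max(1, int(round(n * val_frac)))
        perm = rng.permutation(n)
        val_idx, tr_idx = perm[:n_val], perm[n_val:]
        Xval, Tval = X[val_idx], T[val_idx]
        X, T = X[tr_idx], T[tr_idx]
        n = X.shape[0]
    else:
        Xval = Tval = None

    if n < 1:
        raise ValueError("no training samples")
    net = _MLP(len(gene_list), config.hidden_sizes, len(cell_types),
               config.batch_norm, config.dropout_rate, rng)
    opt = _Adam(lr=config.learning_rate)
    history = []
    for epoch in range(config.epochs):
        order = rng.permutation(n)
        losses = []
        for start in range(0, n, config.batch_size):
            idx = order[start:start + config.batch_size]
            if idx.size < 2 and config.batch_norm:
                continue  # batchnorm needs >1 sample
            p, cache = net.forward(X[idx], training=True, rng=rng)
            val, dlogits = _loss_and_dlogits(config.loss, p, T[idx])
            if not np.isfinite(val):
                raise RuntimeError(
                    f"non-finite loss at epoch {epoch}, batch {start // config.batch_size} "
                    f"(learning rate {config.learning_rate})"
                )
            grads = net.backward(cache, dlogits)
            opt.step(net.params(), grads)
            losses.append(val)
        p_tr, _ = net.forward(X, training=False)
        max_abs, max_prop = _error_metrics(p_tr, T)
        rec = {"epoch": epoch, "loss": float(np.mean(losses)),
               "max_abs_error": max_abs, "max_prop_error": max_prop}
        if Xval is not None:
            p_val, _ = net.forward(Xval, training=False)
            rec["val_loss"] = _loss_and_dlogits(config.loss, p_val, Tval)[0]
        history.append(rec)
        if verbose:
            print(f"epoch {epoch + 1}/{config.epochs}: " +
                  ", ".join(f"{k}={v:.4g}" for k, v in rec.items() if k != "epoch"))
    return TrainedModel(config, gene_list, cell_types, net, scaler,
                        pd.DataFrame(history))


def predict(
    model: TrainedModel,
    bulk: ExpressionMatrix,
    hard_fail_missing_frac: float = 0.9,
) -> ProportionSet:
    """Apply a trained model to bulk samples; returns proportions on 0-100.

    Input is aligned to the model's gene list (missing genes zero-filled,
    excess fraction is an error), TPM-renormalized over that list, scaled
    with the stored feature scaler, and passed through the network in
    inference mode (dropout off, batchnorm running statistics).
    """
    aligned, report = align_to_gene_list(bulk, model.gene_list,
                                         hard_fail_missing_frac)
    aligned = tpm_normalize(aligned)
    X, _ = preprocess_features(aligned, model.scaler)
    p, _ = model.net.forward(X, training=False)
    return ProportionSet(p * 100.0, list(model.cell_types),
                         list(bulk.obs_ids), scheme="predicted")


def calibrate_sqrt(props: ProportionSet) -> ProportionSet:
    """Square-root calibration: p'_k = sqrt(p_k) / sum_j sqrt(p_j) * 100.

    Compresses the dynamic range of predictions whose relation to the truth
    is quadratic rather than linear; rank order within each row is preserved.
    """
    r = np.sqrt(props.weights)
    r = r / r.sum(axis=1, keepdims=True) * 100.0
    return ProportionSet(r, list(props.cell_types), list(props.sample_ids),
                         scheme=props.scheme + "+sqrt")


def grid_search(
    space: dict[str, list],
    train_set: PseudoBulkSet,
    n_bulk: int | None = 2000,
    split: float = 0.7,
    seed: int = 0,
    base_config: ModelConfig | None = None,
) -> pd.DataFrame:
    """Train every configuration in the Cartesian product of ``space``.

    Each candidate trains on a ``split`` fraction of (up to ``n_bulk``)
    samples and is scored by validation loss; the result table is sorted
    ascending by validation loss, ties broken by max absolute error then
    configuration order. Deterministic under ``seed``.
    """
    if not space:
        raise ValueError("empty hyperparameter space")
    rng = np.random.default_rng(seed)
    ps = train_set
    if n_bulk is not None and n_bulk < ps.n_samples:
        keep = np.sort(rng.choice(ps.n_samples, size=n_bulk, replace=False))
        from .mixtures import PseudoBulkSet as _PBS
        expr = ps.expr.select_obs(keep)
        truth = ProportionSet(ps.truth.weights[keep], list(ps.truth.cell_types),
                              [ps.truth.sample_ids[i] for i in keep],
                              scheme=ps.truth.scheme)
        manifest = [ps.cell_manifest[i] for i in keep] if ps.cell_manifest else []
        ps = _PBS(expr, truth, ps.cells_per_sample, manifest)

    base = base_config or ModelConfig()
    keys = list(space.keys())
    rows = []
    for order, combo in enumerate(itertools.product(*(space[k] for k in keys))):
        kwargs = asdict(base)
        kwargs.update(dict(zip(keys, combo)))
        kwargs["seed"] = int(rng.integers(2**31))
        cfg = ModelConfig(**kwargs)
        model = train(cfg, ps, val_frac=1.0 - split)
        last = model.history.iloc[-1]
        row = {k: (tuple(v) if isinstance(v, list) else v)
               for k, v in zip(keys, combo)}
        row.update({
            "order": order,
            "val_loss": float(last["val_loss"]),
            "max_abs_error": float(last["max_abs_error"]),
            "train_loss": float(last["loss"]),
        })
        rows.append(row)
    df = pd.DataFrame(rows).sort_values(
        ["val_loss", "max_abs_error", "order"]).reset_index(drop=True)
    return df


_FORMAT_VERSION = 1


def save_model(model: TrainedModel, dirpath: str) -> None:
    """Serialize model as JSON manifest + .npz weight arrays."""
    os.makedirs(dirpath, exist_ok=True)
    manifest = {
        "format_version": _FORMAT_VERSION,
        "config": asdict(model.config),
        "gene_list": model.gene_list,
        "cell_types": model.cell_types,
        "scaler": {"min": model.scaler.min_.tolist(),
                   "max": model.scaler.max_.tolist()},
        "batch_norm": model.net.batch_norm,
    }
    with open(os.path.join(dirpath, "manifest.json"), "w") as fh:
        json.dump(manifest, fh)
    arrays = {}
    for i, (W, b) in enumerate(zip(model.net.W, model.net.b)):
        arrays[f"W{i}"] = W
        arrays[f"b{i}"] = b
    if model.net.batch_norm:
        for i in range(len(model.net.hidden)):
            arrays[f"gamma{i}"] = model.net.gamma[i]
            arrays[f"beta{i}"] = model.net.beta[i]
            arrays[f"run_mean{i}"] = model.net.run_mean[i]
            arrays[f"run_var{i}"] = model.net.run_var[i]
    np.savez(os.path.join(dirpath, "weights.npz"), **arrays)
    model.history.to_csv(os.path.join(dirpath, "history.tsv"), sep="\t",
                         index=False)


def load_model(dirpath: str) -> TrainedModel:
    with open(os.path.join(dirpath, "manifest.json")) as fh:
        manifest = json.load(fh)
    version = manifest.get("format_version")
    if version != _FORMAT_VERSION:
        raise ValueError(
            f"model format version {version!r} does not match "
            f"supported version {_FORMAT_VERSION}"
        )
    for key in ("config", "gene_list", "cell_types", "scaler"):
        if key not in manifest:
            raise ValueError(f"model manifest is missing field {key!r}")
    config = ModelConfig(**manifest["config"])
    gene_list = list(manifest["gene_list"])
    cell_types = list(manifest["cell_types"])
    scaler = FeatureScaler(np.array(manifest["scaler"]["min"]),
                           np.array(manifest["scaler"]["max"]))
    if scaler.min_.shape != (len(gene_list),):
        raise ValueError("scaler parameters do not match the gene list length")
    net = _MLP(len(gene_list), config.hidden_sizes, len(cell_types),
               manifest["batch_norm"], config.dropout_rate,
               np.random.default_rng(0))
    with np.load(os.path.join(dirpath, "weights.npz")) as z:
        for i in range(len(net.W)):
            W, b = z[f"W{i}"], z[f"b{i}"]
            if W.shape != net.W[i].shape:
                raise ValueError(
                    f"layer {i} weight shape {W.shape} does not match "
                    f"manifest architecture {net.W[i].shape}"
                )
            net.W[i], net.b[i] = W, b
        if net.batch_norm:
            for i in range(len(net.hidden)):
                net.gamma[i] = z[f"gamma{i}"]
                net.beta[i] = z[f"beta{i}"]
                net.run_mean[i] = z[f"run_mean{i}"]
                net.run_var[i] = z[f"run_var{i}"]
    hist_path = os.path.join(dirpath, "history.tsv")
    history = pd.read_csv(hist_path, sep="\t") if os.path.exists(hist_path) \
        else pd.DataFrame()
    return TrainedModel(config, gene_list, cell_types, net, scaler, history)
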