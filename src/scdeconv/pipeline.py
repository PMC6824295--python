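"""End-to-end pipeline stages and run configuration.

The pipeline chains five stages, each reading/writing declared artifacts in
an output directory and leaving a JSON run manifest beside every product:

1. ``simulate``  — fit per-gene ZINB models to the single-cell reference and
   oversample under-represented cell types;
2. ``mix``       — split cells into train/test and build pseudo-bulk
   train/test collections under the five proportion schemes;
3. ``train``     — train the deconvolution network on the training collection;
4. ``predict``   — apply a trained model to bulk samples (FPKM input is
   converted to TPM first);
5. ``evaluate``  — correlation / agreement / error reports of predictions
   against the known test-set compositions.

Stage seeds are derived deterministically from the global seed and the stage
name, so a rerun with the same configuration reproduces every artifact.
"""

from __future__ import annotations

import hashlib
import json
import os
from dataclasses import dataclass, field, asdict

import pandas as pd

from . import io as io_mod
from . import zinb, mixtures, nn, evaluation


__all__ = [
    "RunConfig",
    "stage_seed",
    "cmd_simulate",
    "cmd_mix",
    "cmd_train",
    "cmd_predict",
    "cmd_evaluate",
    "run_all",
    "load_config",
]


def stage_seed(global_seed: int, stage: str) -> int:
    """Deterministic per-stage seed below 2^31."""
    h = hashlib.sha256(f"{global_seed}:{stage}".encode()).digest()
    return int.from_bytes(h[:4], "big") % (2**31)


def _checksum(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()[:16]


def _write_manifest(outdir: str, stage: str, config: dict,
                    inputs: list[str], seed: int) -> None:
    from . import __version__
    manifest = {
        "stage": stage,
        "version": __version__,
        "seed": seed,
        "config": config,
        "input_checksums": {p: _checksum(p) for p in inputs
                            if os.path.isfile(p)},
    }
    with open(os.path.join(outdir, f"{stage}_manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=1, default=str)


@dataclass
class RunConfig:
    """Flat configuration for a full pipeline run.

    Defaults mirror the method's published hyperparameters; keys whose value
    the method leaves open (gene filters, bulk counts, feature scaling) are
    design decisions of this package and marked so in the config schema.
    """

    sc_matrix: str = ""
    sc_metadata: str = ""
    outdir: str = "run"
    sc_format: str = "tsv"
    sc_unit: str = "counts"
    design: list[str] = field(default_factory=lambda: ["cell_type"])
    # gene filtering (design decision: thresholds are unpublished)
    min_gene_total: float = 0.0
    min_obs_expressing: int = 0
    # oversampling
    target_per_type: int = 1000
    oversample_mode: str = "fixed"
    # mixing
    train_frac: float = 0.65
    n_bulk_train: int = 2000
    n_bulk_test: int = 700
    cells_per_sample: int = 100
    schemes: list[str] = field(default_factory=lambda: list(mixtures.SCHEMES))
    # training
    hidden_sizes: list[int] = field(default_factory=lambda: [200, 200])
    dropout_rate: float = 0.25
    loss: str = "kld"
    epochs: int = 50
    batch_size: int = 100
    # evaluation
    fit: str = "linear"
    sqrt_calibrate: bool = False
    seed: int = 0


_LIST_KEYS = {"design", "schemes", "hidden_sizes"}


def load_config(path: str) -> RunConfig:
    """Parse a flat ``key = value`` text config file into a RunConfig."""
    defaults = RunConfig()
    kwargs = {}
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.split("#")[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ValueError(f"{path}:{ln}: expected 'key = value'")
            key, _, value = line.partition("=")
            key, value = key.strip(), value.strip()
            if not hasattr(defaults, key):
                raise ValueError(f"{path}:{ln}: unknown config key {key!r}")
            default = getattr(defaults, key)
            if key in _LIST_KEYS:
                items = [v.strip() for v in value.split(",") if v.strip()]
                kwargs[key] = [int(v) for v in items] \
                    if key == "hidden_sizes" else items
            elif isinstance(default, bool):
                kwargs[key] = value.lower() in ("1", "true", "yes")
            elif isinstance(default, int):
                kwargs[key] = int(value)
            elif isinstance(default, float):
                kwargs[key] = float(value)
            else:
                kwargs[key] = value
    return RunConfig(**kwargs)


def _read_reference(cfg: RunConfig):
    sc = io_mod.read_expression(cfg.sc_matrix, format=cfg.sc_format,
                                unit=cfg.sc_unit)
    ann = io_mod.read_annotation(cfg.sc_metadata)
    io_mod.validate_annotation(ann, sc)
    if cfg.min_gene_total > 0 or cfg.min_obs_expressing > 0:
        sc = io_mod.filter_genes(sc, cfg.min_gene_total, cfg.min_obs_expressing)
    return sc, ann


def _require(path: str, producer: str) -> str:
    if not os.path.exists(path):
        raise FileNotFoundError(
            f"missing artifact {path}; run `scdeconv {producer}` first"
        )
    return path


def cmd_simulate(cfg: RunConfig) -> None:
    """Stage 1-2: fit ZINB models and oversample under-represented types."""
    os.makedirs(cfg.outdir, exist_ok=True)
    seed = stage_seed(cfg.seed, "simulate")
    sc, ann = _read_reference(cfg)
    models = zinb.estimate_zinb(sc, ann, design=cfg.design)
    aug, aug_ann = zinb.oversample(sc, ann, models, cfg.target_per_type,
                                   cfg.oversample_mode, seed=seed)
    zinb.save_models(models, os.path.join(cfg.outdir, "zinb_models"))
    io_mod.write_expression(aug, os.path.join(cfg.outdir, "sc_augmented.tsv"))
    io_mod.write_annotation(aug_ann,
                            os.path.join(cfg.outdir, "sc_augmented_meta.tsv"))
    _write_manifest(cfg.outdir, "simulate", asdict(cfg),
                    [cfg.sc_matrix, cfg.sc_metadata], seed)


def _save_pseudobulk(ps: mixtures.PseudoBulkSet, outdir: str, name: str):
    io_mod.write_expression(ps.expr, os.path.join(outdir, f"{name}_expr.tsv"))
    ps.truth.to_frame().to_csv(os.path.join(outdir, f"{name}_truth.tsv"),
                               sep="\t")
    with open(os.path.join(outdir, f"{name}_mixinfo.json"), "w") as fh:
        json.dump({"scheme": ps.truth.scheme,
                   "cells_per_sample": ps.cells_per_sample,
                   "cell_manifest": ps.cell_manifest}, fh)


def _load_pseudobulk(outdir: str, name: str, producer: str = "mix"):
    expr = io_mod.read_expression(
        _require(os.path.join(outdir, f"{name}_expr.tsv"), producer),
        unit="TPM")
    truth_df = pd.read_csv(os.path.join(outdir, f"{name}_truth.tsv"),
                           sep="\t", index_col=0)
    with open(os.path.join(outdir, f"{name}_mixinfo.json")) as fh:
        info = json.load(fh)
    truth = mixtures.ProportionSet(
        truth_df.to_numpy(), list(truth_df.columns),
        list(truth_df.index.astype(str)), scheme=info["scheme"])
    return mixtures.PseudoBulkSet(expr, truth, info["cells_per_sample"],
                                  info["cell_manifest"])


def cmd_mix(cfg: RunConfig) -> None:
    """Stage 3-4: split cells and build pseudo-bulk train/test collections."""
    seed = stage_seed(cfg.seed, "mix")
    sc = io_mod.read_expression(
        _require(os.path.join(cfg.outdir, "sc_augmented.tsv"), "simulate"),
        unit=cfg.sc_unit)
    ann = io_mod.read_annotation(
        os.path.join(cfg.outdir, "sc_augmented_meta.tsv"))
    split = mixtures.split_cells(ann, cfg.train_frac,
                                 seed=stage_seed(cfg.seed, "split"))
    split.rename_axis("cell_id").reset_index().to_csv(
        os.path.join(cfg.outdir, "split.tsv"), sep="\t", index=False)
    sets = mixtures.assemble_training_sets(
        sc, ann, split, n_train=cfg.n_bulk_train, n_test=cfg.n_bulk_test,
        schemes=cfg.schemes, cells_per_sample=cfg.cells_per_sample, seed=seed)
    for name, ps in sets.items():
        _save_pseudobulk(ps, cfg.outdir, name)
    _write_manifest(cfg.outdir, "mix", asdict(cfg),
                    [os.path.join(cfg.outdir, "sc_augmented.tsv")], seed)


def cmd_train(cfg: RunConfig) -> None:
    """Stage 5: train the deconvolution network on the training collection."""
    seed = stage_seed(cfg.seed, "train")
    train_set = _load_pseudobulk(cfg.outdir, "train")
    config = nn.ModelConfig(hidden_sizes=list(cfg.hidden_sizes),
                            dropout_rate=cfg.dropout_rate, loss=cfg.loss,
                            epochs=cfg.epochs, batch_size=cfg.batch_size,
                            seed=seed)
    model = nn.train(config, train_set)
    nn.save_model(model, os.path.join(cfg.outdir, "model"))
    _write_manifest(cfg.outdir, "train", asdict(cfg),
                    [os.path.join(cfg.outdir, "train_expr.tsv")], seed)


def cmd_predict(cfg: RunConfig, bulk_path: str | None = None,
                input_unit: str = "TPM", out_name: str = "predictions") -> None:
    """Stage 6: apply the trained model to bulk samples.

    With no explicit bulk path the held-out pseudo-bulk test set is used.
    FPKM input is converted to TPM (and the conversion logged).
    """
    _require(os.path.join(cfg.outdir, "model", "manifest.json"), "train")
    model = nn.load_model(os.path.join(cfg.outdir, "model"))
    if bulk_path is None:
        bulk = _load_pseudobulk(cfg.outdir, "test").expr
    else:
        bulk = io_mod.read_expression(bulk_path, unit=input_unit.upper()
                                      if input_unit.lower() == "fpkm"
                                      else input_unit)
        if bulk.unit == "FPKM":
            bulk = io_mod.fpkm_to_tpm(bulk)
            print("converted FPKM input to TPM")
    preds = nn.predict(model, bulk)
    if cfg.sqrt_calibrate:
        preds = nn.calibrate_sqrt(preds)
    preds.to_frame().to_csv(os.path.join(cfg.outdir, f"{out_name}.tsv"),
                            sep="\t")
    _write_manifest(cfg.outdir, "predict", asdict(cfg),
                    [bulk_path] if bulk_path else [], stage_seed(cfg.seed,
                                                                 "predict"))


def cmd_evaluate(cfg: RunConfig) -> dict:
    """Stage 6b: score test-set predictions against known compositions."""
    test = _load_pseudobulk(cfg.outdir, "test")
    pred_df = pd.read_csv(
        _require(os.path.join(cfg.outdir, "predictions.tsv"), "predict"),
        sep="\t", index_col=0)
    preds = mixtures.ProportionSet(pred_df.to_numpy(), list(pred_df.columns),
                                   list(pred_df.index.astype(str)),
                                   scheme="predicted")
    corr = evaluation.correlation_report(preds, test.truth, fit=cfg.fit)
    ba = evaluation.bland_altman(preds, test.truth)
    bins, per_sample = evaluation.proportional_error_bins(preds, test.truth)
    report = {
        "per_type": {
            t: {"pearson_r": corr[t]["pearson_r"], "p_value": corr[t]["p_value"]}
            for t in preds.cell_types
        },
        "pooled_pearson_r": corr["pooled"]["pearson_r"],
        "bland_altman": {
            "mean_diff": ba["mean_diff"], "sd_diff": ba["sd_diff"],
            "limits": ba["limits"],
            "per_type": ba["per_type"],
        },
        "max_abs_error": float(per_sample["max_abs_error"].max()),
        "max_prop_error": float(per_sample["max_prop_error"].max()),
    }
    with open(os.path.join(cfg.outdir, "eval_report.json"), "w") as fh:
        json.dump(report, fh, indent=1)
    bins.to_csv(os.path.join(cfg.outdir, "eval_error_bins.tsv"), sep="\t",
                index=False)
    per_sample.to_csv(os.path.join(cfg.outdir, "eval_per_sample.tsv"),
                      sep="\t", index=False)
    _write_manifest(cfg.outdir, "evaluate", asdict(cfg), [],
                    stage_seed(cfg.seed, "evaluate"))
    return report


def run_all(cfg: RunConfig) -> dict:
    """Chain simulate → mix → train → predict → evaluate."""
    cmd_simulate(cfg)
    cmd_mix(cfg)
    cmd_train(cfg)
    cmd_predict(cfg)
    return cmd_evaluate(cfg)
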