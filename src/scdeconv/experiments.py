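"""Canned end-to-end experiments on synthetic data.

The parameter-recovery experiment is the package's benchmark of the whole
pipeline: generate a synthetic single-cell dataset with known ZINB ground
truth, run ZINB estimation + oversampling, mix pseudo-bulk training and test
collections, train the network, and score predicted against expected
compositions on the held-out test mixtures.

Problem sizes default to 5 cell types x 500 genes x 600 cells per type with
3000 training and 1000 test mixtures at 50 epochs — large enough for the
network to recover compositions, small enough to run in about a minute on
one CPU. The training collection for this experiment consists of the bulk
mixtures only; appending the one-hot single-cell columns (the default of the
standard pipeline) is driven by ``include_onehot`` and its effect on
calibration is discussed in the methods notes.
"""

from __future__ import annotations

import numpy as np

from . import evaluation, mixtures, nn, zinb
from .fixtures import FixtureSpec, make_ground_truth
from .pipeline import stage_seed

__all__ = ["recovery_experiment"]


def recovery_experiment(
    seed: int = 0,
    spec: FixtureSpec | None = None,
    n_train: int = 3000,
    n_test: int = 1000,
    epochs: int = 50,
    target_per_type: int = 1000,
    include_onehot: bool = False,
) -> dict:
    """Full-pipeline recovery run on a known-truth fixture.

    Returns a dict with pooled/per-type Pearson r, per-type Bland-Altman
    mean differences, max absolute/proportional errors, and the sizes used.
    ``n_train``/``n_test`` are total bulk mixtures, spread evenly over the
    five proportion schemes.
    """
    if spec is None:
        spec = FixtureSpec(seed=stage_seed(seed, "fixture"))
    em, ann, truth = make_ground_truth(spec)
    models = zinb.estimate_zinb(em, ann)
    aug, aug_ann = zinb.oversample(em, ann, models, target_per_type,
                                   mode="fixed",
                                   seed=stage_seed(seed, "oversample"))
    split = mixtures.split_cells(aug_ann, 0.65,
                                 seed=stage_seed(seed, "split"))
    n_schemes = len(mixtures.SCHEMES)
    sets = mixtures.assemble_training_sets(
        aug, aug_ann, split,
        n_train=n_train // n_schemes, n_test=n_test // n_schemes,
        include_onehot=include_onehot, seed=stage_seed(seed, "mix"))
    cfg = nn.ModelConfig(epochs=epochs, seed=stage_seed(seed, "train"))
    model = nn.train(cfg, sets["train"])
    preds = nn.predict(model, sets["test"].expr)
    corr = evaluation.correlation_report(preds, sets["test"].truth)
    ba = evaluation.bland_altman(preds, sets["test"].truth)
    _, per_sample = evaluation.proportional_error_bins(preds,
                                                       sets["test"].truth)
    return {
        "pooled_pearson_r": corr["pooled"]["pearson_r"],
        "per_type_pearson_r": {
            t: corr[t]["pearson_r"] for t in preds.cell_types
        },
        "per_type_ba_mean_diff": {
            t: ba["per_type"][t]["mean_diff"] for t in preds.cell_types
        },
        "max_abs_error": float(per_sample["max_abs_error"].max()),
        "mean_abs_error": float(
            np.abs(preds.weights - sets["test"].truth.weights).mean()),
        "n_train": sets["train"].n_samples,
        "n_test": sets["test"].n_samples,
        "history": model.history,
    }
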