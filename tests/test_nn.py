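import numpy as np
import pytest

from scdeconv.io import ExpressionMatrix
from scdeconv.fixtures import make_separable_toy
from scdeconv.mixtures import (
    ProportionSet,
    split_cells,
    assemble_training_sets,
)
from scdeconv.nn import (
    FeatureScaler,
    ModelConfig,
    calibrate_sqrt,
    grid_search,
    kld_loss,
    load_model,
    predict,
    preprocess_features,
    save_model,
    train,
)


@pytest.fixture(scope="module")
def toy_training():
    """Separable 2-type toy: data, split, train/test pseudo-bulk sets."""
    em, ann, _ = make_separable_toy(n_cells_per_type=60, seed=2)
    split = split_cells(ann, 0.65, seed=3)
    sets = assemble_training_sets(em, ann, split, n_train=60, n_test=30,
                                  seed=4)
    return em, ann, split, sets


@pytest.fixture(scope="module")
def toy_model(toy_training):
    _, _, _, sets = toy_training
    cfg = ModelConfig(hidden_sizes=[32], epochs=25, batch_size=32, seed=5)
    return train(cfg, sets["train"])


class TestConfig:
    def test_defaults_match_published_hyperparameters(self):
        cfg = ModelConfig()
        assert cfg.hidden_sizes == [200, 200]
        assert cfg.dropout_rate == 0.25
        assert cfg.loss == "kld"
        assert cfg.epochs == 50
        assert cfg.batch_size == 100
        assert cfg.activation == "relu"

    def test_invalid_values_rejected(self):
        with pytest.raises(ValueError):
            ModelConfig(hidden_sizes=[])
        with pytest.raises(ValueError):
            ModelConfig(dropout_rate=1.0)
        with pytest.raises(ValueError):
            ModelConfig(loss="hinge")


class TestKLD:
    def test_identical_distributions_give_zero(self):
        t = np.array([[0.2, 0.3, 0.5], [1.0, 0.0, 0.0]])
        assert kld_loss(t, t) < 1e-12

    def test_onehot_vs_uniform_is_log2(self):
        val = kld_loss(np.array([1.0, 0.0]), np.array([0.5, 0.5]))
        assert abs(val - np.log(2)) < 1e-6

    def test_nonnegative_on_random_simplex_pairs(self):
        rng = np.random.default_rng(0)
        t = rng.dirichlet(np.ones(4), size=10_000)
        p = rng.dirichlet(np.ones(4), size=10_000)
        terms = np.where(t > 0, t * (np.log(t) - np.log(p)), 0.0).sum(axis=1)
        assert terms.min() > -1e-12          # Gibbs inequality, per pair
        assert kld_loss(t, p) >= 0.0

    def test_accepts_sum_100_truth_rows(self):
        assert kld_loss(np.array([100.0, 0.0]), np.array([0.5, 0.5])) \
            == pytest.approx(np.log(2), abs=1e-6)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError, match="shape"):
            kld_loss(np.ones(3) / 3, np.ones(4) / 4)


class TestFeatureScaling:
    def test_all_zero_gene_maps_to_zero(self):
        em = ExpressionMatrix(np.array([[0.0, 0.0], [1.0, 3.0]]),
                              ["z", "g"], ["s1", "s2"])
        X, scaler = preprocess_features(em)
        np.testing.assert_allclose(X[:, 0], 0.0)

    def test_training_max_maps_to_one(self):
        em = ExpressionMatrix(np.array([[1.0, 7.0, 3.0]]), ["g"],
                              ["a", "b", "c"])
        X, _ = preprocess_features(em)
        assert X.max() == pytest.approx(1.0)
        assert X.min() == pytest.approx(0.0)

    def test_stored_scaler_is_deterministic_and_clips(self):
        em = ExpressionMatrix(np.array([[1.0, 7.0]]), ["g"], ["a", "b"])
        _, scaler = preprocess_features(em)
        big = ExpressionMatrix(np.array([[100.0]]), ["g"], ["x"])
        X1, _ = preprocess_features(big, scaler)
        X2, _ = preprocess_features(big, scaler)
        np.testing.assert_array_equal(X1, X2)
        assert X1.max() <= 1.0


class TestTrainPredict:
    def test_loss_decreases_during_training(self, toy_model):
        hist = toy_model.history
        assert hist["loss"].iloc[-1] < hist["loss"].iloc[0]
        # halving of the training loss over the run
        assert hist["loss"].iloc[-1] <= 0.5 * hist["loss"].iloc[0]
        assert {"max_abs_error", "max_prop_error"} <= set(hist.columns)

    def test_predictions_on_simplex(self, toy_model, toy_training):
        _, _, _, sets = toy_training
        preds = predict(toy_model, sets["test"].expr)
        np.testing.assert_allclose(preds.weights.sum(axis=1), 100.0,
                                   atol=1e-6)
        assert np.all(preds.weights >= 0)

    def test_duplicate_input_gives_identical_output(self, toy_model,
                                                    toy_training):
        _, _, _, sets = toy_training
        expr = sets["test"].expr
        dup = ExpressionMatrix(
            np.column_stack([expr.values[:, 0], expr.values[:, 0]]),
            expr.gene_ids, ["d1", "d2"], expr.unit)
        preds = predict(toy_model, dup)
        np.testing.assert_allclose(preds.weights[0], preds.weights[1])

    def test_separable_types_classified_correctly(self, toy_model,
                                                  toy_training):
        em, ann, split, sets = toy_training
        test = sets["test"]
        onehot = np.isin(test.truth.weights, [0.0, 100.0]).all(axis=1)
        preds = predict(toy_model, test.expr)
        pred_type = preds.weights[onehot].argmax(axis=1)
        true_type = test.truth.weights[onehot].argmax(axis=1)
        assert (pred_type == true_type).mean() >= 0.95

    def test_same_seed_same_trajectory(self, toy_training):
        _, _, _, sets = toy_training
        cfg = ModelConfig(hidden_sizes=[16], epochs=3, batch_size=32, seed=11)
        h1 = train(cfg, sets["train"]).history
        h2 = train(cfg, sets["train"]).history
        np.testing.assert_allclose(h1["loss"], h2["loss"])


class TestCalibrateSqrt:
    def test_uniform_row_unchanged(self):
        ps = ProportionSet(np.full((1, 4), 25.0), list("ABCD"), ["s"])
        np.testing.assert_allclose(calibrate_sqrt(ps).weights, 25.0)

    def test_worked_example_81_19(self):
        ps = ProportionSet(np.array([[81.0, 19.0]]), ["A", "B"], ["s"])
        out = calibrate_sqrt(ps)
        np.testing.assert_allclose(out.weights, [[67.37, 32.63]], atol=0.01)

    def test_onehot_unchanged(self):
        ps = ProportionSet(np.array([[0.0, 100.0]]), ["A", "B"], ["s"])
        np.testing.assert_allclose(calibrate_sqrt(ps).weights,
                                   [[0.0, 100.0]])

    def test_rank_order_preserved(self):
        rng = np.random.default_rng(1)
        w = rng.dirichlet(np.ones(5), size=50) * 100
        ps = ProportionSet(w, list("ABCDE"), [f"s{i}" for i in range(50)])
        out = calibrate_sqrt(ps)
        for i in range(50):
            np.testing.assert_array_equal(np.argsort(w[i]),
                                          np.argsort(out.weights[i]))


class TestGridSearch:
    def test_product_size_and_ranking(self, toy_training):
        _, _, _, sets = toy_training
        space = {"loss": ["kld", "mse"], "hidden_sizes": [[8], [16, 16]]}
        base = ModelConfig(epochs=3, batch_size=32)
        df = grid_search(space, sets["train"], n_bulk=120, split=0.7,
                         seed=1, base_config=base)
        assert len(df) == 4
        assert df["val_loss"].is_monotonic_increasing

    def test_reproducible_under_seed(self, toy_training):
        _, _, _, sets = toy_training
        space = {"hidden_sizes": [[8], [12]]}
        base = ModelConfig(epochs=2, batch_size=32)
        d1 = grid_search(space, sets["train"], n_bulk=100, seed=2,
                         base_config=base)
        d2 = grid_search(space, sets["train"], n_bulk=100, seed=2,
                         base_config=base)
        np.testing.assert_allclose(d1["val_loss"], d2["val_loss"])

    def test_empty_space_rejected(self, toy_training):
        _, _, _, sets = toy_training
        with pytest.raises(ValueError, match="empty"):
            grid_search({}, sets["train"])


class TestSerialization:
    def test_save_load_predict_identity(self, toy_model, toy_training,
                                        tmp_path):
        _, _, _, sets = toy_training
        save_model(toy_model, str(tmp_path / "model"))
        back = load_model(str(tmp_path / "model"))
        assert back.gene_list == toy_model.gene_list
        assert back.cell_types == toy_model.cell_types
        p1 = predict(toy_model, sets["test"].expr)
        p2 = predict(back, sets["test"].expr)
        np.testing.assert_allclose(p1.weights, p2.weights, atol=1e-6)

    def test_tampered_manifest_fails(self, toy_model, tmp_path):
        import json
        save_model(toy_model, str(tmp_path / "model"))
        mpath = tmp_path / "model" / "manifest.json"
        manifest = json.loads(mpath.read_text())
        manifest["format_version"] = 99
        mpath.write_text(json.dumps(manifest))
        with pytest.raises(ValueError, match="version"):
            load_model(str(tmp_path / "model"))
        manifest["format_version"] = 1
        manifest["gene_list"] = manifest["gene_list"][:3]
        mpath.write_text(json.dumps(manifest))
        with pytest.raises(ValueError):
            load_model(str(tmp_path / "model"))
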