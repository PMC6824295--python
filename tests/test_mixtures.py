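import numpy as np
import pandas as pd
import pytest

from scdeconv.io import ExpressionMatrix
from scdeconv.mixtures import (
    SCHEMES,
    ProportionSet,
    split_cells,
    default_uniform_limits,
    gen_proportions,
    build_bulk,
    onehot_singlecell_samples,
    concat_pseudobulk,
    assemble_training_sets,
)


@pytest.fixture(scope="module")
def dataset():
    """40 cells, 2 types, distinctive block expression."""
    rng = np.random.default_rng(21)
    n_per = 20
    vals_a = rng.poisson(8.0, size=(10, n_per)).astype(float) + 1
    vals_b = rng.poisson(8.0, size=(10, n_per)).astype(float) + 1
    vals_a[5:, :] = 0.1
    vals_b[:5, :] = 0.1
    values = np.hstack([vals_a, vals_b])
    ids = [f"a{i}" for i in range(n_per)] + [f"b{i}" for i in range(n_per)]
    em = ExpressionMatrix(values, [f"g{i}" for i in range(10)], ids)
    ann = pd.DataFrame({"cell_id": ids,
                        "cell_type": ["A"] * n_per + ["B"] * n_per,
                        "origin": "real"})
    return em, ann


class TestSplit:
    def test_rounding_per_type(self, dataset):
        em, ann = dataset
        split = split_cells(ann, 0.65, seed=0)
        for t in ("A", "B"):
            ids = ann.loc[ann.cell_type == t, "cell_id"]
            n_train = (split.loc[ids] == "train").sum()
            assert n_train == 13  # round(20 * 0.65)
            assert (split.loc[ids] == "test").sum() == 7

    def test_partitions_disjoint_and_exhaustive(self, dataset):
        em, ann = dataset
        split = split_cells(ann, 0.65, seed=1)
        assert set(split.index) == set(ann.cell_id)
        assert set(split.unique()) == {"train", "test"}

    def test_determinism(self, dataset):
        em, ann = dataset
        a = split_cells(ann, 0.65, seed=5)
        b = split_cells(ann, 0.65, seed=5)
        assert (a == b).all()

    def test_singleton_type_instructs_oversampling(self):
        ann = pd.DataFrame({"cell_id": ["c1", "c2", "c3"],
                            "cell_type": ["A", "A", "B"]})
        with pytest.raises(ValueError, match="oversample"):
            split_cells(ann, 0.65, seed=0)


class TestGenProportions:
    @pytest.mark.parametrize("scheme", SCHEMES)
    def test_rows_sum_to_100(self, scheme):
        ps = gen_proportions(list("ABCD"), 200, scheme, seed=3)
        np.testing.assert_allclose(ps.weights.sum(axis=1), 100.0, atol=1e-9)
        assert np.all(ps.weights >= 0)

    @pytest.mark.parametrize("scheme", SCHEMES)
    def test_single_type_is_always_100(self, scheme):
        ps = gen_proportions(["only"], 20, scheme, seed=0)
        np.testing.assert_allclose(ps.weights, 100.0)

    def test_dirichlet_mean_matches_theory(self):
        k, n = 5, 10_000
        ps = gen_proportions(list("ABCDE"), n, "DS5_dirichlet",
                             alpha=1.0, seed=4)
        # Dir(1,...,1): E[w] = 100/k, var = 100^2 (k-1)/(k^2 (k+1))
        se = np.sqrt(100.0**2 * (k - 1) / (k**2 * (k + 1)) / n)
        means = ps.weights.mean(axis=0)
        assert np.all(np.abs(means - 100.0 / k) < 3 * se)

    def test_norep_rejects_duplicate_vectors(self):
        ps = gen_proportions(list("AB"), 500, "DS3_norep", seed=5)
        keys = {tuple(np.round(r, 1)) for r in ps.weights}
        assert len(keys) == 500

    def test_permuted_scheme_shuffles_within_rows(self):
        base = gen_proportions(list("ABCD"), 300, "DS1_uniform",
                               limits=np.array([[0, 5], [0, 10], [0, 50],
                                                [50, 100]]), seed=6)
        perm = gen_proportions(list("ABCD"), 300, "DS2_uniform_permuted",
                               limits=np.array([[0, 5], [0, 10], [0, 50],
                                                [50, 100]]), seed=6)
        # permutation evens out the per-column means relative to DS1
        spread_base = np.ptp(base.weights.mean(axis=0))
        spread_perm = np.ptp(perm.weights.mean(axis=0))
        assert spread_perm < spread_base / 2

    def test_infeasible_limits_rejected(self):
        with pytest.raises(ValueError, match="infeasible"):
            gen_proportions(list("AB"), 5, "DS1_uniform",
                            limits=np.zeros((2, 2)), seed=0)

    def test_default_limits_cap_and_scale(self, dataset):
        _, ann = dataset
        limits = default_uniform_limits(ann, ["A", "B"])
        np.testing.assert_allclose(limits[:, 0], 0)
        np.testing.assert_allclose(limits[:, 1], [100, 100])  # 2*50% capped


class TestBuildBulk:
    def test_manifest_has_exactly_cells_per_sample(self, dataset):
        em, ann = dataset
        split = split_cells(ann, 0.65, seed=0)
        props = gen_proportions(["A", "B"], 20, "DS5_dirichlet", seed=1)
        pb = build_bulk(em, ann, split, "train", props, 100, seed=2)
        assert all(len(m) == 100 for m in pb.cell_manifest)

    def test_column_equals_weighted_sum_of_manifest(self, dataset):
        """Mixture oracle: each bulk column is the brute-force mean of its
        manifest cells (up to the TPM rescale)."""
        em, ann = dataset
        split = split_cells(ann, 0.65, seed=0)
        props = gen_proportions(["A", "B"], 15, "DS1_uniform", seed=3)
        pb = build_bulk(em, ann, split, "train", props, 100, seed=4)
        col_of = {c: i for i, c in enumerate(em.obs_ids)}
        for s in range(pb.n_samples):
            brute = em.values[:, [col_of[c] for c in pb.cell_manifest[s]]] \
                .mean(axis=1)
            brute = brute / brute.sum() * 1e6
            np.testing.assert_allclose(pb.expr.values[:, s], brute, rtol=1e-9)

    def test_one_hot_props_average_single_type(self, dataset):
        em, ann = dataset
        split = split_cells(ann, 0.65, seed=0)
        props = ProportionSet(np.array([[100.0, 0.0]]), ["A", "B"], ["s0"])
        pb = build_bulk(em, ann, split, "train", props, 100, seed=5)
        assert all(c.startswith("a") for c in pb.cell_manifest[0])
        np.testing.assert_allclose(pb.truth.weights, [[100.0, 0.0]])

    def test_realized_truth_within_rounding_bound(self, dataset):
        em, ann = dataset
        split = split_cells(ann, 0.65, seed=0)
        props = gen_proportions(["A", "B"], 50, "DS5_dirichlet", seed=6)
        pb = build_bulk(em, ann, split, "train", props, 100, seed=7)
        assert np.all(np.abs(pb.truth.weights - props.weights) <= 100 / 100 + 1e-9)

    def test_manifest_cells_stay_in_partition(self, dataset):
        em, ann = dataset
        split = split_cells(ann, 0.65, seed=0)
        props = gen_proportions(["A", "B"], 10, "DS5_dirichlet", seed=8)
        pb = build_bulk(em, ann, split, "test", props, 100, seed=9)
        test_ids = set(split.index[split == "test"])
        assert all(set(m) <= test_ids for m in pb.cell_manifest)

    def test_type_missing_from_partition_is_error(self, dataset):
        em, ann = dataset
        split = pd.Series("train", index=ann.cell_id)
        split.loc[ann.loc[ann.cell_type == "B", "cell_id"]] = "test"
        props = gen_proportions(["A", "B"], 5, "DS5_dirichlet", seed=0)
        with pytest.raises(ValueError, match="'B' has no cells"):
            build_bulk(em, ann, split, "train", props, 100, seed=0)


class TestOnehotAndAssemble:
    def test_onehot_truth_rows(self, dataset):
        em, ann = dataset
        split = split_cells(ann, 0.65, seed=0)
        pb = onehot_singlecell_samples(em, ann, split, "train")
        assert pb.n_samples == 26  # 13 per type
        np.testing.assert_allclose(pb.truth.weights.sum(axis=1), 100.0)
        assert np.all(np.isin(pb.truth.weights, [0.0, 100.0]))
        # the one-hot column of a type-A cell carries its full weight on A
        a_col = pb.truth.sample_ids.index(
            next(c for c in pb.truth.sample_ids if c.startswith("a")))
        assert pb.truth.weights[a_col, 0] == 100.0

    def test_concat_preserves_alignment(self, dataset):
        em, ann = dataset
        split = split_cells(ann, 0.65, seed=0)
        props = gen_proportions(["A", "B"], 8, "DS5_dirichlet", seed=1)
        pb = build_bulk(em, ann, split, "train", props, 100, seed=2)
        oh = onehot_singlecell_samples(em, ann, split, "train")
        both = concat_pseudobulk([pb, oh])
        assert both.n_samples == pb.n_samples + oh.n_samples
        assert both.truth.sample_ids == both.expr.obs_ids

    def test_assemble_counts_and_no_leakage(self, dataset):
        em, ann = dataset
        split = split_cells(ann, 0.65, seed=0)
        sets = assemble_training_sets(em, ann, split, n_train=12, n_test=6,
                                      seed=3)
        # 5 schemes x 12 bulk + 26 one-hot training cells
        assert sets["train"].n_samples == 5 * 12 + 26
        assert sets["test"].n_samples == 5 * 6 + 14
        train_cells = {c for m in sets["train"].cell_manifest for c in m}
        test_cells = {c for m in sets["test"].cell_manifest for c in m}
        assert not (train_cells & test_cells)

    def test_assemble_reproducible_under_seed(self, dataset):
        em, ann = dataset
        split = split_cells(ann, 0.65, seed=0)
        a = assemble_training_sets(em, ann, split, n_train=5, n_test=3, seed=9)
        b = assemble_training_sets(em, ann, split, n_train=5, n_test=3, seed=9)
        np.testing.assert_array_equal(a["train"].expr.values,
                                      b["train"].expr.values)
        assert a["train"].truth.sample_ids == b["train"].truth.sample_ids
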