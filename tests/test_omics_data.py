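import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from caencoder.omics_data import (CategoricalEncoding, OmicsDataError,
                                  OmicsModality, concat_features,
                                  encode_categoricals, load_modality,
                                  make_folds, preprocess_fold,
                                  zscore_fit_transform)


def _write(tmp_path, text, name="mod.tsv"):
    p = tmp_path / name
    p.write_text(text)
    return str(p)


class TestLoadModality:
    def test_reads_tsv_with_shape_and_row_order(self, tmp_path):
        path = _write(tmp_path, "sample_id\tf1\tf2\tf3\n"
                                "s1\t1\t2\t3\ns2\t4\t5\t6\ns3\t7\t8\t9\ns4\t0\t1\t2\n")
        mod = load_modality(path, id_column="sample_id", name="cnv")
        assert mod.values.shape == (4, 3)
        assert mod.sample_ids == ["s1", "s2", "s3", "s4"]
        assert mod.feature_names == ["f1", "f2", "f3"]
        assert mod.values[0].tolist() == [1.0, 2.0, 3.0]

    def test_duplicate_sample_id_rejected(self, tmp_path):
        path = _write(tmp_path, "sample_id,f1\ns1,1\ns1,2\n", name="mod.csv")
        with pytest.raises(OmicsDataError, match="duplicate sample id"):
            load_modality(path, id_column="sample_id")

    def test_id_column_only_rejected(self, tmp_path):
        path = _write(tmp_path, "sample_id\ns1\ns2\n")
        with pytest.raises(OmicsDataError, match="no feature columns"):
            load_modality(path, id_column="sample_id")

    def test_missing_file_rejected(self):
        with pytest.raises(OmicsDataError, match="not found"):
            load_modality("/nonexistent/x.csv", id_column="sample_id")


class TestEncodeCategoricals:
    def _cat_modality(self):
        vals = np.array([["gain", 1.0], ["loss", 2.0], ["neutral", 3.0],
                         ["gain", 4.0]], dtype=object)
        return OmicsModality(name="cnv", values=vals,
                             feature_names=["state", "score"],
                             sample_ids=["a", "b", "c", "d"])

    def test_sorted_level_ordinal_codes(self):
        mod, enc = encode_categoricals(self._cat_modality())
        # lexicographic: gain=0, loss=1, neutral=2
        assert enc.column_levels["state"] == {"gain": 0, "loss": 1, "neutral": 2}
        assert mod.values[:, 0].tolist() == [0.0, 1.0, 2.0, 0.0]
        assert mod.values.dtype == float

    def test_all_numeric_returned_unchanged(self):
        vals = np.arange(8.0).reshape(4, 2)
        mod = OmicsModality(name="m", values=vals, feature_names=["a", "b"],
                            sample_ids=list("wxyz"))
        out, enc = encode_categoricals(mod)
        assert out is mod
        assert enc.column_levels == {}

    def test_unseen_level_raises_with_column_and_level(self):
        _, enc = encode_categoricals(self._cat_modality())
        test = OmicsModality(
            name="cnv",
            values=np.array([["amplified", 0.0]], dtype=object),
            feature_names=["state", "score"], sample_ids=["t1"])
        with pytest.raises(OmicsDataError, match="'amplified'.*'state'"):
            encode_categoricals(test, encoding=enc)


class TestZScore:
    def test_fit_rows_have_mean_zero_sd_one(self, tiny_dataset):
        mod = tiny_dataset.modalities[0]
        out, rec = zscore_fit_transform(mod, fit_indices=range(8))
        fit = out.values[:8]
        np.testing.assert_allclose(fit.mean(axis=0), 0, atol=1e-9)
        np.testing.assert_allclose(fit.std(axis=0, ddof=0), 1, atol=1e-9)

    def test_population_sd_on_1_2_3(self):
        mod = OmicsModality(name="m", values=np.array([[1.0], [2.0], [3.0]]),
                            feature_names=["f"], sample_ids=["a", "b", "c"])
        out, rec = zscore_fit_transform(mod, fit_indices=[0, 1, 2])
        np.testing.assert_allclose(out.values[:, 0], [-1.2247, 0.0, 1.2247],
                                   atol=1e-4)
        assert rec.sd[0] == pytest.approx(np.sqrt(2.0 / 3.0))

    def test_constant_column_maps_to_zeros_with_flag(self):
        mod = OmicsModality(name="m", values=np.full((4, 1), 3.3),
                            feature_names=["f"], sample_ids=list("abcd"))
        out, rec = zscore_fit_transform(mod, fit_indices=[0, 1, 2, 3])
        assert np.all(out.values == 0.0)
        assert rec.sd[0] == 0.0

    def test_empty_fit_indices_rejected(self, tiny_dataset):
        with pytest.raises(OmicsDataError, match="empty"):
            zscore_fit_transform(tiny_dataset.modalities[0], fit_indices=[])

    @settings(deadline=None, derandomize=True)
    @given(st.integers(min_value=0, max_value=2 ** 31 - 1))
    def test_stored_record_reproduces_joint_transform_on_heldout(self, seed):
        rng = np.random.default_rng(seed)
        vals = rng.normal(size=(10, 3)) * rng.uniform(0.5, 3.0, size=3)
        mod = OmicsModality(name="m", values=vals,
                            feature_names=["a", "b", "c"],
                            sample_ids=[f"s{i}" for i in range(10)])
        fit_idx = [0, 1, 2, 3, 4, 5]
        out, rec = zscore_fit_transform(mod, fit_indices=fit_idx)
        np.testing.assert_allclose(rec.transform(vals[6:]), out.values[6:],
                                   atol=1e-9)


class TestMakeFolds:
    def _balanced(self, n=100):
        from caencoder.synthetic_data import SyntheticSpec, generate
        return generate(SyntheticSpec(
            n_classes=2, samples_per_class=(n // 2, n // 2), modality_dims=(4,),
            latent_factor_dim=2, class_separation=3.0, categorical_fraction=0.0,
            seed=3))

    def test_k5_repeats5_yields_25_splits_of_test_size_20(self):
        ds = self._balanced(100)
        folds = make_folds(ds, k=5, repeats=5, seed=0)
        assert len(folds) == 25
        assert all(len(f.test_indices) == 20 for f in folds)
        for f in folds:
            assert set(f.train_indices) | set(f.test_indices) == set(range(100))

    def test_same_seed_gives_identical_partitions(self):
        ds = self._balanced(60)
        a = make_folds(ds, k=5, repeats=2, seed=9)
        b = make_folds(ds, k=5, repeats=2, seed=9)
        for fa, fb in zip(a, b):
            assert fa.train_indices.tolist() == fb.train_indices.tolist()
            assert fa.test_indices.tolist() == fb.test_indices.tolist()

    def test_class_smaller_than_k_is_rejected_by_name(self):
        from caencoder.synthetic_data import SyntheticSpec, generate
        ds = generate(SyntheticSpec(
            n_classes=2, samples_per_class=(20, 3), modality_dims=(4,),
            latent_factor_dim=2, class_separation=3.0, categorical_fraction=0.0,
            seed=3))
        with pytest.raises(OmicsDataError, match="class2"):
            make_folds(ds, k=5, repeats=1, seed=0)

    def test_stratification_within_one_sample_of_global_proportions(self):
        ds = self._balanced(100)
        n_class = {c: np.sum(ds.labels == c) for c in ds.class_names}
        for f in make_folds(ds, k=5, repeats=3, seed=1):
            te = ds.labels[f.test_indices]
            for c in ds.class_names:
                expected = n_class[c] * len(te) / 100
                assert abs(np.sum(te == c) - expected) <= 1


class TestConcatFeatures:
    def test_length_is_sum_of_modality_dims(self, tiny_dataset):
        v = concat_features(tiny_dataset, [2, 2, 2])
        assert len(v) == 5 + 4 + 3

    def test_leading_block_comes_from_first_modality_source(self, tiny_dataset):
        v = concat_features(tiny_dataset, [1, 5, 9])
        np.testing.assert_array_equal(v[:5], tiny_dataset.modalities[0].values[1])
        np.testing.assert_array_equal(v[5:9], tiny_dataset.modalities[1].values[5])

    def test_single_modality_is_identity(self, tiny_dataset):
        ds = tiny_dataset.subset_modalities(["mrna"])
        v = concat_features(ds, [4])
        np.testing.assert_array_equal(v, ds.modalities[0].values[4])

    def test_out_of_range_source_rejected(self, tiny_dataset):
        with pytest.raises(OmicsDataError, match="out of range"):
            concat_features(tiny_dataset, [0, 0, 99])

    def test_distinct_sources_give_distinct_vectors(self, tiny_dataset):
        seen = set()
        for i in range(tiny_dataset.n_samples):
            seen.add(tuple(concat_features(tiny_dataset, [i, i, i])))
        assert len(seen) == tiny_dataset.n_samples


def test_preprocess_fold_fits_on_train_rows_only(tiny_dataset):
    folds = make_folds(tiny_dataset, k=3, repeats=1, seed=0)
    fold = folds[0]
    processed, encs, stds = preprocess_fold(tiny_dataset, fold)
    for mod in processed.modalities:
        tr = mod.values[fold.train_indices]
        np.testing.assert_allclose(tr.mean(axis=0), 0, atol=1e-9)
        np.testing.assert_allclose(tr.std(axis=0, ddof=0), 1, atol=1e-9)
        # held-out rows use train statistics, so they are not exactly standard
        te = mod.values[fold.test_indices]
        assert not np.allclose(te.mean(axis=0), 0, atol=1e-12)
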