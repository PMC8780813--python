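"""Splitting protocol, dense and convolutional training, persistence."""

import numpy as np
import pytest
from dataclasses import replace

from sndsubtype import (
    CDNNSpec,
    DNNSpec,
    LabelTable,
    ReferenceGeneList,
    SplitSpec,
    embed_matrix,
    load_model,
    predict,
    save_model,
    snd_transform_matrix,
    split_dataset,
    train_cdnn,
    train_dnn,
)
from sndsubtype.classifiers import accuracy
from sndsubtype.errors import ArgumentError, ModelFormatError
from sndsubtype.synthetic import nearest_centroid_accuracy

from conftest import int_labels

SMALL_DNN = DNNSpec(hidden_sizes=(64, 32), learning_rate=0.01, epochs=8,
                    iterations=5, seed=0)


class TestSplit:
    ids = [f"s{i:03d}" for i in range(100)]

    def test_protocol_sizes_100_samples(self):
        train, test, val = split_dataset(self.ids, None, SplitSpec(seed=1))
        # 10% validation first, then 70/30 of the remaining 90
        assert (len(train), len(test), len(val)) == (63, 27, 10)
        assert sorted(train + test + val) == sorted(self.ids)
        assert not (set(train) & set(test) or set(train) & set(val)
                    or set(test) & set(val))

    def test_same_seed_reproduces_partition(self):
        a = split_dataset(self.ids, None, SplitSpec(seed=42))
        b = split_dataset(self.ids, None, SplitSpec(seed=42))
        assert a == b
        c = split_dataset(self.ids, None, SplitSpec(seed=43))
        assert a != c

    def test_zero_validation_gives_two_way_split(self):
        train, test, val = split_dataset(
            self.ids, None, SplitSpec(validate_fraction=0.0, seed=0)
        )
        assert (len(train), len(test), len(val)) == (70, 30, 0)

    def test_stratified_preserves_class_proportions(self):
        labels = LabelTable(self.ids, ["A", "B", "C", "D"] * 25)
        train, test, val = split_dataset(
            self.ids, labels, SplitSpec(seed=3, stratified=True)
        )
        mapping = labels.as_mapping()
        for part, frac in ((train, 0.63), (test, 0.27), (val, 0.10)):
            for cls in "ABCD":
                count = sum(mapping[s] == cls for s in part)
                assert abs(count - frac * 25) <= 1

    def test_bad_fractions_rejected(self):
        with pytest.raises(ArgumentError):
            SplitSpec(validate_fraction=1.0)
        with pytest.raises(ArgumentError):
            SplitSpec(train_fraction_of_remainder=0.0)


@pytest.fixture(scope="module")
def separable_features(separable_cohort):
    table = separable_cohort.latent
    rgl = ReferenceGeneList(tuple(table.gene_ids))
    snd = snd_transform_matrix(table, rgl)
    labels = separable_cohort.labels
    train, test, _ = split_dataset(
        snd.sample_ids, labels, SplitSpec(validate_fraction=0.0, seed=7,
                                          stratified=True)
    )
    pos = {s: i for i, s in enumerate(snd.sample_ids)}
    return snd, labels, train, test, pos


class TestDNN:
    def test_separable_cohort_reaches_high_test_accuracy(
        self, separable_cohort, separable_features
    ):
        snd, labels, train, test, pos = separable_features
        # the oracle certifies the cohort is separable before the net runs
        X = separable_cohort.latent.values.T
        y = int_labels(labels)
        tr = [pos[s] for s in train]
        te = [pos[s] for s in test]
        assert nearest_centroid_accuracy((X[tr], y[tr]), (X[te], y[te])) >= 0.99

        from sndsubtype.snd import SNDMatrix

        sub = SNDMatrix(rgl=snd.rgl, sample_ids=train, values=snd.values[:, tr])
        model = train_dnn(sub, labels.subset(train), SMALL_DNN)
        test_feats = SNDMatrix(rgl=snd.rgl, sample_ids=test, values=snd.values[:, te])
        test_acc = accuracy(model, test_feats, labels.subset(test), sample_ids=test)
        assert test_acc >= 0.95
        # predicting the training set is at least nearly as good
        train_acc = accuracy(model, sub, labels.subset(train), sample_ids=train)
        assert train_acc >= test_acc - 0.05
        assert model.training_log  # per-epoch losses recorded

    def test_single_class_training_rejected(self, separable_features):
        snd, labels, train, _, pos = separable_features
        ones = [s for s in train if labels.as_mapping()[s] == "C1"]
        from sndsubtype.snd import SNDMatrix

        sub = SNDMatrix(rgl=snd.rgl, sample_ids=ones,
                        values=snd.values[:, [pos[s] for s in ones]])
        with pytest.raises(ArgumentError, match="single class"):
            train_dnn(sub, labels.subset(ones), SMALL_DNN)

    def test_zero_epochs_rejected(self):
        with pytest.raises(ArgumentError):
            DNNSpec(epochs=0)

    def test_dropout_unsupported_by_dense_backend(self):
        with pytest.raises(ArgumentError, match="dropout"):
            DNNSpec(dropout=0.5)


@pytest.fixture(scope="module")
def trained_dnn(separable_features):
    snd, labels, train, test, pos = separable_features
    from sndsubtype.snd import SNDMatrix

    sub = SNDMatrix(rgl=snd.rgl, sample_ids=train,
                    values=snd.values[:, [pos[s] for s in train]])
    return train_dnn(sub, labels.subset(train), SMALL_DNN)


class TestPredict:
    def test_probabilities_normalized(self, trained_dnn, separable_features):
        snd, *_ = separable_features
        _, proba = predict(trained_dnn, snd)
        np.testing.assert_allclose(proba.sum(axis=1), 1.0, atol=1e-6)

    def test_sample_order_equivariance(self, trained_dnn, separable_features):
        snd, *_ = separable_features
        x = snd.values.T
        labels_fwd, _ = predict(trained_dnn, x)
        labels_rev, _ = predict(trained_dnn, x[::-1])
        assert labels_fwd == labels_rev[::-1]

    def test_dimension_mismatch_names_expected_and_received(self, trained_dnn):
        with pytest.raises(ArgumentError, match="100"):
            predict(trained_dnn, np.zeros((3, 55)))


class TestCDNN:
    def test_separable_images_reach_high_test_accuracy(self, separable_features):
        snd, labels, train, test, pos = separable_features
        images = embed_matrix(snd)
        spec = CDNNSpec(seed=7)
        model = train_cdnn(images[[pos[s] for s in train]], labels.subset(train),
                           spec=spec)
        acc = accuracy(model, images[[pos[s] for s in test]],
                       labels.subset(test), sample_ids=test)
        assert acc >= 0.95

    def test_single_pixel_images_are_uninformative(self):
        # 4 balanced classes, a single non-signature gene per sample:
        # accuracy must hover at chance
        rng = np.random.default_rng(0)
        n = 200
        ids = [f"s{i}" for i in range(n)]
        labels = LabelTable(ids, [("A", "B", "C", "D")[i % 4] for i in range(n)])
        images = rng.normal(size=(n, 1, 1))
        model = train_cdnn(images[: n // 2], labels.subset(ids[: n // 2]),
                           spec=CDNNSpec(epochs=10, seed=0))
        acc = accuracy(model, images[n // 2 :], labels.subset(ids[n // 2 :]),
                       sample_ids=ids[n // 2 :])
        assert 0.25 - 0.15 <= acc <= 0.25 + 0.15

    def test_inconsistent_image_sides_rejected(self):
        from sndsubtype import embed_2d

        images = [embed_2d(np.arange(9.0)), embed_2d(np.arange(16.0))]
        labels = LabelTable(["a", "b"], ["X", "Y"])
        with pytest.raises(ArgumentError, match="sides"):
            train_cdnn(images, labels, spec=CDNNSpec(epochs=1))


class TestPersistence:
    def test_round_trip_predictions_bit_identical(
        self, trained_dnn, separable_features, tmp_path
    ):
        snd, *_ = separable_features
        path = tmp_path / "model.bin"
        save_model(trained_dnn, path)
        back = load_model(path)
        labels_a, proba_a = predict(trained_dnn, snd)
        labels_b, proba_b = predict(back, snd)
        assert labels_a == labels_b
        np.testing.assert_array_equal(proba_a, proba_b)
        assert back.spec == trained_dnn.spec

    def test_kind_mismatch_rejected(self, trained_dnn, tmp_path):
        path = tmp_path / "model.bin"
        save_model(trained_dnn, path)
        with pytest.raises(ModelFormatError, match="dnn"):
            load_model(path, kind="cdnn")

    def test_corrupt_file_rejected(self, tmp_path):
        path = tmp_path / "junk.bin"
        path.write_bytes(b"not a model at all")
        with pytest.raises(ModelFormatError):
            load_model(path)

    def test_version_mismatch_rejected(self, trained_dnn, tmp_path):
        import pickle

        from sndsubtype import classifiers

        path = tmp_path / "model.bin"
        save_model(trained_dnn, path)
        payload = pickle.loads(path.read_bytes())
        payload["version"] = 99
        path.write_bytes(pickle.dumps(payload))
        with pytest.raises(ModelFormatError, match="version"):
            load_model(path)
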