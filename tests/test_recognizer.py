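"""Classifier: split contract, training determinism, separable-regime accuracy.

The independent oracle for the separable regime is a nearest-centroid
classifier: when the per-motion amplitude profiles are far apart
relative to window-RMS noise, nearest-centroid attains 100%, so the
network is required to reach >= 99%.
"""

import numpy as np
import pytest

from semglove import (
    ClassifierConfig,
    FeatureMatrix,
    InsufficientDataError,
    Motion,
    SyntheticConfig,
    concatenate,
    generate_dataset,
    predict,
    rms_features,
    split_dataset,
    train_classifier,
)
from semglove.motions import MOTION_INDEX, MOTION_ORDER


def labeled_features(seed=0, trials=3, trial_s=4.0):
    cfg = SyntheticConfig(trial_s=trial_s, trials_per_motion=trials)
    data = generate_dataset(cfg, seed=seed)
    feats = [rms_features(concatenate(v)) for v in data.values()]
    return FeatureMatrix(
        np.vstack([f.values for f in feats]),
        np.concatenate([f.labels for f in feats]),
    )


@pytest.fixture(scope="module")
def features():
    return labeled_features(seed=1)


class TestSplitDataset:
    def test_stratified_70_30(self, features):
        train, test = split_dataset(features, 0.7, seed=0)
        assert train.n_windows + test.n_windows == features.n_windows
        for code in "ERSF":
            n_tr = int(np.sum(train.labels == code))
            n_te = int(np.sum(test.labels == code))
            total = int(np.sum(features.labels == code))
            assert abs(n_tr - 0.7 * total) <= 1  # stratified to within rounding
            assert n_tr + n_te == total

    def test_disjoint_union_of_rows(self, features):
        train, test = split_dataset(features, 0.7, seed=0)
        merged = np.vstack([train.values, test.values])
        assert (
            np.unique(merged, axis=0).shape == np.unique(features.values, axis=0).shape
        )

    def test_full_train_fraction_gives_empty_test(self, features):
        train, test = split_dataset(features, 1.0, seed=0)
        assert train.n_windows == features.n_windows
        assert test.n_windows == 0

    def test_same_seed_same_split(self, features):
        a, _ = split_dataset(features, 0.7, seed=5)
        b, _ = split_dataset(features, 0.7, seed=5)
        np.testing.assert_array_equal(a.values, b.values)

    def test_thin_class_rejected(self):
        fm = FeatureMatrix(np.ones((3, 4)), np.array(["E", "E", "R"]))
        with pytest.raises(InsufficientDataError):
            split_dataset(fm, 0.7, seed=0)


class TestTraining:
    def test_network_beats_99pct_in_separable_regime(self, features):
        train, test = split_dataset(features, 0.7, seed=0)
        model = train_classifier(train, ClassifierConfig(epochs=40, seed=0))
        pred, _ = predict(model, test)
        acc = np.mean([p.value == t for p, t in zip(pred, test.labels)])
        assert acc >= 0.99

        # independent oracle: nearest centroid attains 100% here
        centroids = {
            c: train.values[train.labels == c].mean(axis=0) for c in "ERSF"
        }
        nc_pred = [
            min(centroids, key=lambda c: np.linalg.norm(v - centroids[c]))
            for v in test.values
        ]
        assert np.mean([p == t for p, t in zip(nc_pred, test.labels)]) == 1.0

    def test_training_is_deterministic(self, features):
        train, _ = split_dataset(features, 0.7, seed=0)
        cfg = ClassifierConfig(epochs=5, seed=3)
        m1 = train_classifier(train, cfg)
        m2 = train_classifier(train, cfg)
        for w1, w2 in zip(m1.weights, m2.weights):
            np.testing.assert_array_equal(w1, w2)
        assert m1.train_accuracy == m2.train_accuracy

    def test_single_class_training_warns_and_predicts_that_class(self):
        fm = FeatureMatrix(
            np.abs(np.random.default_rng(0).standard_normal((40, 4))) + 1.0,
            np.array(["S"] * 40),
        )
        with pytest.warns(UserWarning, match="single class"):
            model = train_classifier(fm, ClassifierConfig(epochs=10, seed=0))
        pred, _ = predict(model, fm)
        assert all(p == Motion.SPHERICAL for p in pred)

    def test_row_order_permutation_barely_changes_accuracy(self, features):
        train, test = split_dataset(features, 0.7, seed=0)
        cfg = ClassifierConfig(epochs=20, seed=0)
        m1 = train_classifier(train, cfg)
        perm = np.random.default_rng(8).permutation(train.n_windows)
        shuffled = FeatureMatrix(train.values[perm], train.labels[perm])
        m2 = train_classifier(shuffled, cfg)
        accs = []
        for m in (m1, m2):
            pred, _ = predict(m, test)
            accs.append(np.mean([p.value == t for p, t in zip(pred, test.labels)]))
        assert abs(accs[0] - accs[1]) < 0.02

    def test_reported_sgd_variant_exposes_transposed_settings(self):
        cfg = ClassifierConfig.reported_sgd()
        assert cfg.momentum == pytest.approx(1e-6)
        assert cfg.decay == pytest.approx(0.9)


@pytest.fixture(scope="module")
def model(features):
    train, _ = split_dataset(features, 0.7, seed=0)
    return train_classifier(train, ClassifierConfig(epochs=20, seed=0))


class TestPredict:
    def test_probability_rows_are_simplices(self, model, features):
        probs = model.predict_proba(features)
        assert np.all(probs >= 0)
        np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-6)

    def test_batch_of_n_windows_gives_n_labels(self, model, features):
        labels, probs = predict(model, features)
        assert len(labels) == features.n_windows == probs.shape[0]

    def test_training_vectors_replay_their_labels(self, model, features):
        train, _ = split_dataset(features, 0.7, seed=0)
        pred, _ = predict(model, train)
        assert np.mean([p.value == t for p, t in zip(pred, train.labels)]) == 1.0

    def test_wrong_dimensionality_rejected(self, model):
        from semglove import InvalidConfigError

        with pytest.raises(InvalidConfigError):
            model.predict_proba(np.ones((3, 5)))

    def test_argmax_tie_resolves_to_lowest_canonical_index(self, model):
        # identical logits across classes -> argmax picks index 0 = E
        probs = np.full((1, 4), 0.25)
        idx = probs.argmax(axis=1)[0]
        assert MOTION_ORDER[idx] == Motion.EXTENSION

    def test_roundtrip_persistence(self, model, features, tmp_path):
        path = tmp_path / "model.json"
        model.save(path)
        from semglove import TrainedModel

        loaded = TrainedModel.load(path)
        np.testing.assert_allclose(
            loaded.predict_proba(features), model.predict_proba(features)
        )
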