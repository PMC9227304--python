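"""Split protocol, outlier screening, evaluation and the training loop."""

import numpy as np
import pytest

import ramancaps as rc
from ramancaps.imaging import SampleImage
from ramancaps.training import (
    SplitError,
    SplitSpec,
    TrainConfig,
    evaluate,
    screen_outliers,
    split_dataset,
    train,
)

# per-variety sample counts after the field study's outlier screening
FIELD_COUNTS = {
    "LJ47": 32, "KY131": 34, "LJ11": 32, "HH311": 34,
    "QJ1": 34, "SJ13": 34, "HJ313": 33,
}
VARIETY_LABELS = {"LJ47": 0, "KY131": 0, "LJ11": 0, "HH311": 0,
                  "QJ1": 1, "SJ13": 2, "HJ313": 2}


def make_images(counts, rng, scale=1.0):
    images = []
    for var, n in counts.items():
        for i in range(n):
            images.append(
                SampleImage(
                    pixels=scale * rng.normal(size=(28, 28)),
                    sample_id=f"{var}_{i}",
                    label=VARIETY_LABELS[var],
                    variety=var,
                )
            )
    return images


class TestSplit:
    def test_field_counts_give_177_train_56_test(self, rng):
        images = make_images(FIELD_COUNTS, rng)
        assert len(images) == 233
        tr, te = split_dataset(images, SplitSpec(per_variety_test=8, seed=0))
        assert len(te) == 56
        assert len(tr) == 177

    def test_split_is_a_partition(self, rng):
        images = make_images(FIELD_COUNTS, rng)
        tr, te = split_dataset(images, SplitSpec(per_variety_test=8, seed=3))
        ids = sorted(im.sample_id for im in tr) + sorted(im.sample_id for im in te)
        assert sorted(ids) == sorted(im.sample_id for im in images)
        assert not (set(i.sample_id for i in tr) & set(i.sample_id for i in te))

    def test_same_seed_same_partition(self, rng):
        images = make_images(FIELD_COUNTS, rng)
        a = split_dataset(images, SplitSpec(8, seed=5))
        b = split_dataset(images, SplitSpec(8, seed=5))
        assert [i.sample_id for i in a[1]] == [i.sample_id for i in b[1]]

    def test_every_variety_contributes_exactly_eight(self, rng):
        images = make_images(FIELD_COUNTS, rng)
        _, te = split_dataset(images, SplitSpec(8, seed=1))
        from collections import Counter

        assert Counter(im.variety for im in te) == {v: 8 for v in FIELD_COUNTS}

    def test_too_few_samples_names_variety(self, rng):
        images = make_images({"LJ47": 35, "QJ1": 30}, rng)
        with pytest.raises(SplitError, match="QJ1"):
            split_dataset(images, SplitSpec(per_variety_test=32, seed=0))


class TestScreenOutliers:
    def test_disabled_returns_input(self, rng):
        images = make_images({"LJ47": 5}, rng)
        kept, rejected = screen_outliers(images, enabled=False)
        assert kept == images and rejected == []

    def test_extreme_image_rejected(self, rng):
        base = np.abs(rng.normal(size=(28, 28))) + 1.0
        images = [
            SampleImage(base.copy(), sample_id=f"a{i}", label=0, variety="LJ47")
            for i in range(35)
        ]
        images.append(SampleImage(100 * base, sample_id="big", label=0, variety="LJ47"))
        kept, rejected = screen_outliers(images, enabled=True, z_threshold=3.0)
        assert rejected == ["big"]
        assert len(kept) == 35

    def test_zero_spread_keeps_all(self):
        base = np.ones((28, 28))
        images = [
            SampleImage(base.copy(), sample_id=f"a{i}", label=0, variety="LJ47")
            for i in range(6)
        ]
        kept, rejected = screen_outliers(images, enabled=True, z_threshold=3.0)
        assert len(kept) == 6 and rejected == []


class TestEvaluate:
    def _constant_classifier(self, images, labels):
        """Fit a trivially separable memorization problem."""
        clf = rc.CapsNetClassifier(
            conv1_channels=2, primary_channels=8, class_caps_dim=4,
            epochs=1, random_state=0,
        )
        clf.fit(images, labels)
        return clf

    def test_confusion_counts_conserve_n(self, rng):
        images = make_images({"LJ47": 4, "QJ1": 4, "SJ13": 4}, rng)
        clf = self._constant_classifier(images, [im.label for im in images])
        acc, cm = evaluate(clf, images)
        assert cm.sum() == len(images)
        assert 0.0 <= acc <= 100.0

    def test_majority_prediction_accuracy(self, rng):
        # a classifier that (untrained) predicts one class for everything
        # scores exactly that class's prevalence
        images = make_images({"LJ47": 4, "QJ1": 3, "SJ13": 3}, rng)
        clf = self._constant_classifier(images, [im.label for im in images])
        preds = clf.predict(images)
        if len(set(preds)) == 1:
            expect = 100.0 * sum(im.label == preds[0] for im in images) / len(images)
            acc, _ = evaluate(clf, images)
            assert acc == pytest.approx(expect)

    def test_empty_dataset_raises(self, rng):
        images = make_images({"LJ47": 3}, rng)
        clf = self._constant_classifier(images, [0, 0, 0])
        with pytest.raises(ValueError):
            evaluate(clf, [])


@pytest.fixture(scope="module")
def separable_images():
    # three classes with disjoint constant blocks: linearly separable
    rng = np.random.default_rng(0)
    images = []
    for k, var in enumerate(["LJ47", "QJ1", "SJ13"]):
        for i in range(10):
            px = 0.02 * rng.normal(size=(28, 28))
            px[:, 9 * k : 9 * k + 9] += 0.5
            images.append(
                SampleImage(px, sample_id=f"{var}_{i}", label=[0, 1, 2][k], variety=var)
            )
    return images


class TestTrainLoop:
    def test_report_has_one_record_per_epoch(self, separable_images):
        tr, te = split_dataset(separable_images, SplitSpec(per_variety_test=3, seed=0))
        rep = train(
            tr, te, TrainConfig(epochs=3, batch_size=8), seed=0,
            conv1_channels=4, primary_channels=8, class_caps_dim=4,
        )
        assert len(rep.records) == 3
        assert list(rep.records.columns) == ["epoch", "loss", "train_acc", "test_acc"]

    def test_separable_data_reaches_full_training_accuracy(self, separable_images):
        tr, te = split_dataset(separable_images, SplitSpec(per_variety_test=3, seed=0))
        rep = train(
            tr, te, TrainConfig(epochs=50, batch_size=8, learning_rate=3e-3), seed=0,
            conv1_channels=4, primary_channels=8, class_caps_dim=4,
        )
        assert rep.records.train_acc.max() == 100.0
        assert rep.best_test_acc > 60.0

    def test_training_is_deterministic(self, separable_images):
        tr, te = split_dataset(separable_images, SplitSpec(per_variety_test=3, seed=0))
        kw = dict(conv1_channels=4, primary_channels=8, class_caps_dim=4)
        r1 = train(tr, te, TrainConfig(epochs=3, batch_size=8), seed=7, **kw)
        r2 = train(tr, te, TrainConfig(epochs=3, batch_size=8), seed=7, **kw)
        assert r1.records.loss.tolist() == r2.records.loss.tolist()
        for k, arr in r1.params.as_dict().items():
            np.testing.assert_array_equal(arr, r2.params.as_dict()[k])

    def test_empty_train_set_raises(self):
        with pytest.raises(ValueError, match="empty"):
            train([], [], TrainConfig(epochs=1), seed=0)
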