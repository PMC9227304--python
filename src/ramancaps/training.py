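"""Training protocol: outlier screening, stratified per-variety split,
epoch loop with per-epoch train/test accuracy, early stopping at a
configured epoch.

Thin functional layer over :class:`~ramancaps.estimators.CapsNetClassifier`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics import accuracy_score, confusion_matrix

from .capsnet import CapsNetParams
from .estimators import CapsNetClassifier
from .imaging import SampleImage


class SplitError(ValueError):
    """A variety has too few samples for the requested test count."""


@dataclass(frozen=True)
class SplitSpec:
    """Stratified per-variety holdout: ``per_variety_test`` samples of
    every variety go to the test set."""

    per_variety_test: int = 8
    seed: int = 0

    def __post_init__(self) -> None:
        if self.per_variety_test < 1:
            raise ValueError("per_variety_test must be positive")


@dataclass(frozen=True)
class TrainConfig:
    """Schedule for the epoch loop."""

    epochs: int = 160
    batch_size: int = 16
    learning_rate: float = 3e-3
    optimizer_seed: int = 0
    eval_every: int = 1

    def __post_init__(self) -> None:
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")


@dataclass
class TrainReport:
    """Per-epoch records plus the best held-out epoch.

    ``records`` has one row per epoch with columns
    ``epoch, loss, train_acc, test_acc`` (accuracies in percent).
    """

    records: pd.DataFrame
    best_test_epoch: int
    best_test_acc: float
    params: CapsNetParams
    classifier: CapsNetClassifier = field(repr=False, default=None)

    def __post_init__(self) -> None:
        acc = self.records[["train_acc", "test_acc"]].to_numpy(dtype=float)
        finite = acc[np.isfinite(acc)]
        if len(finite) and (finite.min() < 0 or finite.max() > 100):
            raise ValueError("accuracies must lie in [0, 100]")


def screen_outliers(
    images: list[SampleImage], enabled: bool = False, z_threshold: float = 3.5
) -> tuple[list[SampleImage], list[str]]:
    """Drop images whose total pixel intensity is a robust outlier within
    their variety.

    The robust z-score uses the per-variety median and MAD (scaled by
    1.4826).  When the MAD is zero (a majority of identical totals) any
    total equal to the median is kept and any other total is treated as
    infinitely deviant; a fully identical variety therefore keeps all its
    images.  Disabled by default.
    """
    if not enabled:
        return list(images), []
    totals = np.array([im.pixels.sum() for im in images])
    varieties = np.array([im.variety for im in images])
    keep, rejected = [], []
    for var in np.unique(varieties):
        mask = varieties == var
        t = totals[mask]
        med = np.median(t)
        mad = 1.4826 * np.median(np.abs(t - med))
        if mad == 0:
            z = np.where(t == med, 0.0, np.inf)
        else:
            z = np.abs(t - med) / mad
        for im, zi in zip(np.array(images, dtype=object)[mask], z):
            (keep if zi <= z_threshold else rejected).append(im)
    rejected_ids = [im.sample_id for im in rejected]
    kept = [im for im in images if im.sample_id not in set(rejected_ids)]
    return kept, rejected_ids


def split_dataset(
    images: list[SampleImage], spec: SplitSpec = SplitSpec()
) -> tuple[list[SampleImage], list[SampleImage]]:
    """Per-variety stratified holdout split.

    Exactly ``spec.per_variety_test`` images of every variety are drawn
    uniformly at random (seeded) into the test list; the rest train.
    The two lists partition the input.
    """
    rng = np.random.default_rng(spec.seed)
    varieties = np.array([im.variety for im in images])
    test_idx: set[int] = set()
    for var in pd.unique(varieties):
        idx = np.flatnonzero(varieties == var)
        if len(idx) <= spec.per_variety_test:
            raise SplitError(
                f"variety {var!r} has {len(idx)} samples, cannot hold out "
                f"{spec.per_variety_test}"
            )
        test_idx.update(rng.choice(idx, size=spec.per_variety_test, replace=False))
    train = [im for i, im in enumerate(images) if i not in test_idx]
    test = [im for i, im in enumerate(images) if i in test_idx]
    return train, test


def train(
    train_set: list[SampleImage],
    test_set: list[SampleImage],
    train_cfg: TrainConfig = TrainConfig(),
    seed: int = 0,
    **net_kwargs,
) -> TrainReport:
    """Train the capsule network and report per-epoch accuracies.

    ``net_kwargs`` go to :class:`CapsNetClassifier` (e.g. channel widths,
    ``routing_iterations``).  Fully reproducible per seed.
    """
    if not train_set:
        raise ValueError("empty training set")
    clf = CapsNetClassifier(
        epochs=train_cfg.epochs,
        batch_size=train_cfg.batch_size,
        learning_rate=train_cfg.learning_rate,
        eval_every=train_cfg.eval_every,
        random_state=seed,
        **net_kwargs,
    )
    y_train = np.array([im.label for im in train_set])
    eval_set = None
    if test_set:
        eval_set = (test_set, np.array([im.label for im in test_set]))
    clf.fit(train_set, y_train, eval_set=eval_set)
    return TrainReport(
        records=clf.history_,
        best_test_epoch=clf.best_epoch_,
        best_test_acc=clf.best_test_acc_,
        params=clf.params_,
        classifier=clf,
    )


def evaluate(
    model: CapsNetClassifier | TrainReport, dataset: list[SampleImage]
) -> tuple[float, np.ndarray]:
    """Accuracy (percent) and confusion matrix (rows true, columns
    predicted) on a labeled image set."""
    if isinstance(model, TrainReport):
        model = model.classifier
    if not dataset:
        raise ValueError("cannot evaluate on an empty dataset")
    y_true = np.array([im.label for im in dataset])
    y_pred = model.predict(dataset)
    acc = 100.0 * accuracy_score(y_true, y_pred)
    cm = confusion_matrix(y_true, y_pred, labels=model.classes_)
    return float(acc), cm
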