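"""scikit-learn-style estimators wrapping the pipeline.

``CrestImageTransformer`` turns spectra into 784-feature vectors (the
flattened 28x28 crest images); ``CapsNetClassifier`` is the capsule
network as a fit/predict classifier.  Both compose with sklearn
pipelines and model selection.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin, TransformerMixin
from sklearn.utils.validation import check_is_fitted

from . import capsnet as cn
from .imaging import REFERENCE_SHIFTS, CrestConfig, SampleImage, image_from_spectrum
from .io import RamanSpectrum
from .preprocess import FilterSpec


class CrestImageTransformer(TransformerMixin, BaseEstimator):
    """Transform Raman spectra into flattened 28x28 crest pseudo-images.

    Accepts either a list of :class:`RamanSpectrum` or a 2-D intensity
    array (samples x grid points) together with a ``shifts`` axis.

    Parameters
    ----------
    reference_shifts : tuple of float
        The crest centers (cm^-1).
    first_wn, second_wn : float
        Normalized cutoffs of the two zero-phase filter passes.
    shifts : ndarray or None
        Shift axis for plain-array input; inferred from spectra otherwise.
    """

    def __init__(
        self,
        reference_shifts: tuple[float, ...] = REFERENCE_SHIFTS,
        points_before: int = 56,
        points_after: int = 55,
        filter_order: int = 2,
        first_wn: float = 0.002,
        second_wn: float = 0.03,
        normalize: bool = True,
        shifts: np.ndarray | None = None,
    ):
        self.reference_shifts = reference_shifts
        self.points_before = points_before
        self.points_after = points_after
        self.filter_order = filter_order
        self.first_wn = first_wn
        self.second_wn = second_wn
        self.normalize = normalize
        self.shifts = shifts

    def _crest_config(self) -> CrestConfig:
        return CrestConfig(
            reference_shifts=tuple(self.reference_shifts),
            points_before=self.points_before,
            points_after=self.points_after,
        )

    def fit(self, X, y=None):
        if len(X) and isinstance(X[0], RamanSpectrum):
            self.shifts_ = X[0].shifts
        elif self.shifts is not None:
            self.shifts_ = np.asarray(self.shifts, dtype=float)
        else:
            raise ValueError("plain-array input needs the shifts axis")
        self.n_features_in_ = len(self.shifts_)
        return self

    def _spectra(self, X) -> list[RamanSpectrum]:
        if len(X) and isinstance(X[0], RamanSpectrum):
            return list(X)
        X = np.asarray(X, dtype=float)
        return [
            RamanSpectrum(
                sample_id=f"s{i}", variety="", label=0,
                shifts=self.shifts_, intensities=row,
            )
            for i, row in enumerate(X)
        ]

    def transform_images(self, X) -> list[SampleImage]:
        """Like :meth:`transform` but returning :class:`SampleImage` objects."""
        check_is_fitted(self, "shifts_")
        cfg = self._crest_config()
        first = FilterSpec(self.filter_order, self.first_wn)
        second = FilterSpec(self.filter_order, self.second_wn)
        return [
            image_from_spectrum(sp, cfg, first=first, second=second, normalize=self.normalize)
            for sp in self._spectra(X)
        ]

    def transform(self, X) -> np.ndarray:
        """Return an (n_samples, 784) array of flattened crest images."""
        images = self.transform_images(X)
        return np.stack([im.pixels.ravel() for im in images])


def _as_image_array(X, side: int) -> np.ndarray:
    """Coerce images given as SampleImages, (n, side, side) or (n, side^2)."""
    if len(X) and isinstance(X[0], SampleImage):
        return np.stack([im.pixels for im in X])
    X = np.asarray(X, dtype=float)
    if X.ndim == 2 and X.shape[1] == side * side:
        return X.reshape(len(X), side, side)
    if X.ndim == 3 and X.shape[1:] == (side, side):
        return X
    raise ValueError(f"cannot interpret input of shape {X.shape} as {side}x{side} images")


class CapsNetClassifier(ClassifierMixin, BaseEstimator):
    """Capsule-network classifier with dynamic agreement routing.

    Trains by mini-batch Adam on the separation margin loss; predictions
    take the class whose capsule output is longest.

    Parameters
    ----------
    conv1_channels, primary_channels : int
        Widths of the two convolutional stages (256/256 reproduces the
        1152-primary-capsule network; smaller values keep the topology at
        lower cost).
    routing_iterations : int
        Agreement-routing iterations per forward pass.
    epochs, batch_size, learning_rate : training schedule.
    random_state : int or None
        Seeds parameter initialization and batch shuffling.

    Attributes
    ----------
    classes_ : ndarray
        Sorted class labels seen in ``fit``.
    params_ : CapsNetParams
        Learned weights (after restoring the best evaluation epoch when
        an eval set is given).
    history_ : DataFrame
        One row per epoch: ``epoch, loss, train_acc, test_acc``
        (accuracies in percent; ``test_acc`` is NaN without an eval set).
    best_epoch_, best_test_acc_ : best held-out epoch and its accuracy.
    """

    def __init__(
        self,
        conv1_channels: int = 256,
        primary_channels: int = 256,
        primary_caps_dim: int = 8,
        class_caps_dim: int = 16,
        routing_iterations: int = 3,
        m_plus: float = 0.9,
        m_minus: float = 0.1,
        lambda_: float = 0.5,
        w_init_std: float = 0.1,
        epochs: int = 160,
        batch_size: int = 16,
        learning_rate: float = 3e-3,
        eval_every: int = 1,
        restore_best: bool = True,
        image_side: int = 28,
        random_state: int | None = None,
        verbose: int = 0,
    ):
        self.conv1_channels = conv1_channels
        self.primary_channels = primary_channels
        self.primary_caps_dim = primary_caps_dim
        self.class_caps_dim = class_caps_dim
        self.routing_iterations = routing_iterations
        self.m_plus = m_plus
        self.m_minus = m_minus
        self.lambda_ = lambda_
        self.w_init_std = w_init_std
        self.epochs = epochs
        self.batch_size = batch_size
        self.learning_rate = learning_rate
        self.eval_every = eval_every
        self.restore_best = restore_best
        self.image_side = image_side
        self.random_state = random_state
        self.verbose = verbose

    # ------------------------------------------------------------------

    def _config(self, n_classes: int) -> cn.CapsNetConfig:
        return cn.CapsNetConfig(
            image_side=self.image_side,
            conv1_channels=self.conv1_channels,
            primary_channels=self.primary_channels,
            primary_caps_dim=self.primary_caps_dim,
            class_caps_dim=self.class_caps_dim,
            n_classes=n_classes,
            routing_iterations=self.routing_iterations,
            m_plus=self.m_plus,
            m_minus=self.m_minus,
            lambda_=self.lambda_,
            w_init_std=self.w_init_std,
        )

    def _encode(self, y) -> np.ndarray:
        y = np.asarray(y)
        idx = np.searchsorted(self.classes_, y)
        bad = (idx >= len(self.classes_)) | (self.classes_[np.minimum(idx, len(self.classes_) - 1)] != y)
        if np.any(bad):
            raise ValueError(f"labels {np.unique(y[bad])} outside the training classes")
        return idx

    def fit(self, X, y, eval_set: tuple | None = None):
        """Train the network.

        ``eval_set`` is an optional ``(X_test, y_test)`` pair evaluated
        every ``eval_every`` epochs; the best-scoring epoch's weights are
        restored at the end when ``restore_best`` is set.
        """
        if len(X) == 0:
            raise ValueError("empty training set")
        x = _as_image_array(X, self.image_side)[:, None]
        y = np.asarray(y)
        self.classes_ = np.unique(y)
        yi = self._encode(y)
        cfg = self._config(len(self.classes_))
        self.config_ = cfg

        x_ev = y_ev = None
        if eval_set is not None:
            x_ev = _as_image_array(eval_set[0], self.image_side)[:, None]
            y_ev = self._encode(np.asarray(eval_set[1]))

        seed = self.random_state if self.random_state is not None else 0
        rng = np.random.default_rng(seed)
        params = cn.init_params(cfg, seed=int(rng.integers(2**31)))
        opt = cn.AdamState(params, lr=self.learning_rate)

        n = len(x)
        records = []
        best_acc, best_epoch, best_params = -1.0, -1, None
        for epoch in range(1, self.epochs + 1):
            order = rng.permutation(n)
            losses = []
            for start in range(0, n, self.batch_size):
                idx = order[start : start + self.batch_size]
                loss, grads, _ = cn.loss_and_grads(x[idx], yi[idx], params, cfg)
                opt.step(params, grads)
                losses.append(loss)
            train_acc = test_acc = np.nan
            if epoch % self.eval_every == 0 or epoch == self.epochs:
                train_acc = self._accuracy(x, yi, params, cfg)
                if x_ev is not None:
                    test_acc = self._accuracy(x_ev, y_ev, params, cfg)
                    if test_acc > best_acc:
                        best_acc, best_epoch = test_acc, epoch
                        best_params = params.copy()
            records.append(
                {"epoch": epoch, "loss": float(np.mean(losses)),
                 "train_acc": train_acc, "test_acc": test_acc}
            )
            if self.verbose:
                print(
                    f"epoch {epoch:3d}  loss {records[-1]['loss']:.4f}  "
                    f"train {train_acc:5.1f}%  test {test_acc:5.1f}%"
                )
        self.history_ = pd.DataFrame(records)
        self.final_params_ = params
        if best_params is not None:
            self.best_epoch_ = best_epoch
            self.best_test_acc_ = best_acc
            self.params_ = best_params if self.restore_best else params
        else:
            self.best_epoch_ = self.epochs
            self.best_test_acc_ = np.nan
            self.params_ = params
        return self

    def _accuracy(self, x, yi, params, cfg, chunk: int = 64) -> float:
        pred = np.concatenate(
            [
                np.argmax(cn._forward_full(x[i : i + chunk], params, cfg)["lengths"], axis=1)
                for i in range(0, len(x), chunk)
            ]
        )
        return 100.0 * float(np.mean(pred == yi))

    def capsule_lengths(self, X) -> np.ndarray:
        """Class-capsule output lengths, shape (n_samples, n_classes)."""
        check_is_fitted(self, "params_")
        x = _as_image_array(X, self.image_side)[:, None]
        cfg = self.config_
        return np.concatenate(
            [
                cn._forward_full(x[i : i + 64], self.params_, cfg)["lengths"]
                for i in range(0, len(x), 64)
            ]
        )

    def decision_function(self, X) -> np.ndarray:
        return self.capsule_lengths(X)

    def predict(self, X) -> np.ndarray:
        """Predicted labels: argmax of the capsule lengths."""
        return self.classes_[np.argmax(self.capsule_lengths(X), axis=1)]
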