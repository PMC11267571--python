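"""Reference classifiers: RBF support-vector machine, the full-spectrum
perceptron ("model A"), and the naive majority-class model.

These are the yardsticks the compressive-filter models are compared against:
the SVM and model A see the complete spectrum (443+ intensities), while the
naive model always predicts the most frequent class.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.svm import SVC

from .preprocess import FeatureScaler
from .spectra_data import RamanSpectrumSet

__all__ = [
    "SVMConfig",
    "svm_fit_predict",
    "model_a_fit_predict",
    "naive_accuracy",
]


@dataclass(frozen=True)
class SVMConfig:
    """RBF-kernel SVM with the scale rule
    ``gamma = 1 / (n_features * var(flattened training matrix))`` and default
    regularization ``C = 1``."""

    C: float = 1.0

    def gamma(self, X_train: np.ndarray) -> float:
        X_train = np.asarray(X_train, dtype=float)
        g = 1.0 / (X_train.shape[1] * X_train.var())
        if not g > 0:
            raise ValueError("training matrix has zero variance; gamma undefined")
        return g


def svm_fit_predict(
    train: RamanSpectrumSet,
    test: RamanSpectrumSet,
    standardize: bool = False,
    cfg: SVMConfig = SVMConfig(),
) -> tuple[float, np.ndarray]:
    """Fit the RBF SVM on ``train`` and return (test accuracy, predictions).

    ``standardize=True`` applies train-fitted feature-wise standardization
    (used for preprocessed spectra); raw spectra go in unnormalized.
    """
    if train.classes.size < 2:
        raise ValueError("training set must contain at least 2 classes")
    if not np.array_equal(train.wavenumbers, test.wavenumbers):
        raise ValueError("train and test must share the wavenumber axis")
    X_train, X_test = train.intensities, test.intensities
    if standardize:
        scaler = FeatureScaler().fit(X_train)
        X_train, X_test = scaler.transform(X_train), scaler.transform(X_test)
    clf = SVC(C=cfg.C, kernel="rbf", gamma=cfg.gamma(X_train))
    clf.fit(X_train, train.labels)
    pred = clf.predict(X_test)
    return float(np.mean(pred == test.labels)), pred


def model_a_fit_predict(
    train: RamanSpectrumSet,
    test: RamanSpectrumSet,
    epochs: int = 20,
    batch_size: int = 32,
    lr: float = 0.01,
    seed: int = 0,
) -> float:
    """Full-spectrum perceptron on preprocessed, train-standardized spectra.

    Architecture input -> dense 10 ReLU -> dense C softmax, trained with plain
    SGD and sparse categorical cross-entropy; returns the held-out accuracy.
    Standardization statistics come from the training set only.
    """
    scaler = FeatureScaler().fit(train.intensities)
    X_train = scaler.transform(train.intensities)
    X_test = scaler.transform(test.intensities)

    classes = train.classes
    rng = np.random.default_rng(seed)
    n_feat = X_train.shape[1]
    limit_h = np.sqrt(6.0 / (n_feat + 10))
    limit_o = np.sqrt(6.0 / (10 + classes.size))
    W1 = rng.uniform(-limit_h, limit_h, size=(n_feat, 10))
    b1 = np.zeros(10)
    W2 = rng.uniform(-limit_o, limit_o, size=(10, classes.size))
    b2 = np.zeros(classes.size)
    codes = np.searchsorted(classes, train.labels)

    for _ in range(epochs):
        order = rng.permutation(X_train.shape[0])
        for start in range(0, order.size, batch_size):
            idx = order[start : start + batch_size]
            xb, yb = X_train[idx], codes[idx]
            B = xb.shape[0]
            z1 = xb @ W1 + b1
            a1 = np.maximum(z1, 0.0)
            z2 = a1 @ W2 + b2
            z2 -= z2.max(axis=1, keepdims=True)
            p = np.exp(z2)
            p /= p.sum(axis=1, keepdims=True)
            if not np.all(np.isfinite(p)):
                raise FloatingPointError("model A training diverged")
            dz2 = p
            dz2[np.arange(B), yb] -= 1.0
            dz2 /= B
            dW2, db2 = a1.T @ dz2, dz2.sum(axis=0)
            dz1 = (dz2 @ W2.T) * (z1 > 0)
            dW1, db1 = xb.T @ dz1, dz1.sum(axis=0)
            W2 -= lr * dW2
            b2 -= lr * db2
            W1 -= lr * dW1
            b1 -= lr * db1

    z = np.maximum(X_test @ W1 + b1, 0.0) @ W2 + b2
    pred = classes[z.argmax(axis=1)]
    return float(np.mean(pred == test.labels))


def naive_accuracy(train: RamanSpectrumSet, test: RamanSpectrumSet) -> float:
    """Accuracy of always predicting the training set's most frequent class."""
    counts = train.class_counts()
    majority = counts.index[counts.to_numpy().argmax()]
    return float(np.mean(test.labels == majority))
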