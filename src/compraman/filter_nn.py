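"""Constrained multilayer perceptron that learns binary spectral filters.

The network classifies *raw* (unnormalized) Raman spectra while its
first-layer weights are constrained so they can be implemented as physical
optical filters.  Architecture::

    input (K wavenumbers)
      -> dense, N units, no bias, ReLU        # h_i = w_i . s  = compressive measurement
      -> batch- or layer-normalization        # enables training on raw spectra
      -> dense, 10 units, ReLU
      -> dense, C units, softmax

The first hidden layer carries no bias so its pre-activation *is* the
compressive measurement: in deployment, the detector reading m_i replaces the
dot product h_i and the rest of the network is evaluated unchanged.

Training is two-stage: first with a non-negativity constraint on the
first-layer kernel (projection to ``max(w, 0)`` after every SGD step), then —
starting from the pretrained weights — with a binarity constraint that
projects the kernel onto two values ``{0, c}`` after every step.  Plain SGD
with sparse categorical cross-entropy throughout.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np

from .filters import FilterBank
from .spectra_data import RamanSpectrumSet, stratified_split

__all__ = [
    "FilterNNConfig",
    "TrainedFilterModel",
    "binarize_weights",
    "build_model",
    "train_model",
    "train_two_stage",
    "select_model",
    "extract_filters",
    "predict_from_measurements",
]

_EPS = 1e-3  # normalization-layer variance guard
_BN_MOMENTUM = 0.99  # running-statistics EMA for batch norm


@dataclass(frozen=True)
class FilterNNConfig:
    """Hyperparameters of the filter-design network.

    Defaults are the measured-spectra settings (200 + 200 epochs, batch 16);
    :meth:`simulated` gives the preset for simulated spectra (N = 3 filters,
    20 epochs, batch 128).
    """

    n_filters: int = 5
    normalization: str = "layer"  # {"layer", "batch"}
    constraint: str = "binary"  # {"nonneg", "binary"}
    hidden2_units: int = 10
    n_classes: int = 3
    epochs_stage1: int = 200
    epochs_stage2: int = 200
    lr_stage1: float = 0.01
    lr_stage2: float = 0.001
    batch_size: int = 16
    binarize_per_filter: bool = False  # apply the binarity rule per unit
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_filters < 1 or self.hidden2_units < 1 or self.n_classes < 2:
            raise ValueError("layer sizes must be positive (>=2 classes)")
        if self.normalization not in ("layer", "batch"):
            raise ValueError("normalization must be 'layer' or 'batch'")
        if self.constraint not in ("nonneg", "binary"):
            raise ValueError("constraint must be 'nonneg' or 'binary'")
        if min(self.lr_stage1, self.lr_stage2) <= 0:
            raise ValueError("learning rates must be positive")
        if min(self.epochs_stage1, self.epochs_stage2) < 1:
            raise ValueError("epoch counts must be >= 1")

    @classmethod
    def simulated(cls, n_classes: int = 3, **kw) -> "FilterNNConfig":
        """Preset for simulated molecular spectra."""
        kw.setdefault("n_filters", 3)
        kw.setdefault("epochs_stage1", 20)
        kw.setdefault("epochs_stage2", 20)
        kw.setdefault("batch_size", 128)
        return cls(n_classes=n_classes, **kw)


def binarize_weights(W: np.ndarray, per_filter: bool = False) -> np.ndarray:
    """Project a weight matrix onto two values ``{0, c}``.

    Let ``m`` be the mean of all entries and ``H`` the set of entries larger
    than ``m``; with ``c = mean(H)``, entries above ``c / 2`` become ``c`` and
    all others 0.  The common value ``c`` is arbitrary for an optical
    implementation — it is absorbed into the downstream classifier and the
    physical filter uses 0/1.

    With ``per_filter=True`` the rule is applied to each column (filter)
    independently.
    """
    W = np.asarray(W, dtype=float)
    if not np.all(np.isfinite(W)):
        raise ValueError("weights contain non-finite values")
    if per_filter and W.ndim == 2:
        return np.column_stack([binarize_weights(W[:, j]) for j in range(W.shape[1])])
    high = W[W > W.mean()]
    if high.size == 0:
        warnings.warn("constant weight matrix; binarization yields all zeros", stacklevel=2)
        return np.zeros_like(W)
    c = high.mean()
    return np.where(W > c / 2.0, c, 0.0)


def _he_uniform(rng, fan_in: int, shape) -> np.ndarray:
    limit = np.sqrt(6.0 / fan_in)
    return rng.uniform(-limit, limit, size=shape)


def _glorot_uniform(rng, fan_in: int, fan_out: int, shape) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape)


def _softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


@dataclass
class TrainedFilterModel:
    """All weights and normalization statistics of the filter network.

    ``W1`` is ``K x N``: column ``i`` is the spectral response of filter
    ``i``.  Under the binary constraint its entries take at most two values
    ``{0, c}``, so :func:`extract_filters` recovers a :class:`FilterBank`.
    """

    W1: np.ndarray
    gamma: np.ndarray
    beta: np.ndarray
    running_mean: np.ndarray
    running_var: np.ndarray
    W2: np.ndarray
    b2: np.ndarray
    W3: np.ndarray
    b3: np.ndarray
    config: FilterNNConfig
    classes: np.ndarray | None = None
    wavenumbers: np.ndarray | None = None
    history: dict = field(default_factory=lambda: {"loss": [], "accuracy": []})

    # -- forward pieces ----------------------------------------------------
    def _normalize_train(self, a: np.ndarray):
        """Training-mode normalization; returns (output, cache for backprop)."""
        if self.config.normalization == "layer":
            mu = a.mean(axis=1, keepdims=True)
            var = a.var(axis=1, keepdims=True)
        else:
            mu = a.mean(axis=0, keepdims=True)
            var = a.var(axis=0, keepdims=True)
            self.running_mean = _BN_MOMENTUM * self.running_mean + (1 - _BN_MOMENTUM) * mu[0]
            self.running_var = _BN_MOMENTUM * self.running_var + (1 - _BN_MOMENTUM) * var[0]
        inv = 1.0 / np.sqrt(var + _EPS)
        xhat = (a - mu) * inv
        return self.gamma * xhat + self.beta, (xhat, inv)

    def _normalize_infer(self, a: np.ndarray) -> np.ndarray:
        if self.config.normalization == "layer":
            mu = a.mean(axis=1, keepdims=True)
            var = a.var(axis=1, keepdims=True)
        else:
            mu, var = self.running_mean, self.running_var
        return self.gamma * (a - mu) / np.sqrt(var + _EPS) + self.beta

    def _head(self, y: np.ndarray) -> np.ndarray:
        a2 = np.maximum(y @ self.W2 + self.b2, 0.0)
        return _softmax(a2 @ self.W3 + self.b3)

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        """Class probabilities from full spectra (inference mode)."""
        a = np.maximum(np.asarray(X, dtype=float) @ self.W1, 0.0)
        return self._head(self._normalize_infer(a))

    def predict(self, X: np.ndarray) -> np.ndarray:
        p = self.predict_proba(X)
        idx = p.argmax(axis=1)
        return self.classes[idx] if self.classes is not None else idx

    def accuracy(self, X: np.ndarray, labels: np.ndarray) -> float:
        return float(np.mean(self.predict(X) == np.asarray(labels)))

    def n_parameters(self) -> int:
        """Trainable parameters: bias-free first layer, norm scale/shift,
        biased dense head."""
        return (
            self.W1.size
            + self.gamma.size
            + self.beta.size
            + self.W2.size
            + self.b2.size
            + self.W3.size
            + self.b3.size
        )


def build_model(cfg: FilterNNConfig, n_wavenumbers: int) -> TrainedFilterModel:
    """Initialize an untrained model: hidden layers He-uniform, output layer
    Glorot-uniform, normalization scale 1 / shift 0, zero biases."""
    rng = np.random.default_rng(cfg.seed)
    N, H, C = cfg.n_filters, cfg.hidden2_units, cfg.n_classes
    return TrainedFilterModel(
        W1=_he_uniform(rng, n_wavenumbers, (n_wavenumbers, N)),
        gamma=np.ones(N),
        beta=np.zeros(N),
        running_mean=np.zeros(N),
        running_var=np.ones(N),
        W2=_he_uniform(rng, N, (N, H)),
        b2=np.zeros(H),
        W3=_glorot_uniform(rng, H, C, (H, C)),
        b3=np.zeros(C),
        config=cfg,
    )


def _project(W1: np.ndarray, cfg: FilterNNConfig) -> np.ndarray:
    if cfg.constraint == "nonneg":
        return np.maximum(W1, 0.0)
    return binarize_weights(W1, per_filter=cfg.binarize_per_filter)


def _sgd_epoch(model: TrainedFilterModel, X, y_codes, lr: float, rng) -> tuple[float, float]:
    """One epoch of plain SGD with the weight constraint re-applied after every
    update.  Returns (mean loss, training accuracy over the epoch's batches)."""
    cfg = model.config
    n = X.shape[0]
    order = rng.permutation(n)
    total_loss = 0.0
    total_correct = 0
    for start in range(0, n, cfg.batch_size):
        idx = order[start : start + cfg.batch_size]
        xb, yb = X[idx], y_codes[idx]
        B = xb.shape[0]

        # forward
        h = xb @ model.W1
        a = np.maximum(h, 0.0)
        ynorm, (xhat, inv) = model._normalize_train(a)
        z2 = ynorm @ model.W2 + model.b2
        a2 = np.maximum(z2, 0.0)
        z3 = a2 @ model.W3 + model.b3
        p = _softmax(z3)

        batch_loss = -np.log(np.maximum(p[np.arange(B), yb], 1e-300)).sum()
        if not np.isfinite(batch_loss):
            raise FloatingPointError("training diverged: non-finite loss")
        total_loss += batch_loss
        total_correct += int((p.argmax(axis=1) == yb).sum())

        # backward
        dz3 = p.copy()
        dz3[np.arange(B), yb] -= 1.0
        dz3 /= B
        dW3 = a2.T @ dz3
        db3 = dz3.sum(axis=0)
        dz2 = (dz3 @ model.W3.T) * (z2 > 0)
        dW2 = ynorm.T @ dz2
        db2 = dz2.sum(axis=0)
        dy = dz2 @ model.W2.T

        dgamma = (dy * xhat).sum(axis=0)
        dbeta = dy.sum(axis=0)
        dxhat = dy * model.gamma
        if cfg.normalization == "layer":
            m = xhat.shape[1]
            da = (
                inv
                / m
                * (
                    m * dxhat
                    - dxhat.sum(axis=1, keepdims=True)
                    - xhat * (dxhat * xhat).sum(axis=1, keepdims=True)
                )
            )
        else:
            m = B
            da = (
                inv
                / m
                * (m * dxhat - dxhat.sum(axis=0) - xhat * (dxhat * xhat).sum(axis=0))
            )
        dh = da * (h > 0)
        dW1 = xb.T @ dh

        # SGD step + constraint projection
        model.W3 -= lr * dW3
        model.b3 -= lr * db3
        model.W2 -= lr * dW2
        model.b2 -= lr * db2
        model.gamma -= lr * dgamma
        model.beta -= lr * dbeta
        model.W1 = _project(model.W1 - lr * dW1, cfg)

    return total_loss / n, total_correct / n


def train_model(
    model: TrainedFilterModel,
    X: np.ndarray,
    labels: np.ndarray,
    epochs: int,
    lr: float,
    rng,
) -> TrainedFilterModel:
    """Train in place for ``epochs`` epochs; labels may be strings or codes."""
    X = np.asarray(X, dtype=float)
    if model.classes is None:
        model.classes = np.unique(labels)
    codes = np.searchsorted(model.classes, np.asarray(labels))
    for _ in range(epochs):
        loss, acc = _sgd_epoch(model, X, codes, lr, rng)
        model.history["loss"].append(loss)
        model.history["accuracy"].append(acc)
    return model


def train_two_stage(
    train: RamanSpectrumSet, cfg: FilterNNConfig
) -> TrainedFilterModel:
    """Two-stage training on raw spectra.

    Stage 1 trains with the non-negativity constraint (``epochs_stage1`` at
    ``lr_stage1``).  If ``cfg.constraint == "nonneg"`` that model is returned.
    Otherwise the weights are copied into an identical architecture with the
    binarity constraint and trained for ``epochs_stage2`` at ``lr_stage2`` on
    the same data; the stage-2 model is returned.  No normalization is applied
    to the input spectra at any point.
    """
    rng = np.random.default_rng(cfg.seed)
    cfg1 = replace(cfg, constraint="nonneg")
    model = build_model(cfg1, train.n_wavenumbers)
    model.wavenumbers = train.wavenumbers
    train_model(model, train.intensities, train.labels, cfg.epochs_stage1, cfg.lr_stage1, rng)
    if cfg.constraint == "nonneg":
        return model

    model.config = replace(cfg, constraint="binary")
    train_model(model, train.intensities, train.labels, cfg.epochs_stage2, cfg.lr_stage2, rng)
    # projection after the final update guarantees the invariant even if the
    # last step was a partial batch
    model.W1 = _project(model.W1, model.config)
    return model


def select_model(
    data: RamanSpectrumSet,
    cfg: FilterNNConfig,
    n_splits: int = 5,
    n_candidates: int = 3,
) -> dict:
    """Split/train/select protocol.

    For each of ``n_splits`` stratified 80/20 train-test splits, train
    ``n_candidates`` models that each hold out their own bootstrapped 20%
    validation subset of the training pool; the candidate with the best
    validation accuracy is evaluated once on the test set.

    Returns a report with per-split test accuracies, the ``n_splits x
    n_candidates`` validation accuracies, and the selected models.
    """
    report = {"test_accuracy": [], "val_accuracy": [], "models": []}
    for split in range(n_splits):
        train_pool, test = stratified_split(data, 0.2, seed=cfg.seed + 1000 + split)
        candidates = []
        val_accs = []
        for cand in range(n_candidates):
            sub_seed = cfg.seed + 100 * (split + 1) + cand
            fit, val = stratified_split(train_pool, 0.2, seed=sub_seed)
            model = train_two_stage(fit, replace(cfg, seed=sub_seed))
            candidates.append(model)
            val_accs.append(model.accuracy(val.intensities, val.labels))
        best = int(np.argmax(val_accs))
        report["val_accuracy"].append(val_accs)
        report["models"].append(candidates[best])
        report["test_accuracy"].append(
            candidates[best].accuracy(test.intensities, test.labels)
        )
    return report


def extract_filters(model: TrainedFilterModel) -> FilterBank:
    """Read the binary filter bank out of a trained model.

    ``B[i] = 1`` where filter ``i`` (column ``i`` of ``W1``) is nonzero;
    ``scale`` is the common nonzero weight value ``c``.
    """
    if model.config.constraint != "binary":
        raise ValueError("filters can only be extracted from a binary-constrained model")
    W = model.W1
    values = np.unique(W)
    nonzero = values[values != 0]
    if nonzero.size > 1:
        raise ValueError(
            f"first-layer weights take {nonzero.size + 1} distinct values; binary invariant breached"
        )
    scale = float(nonzero[0]) if nonzero.size else 1.0
    return FilterBank(B=(W.T != 0).astype(float), scale=scale, wavenumbers=model.wavenumbers)


def predict_from_measurements(model: TrainedFilterModel, m: np.ndarray) -> np.ndarray:
    """Classify from compressive measurements.

    ``m`` (length N, or a stack of such rows) stands in for the first-layer
    dot products h_i; the network applies ReLU, the normalization layer in
    inference mode, and the dense head.  When ``m = W1.T @ s`` this equals the
    full forward pass on the spectrum ``s``.
    """
    m = np.atleast_2d(np.asarray(m, dtype=float))
    if m.shape[1] != model.config.n_filters:
        raise ValueError(f"expected {model.config.n_filters} measurements per sample")
    a = np.maximum(m, 0.0)
    return model._head(model._normalize_infer(a))
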