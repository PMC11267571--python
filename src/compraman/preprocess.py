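"""Baseline removal, normalization, binning and feature selection.

The preprocessing used for full-spectrum reference classifiers: a slowly
varying baseline is estimated per spectrum by asymmetric least-squares (ALS)
smoothing and subtracted, and the corrected spectrum is normalized by its
intensity sum.  Binning and feature-subset selection support the study of how
much spectral information is actually needed for classification.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
from scipy.sparse.linalg import spsolve
from sklearn.preprocessing import StandardScaler

from .spectra_data import RamanSpectrumSet

__all__ = [
    "ALSConfig",
    "FeatureScaler",
    "als_baseline",
    "preprocess_spectrum",
    "preprocess_set",
    "mean_bin",
    "select_most_variable",
    "select_random",
]


@dataclass(frozen=True)
class ALSConfig:
    """Asymmetric least-squares smoothing parameters.

    ``lam`` penalizes curvature (second differences) of the baseline; ``p`` is
    the asymmetry: points above the current baseline (Raman peaks) get weight
    ``p``, points below get ``1 - p``, so the fit hugs the lower envelope.
    """

    lam: float = 1e6
    p: float = 0.1
    n_iter: int = 10

    def __post_init__(self) -> None:
        if not self.lam > 0:
            raise ValueError("lam must be positive")
        if not 0 < self.p < 1:
            raise ValueError("p must lie in (0, 1)")
        if self.n_iter < 1:
            raise ValueError("n_iter must be >= 1")


class FeatureScaler:
    """Per-wavenumber standardization fitted on training data only.

    Thin wrapper around :class:`sklearn.preprocessing.StandardScaler` that
    replaces the std of a constant feature by 1 (sklearn's behaviour) and
    refuses to transform before fitting.
    """

    def __init__(self) -> None:
        self._scaler = StandardScaler()
        self._fitted = False

    def fit(self, X: np.ndarray) -> "FeatureScaler":
        self._scaler.fit(np.asarray(X, dtype=float))
        self._fitted = True
        return self

    def transform(self, X: np.ndarray) -> np.ndarray:
        if not self._fitted:
            raise RuntimeError("FeatureScaler must be fitted before transform")
        return self._scaler.transform(np.asarray(X, dtype=float))

    def fit_transform(self, X: np.ndarray) -> np.ndarray:
        return self.fit(X).transform(X)

    @property
    def mean_(self) -> np.ndarray:
        return self._scaler.mean_

    @property
    def scale_(self) -> np.ndarray:
        return self._scaler.scale_


def als_baseline(y: np.ndarray, cfg: ALSConfig = ALSConfig()) -> np.ndarray:
    """Estimate a smooth baseline under ``y`` by asymmetric least squares.

    Minimizes ``sum_i w_i (y_i - z_i)^2 + lam * sum (d2 z)^2`` where ``d2`` is
    the second difference, iterating the asymmetric weight update
    ``w_i = p if y_i > z_i else 1 - p`` for ``cfg.n_iter`` iterations from
    uniform weights.  Each iterate solves the sparse normal equations
    ``(W + lam D^T D) z = W y``.
    """
    y = np.asarray(y, dtype=float)
    if y.ndim != 1 or y.size < 3:
        raise ValueError("y must be a 1-D vector of length >= 3")
    if not np.all(np.isfinite(y)):
        raise ValueError("y contains non-finite values")

    n = y.size
    D = sp.diags_array([1.0, -2.0, 1.0], offsets=[0, 1, 2], shape=(n - 2, n))
    penalty = (cfg.lam * (D.T @ D)).tocsc()
    w = np.ones(n)
    z = y
    for _ in range(cfg.n_iter):
        W = sp.diags_array(w)
        z = spsolve((W + penalty).tocsc(), w * y)
        w = np.where(y > z, cfg.p, 1.0 - cfg.p)
    return z


def preprocess_spectrum(y: np.ndarray, cfg: ALSConfig = ALSConfig()) -> np.ndarray:
    """Baseline-correct and sum-normalize one spectrum.

    Subtracts the ALS baseline and divides by the sum of the corrected
    intensities, so the output sums to 1.  A corrected spectrum with a
    non-positive sum cannot be normalized and raises.
    """
    y = np.asarray(y, dtype=float)
    corrected = y - als_baseline(y, cfg)
    total = corrected.sum()
    if total <= 0:
        raise ValueError("baseline-corrected spectrum sums to <= 0; cannot normalize")
    return corrected / total


def preprocess_set(
    s: RamanSpectrumSet, cfg: ALSConfig = ALSConfig()
) -> RamanSpectrumSet:
    """Apply :func:`preprocess_spectrum` to every spectrum in a set.

    Spectra whose baseline-corrected sum is non-positive are flagged with a
    warning and excluded (metadata dropped in lockstep).
    """
    out = []
    keep = []
    for i in range(s.n_spectra):
        y = s.intensities[i]
        corrected = y - als_baseline(y, cfg)
        total = corrected.sum()
        if total <= 0:
            warnings.warn(
                f"spectrum {i}: corrected intensities sum to {total:.3g} <= 0; excluded",
                stacklevel=2,
            )
            continue
        out.append(corrected / total)
        keep.append(i)
    kept = s.take(np.asarray(keep, dtype=int))
    return kept.with_intensities(np.vstack(out), stage="normalized")


def mean_bin(s: RamanSpectrumSet, n_bins: int) -> RamanSpectrumSet:
    """Average intensities within ``n_bins`` contiguous, equally sized index
    intervals (remainder channels go to the leading bins); the output
    wavenumber of a bin is the midpoint of its interval."""
    if not 1 <= n_bins <= s.n_wavenumbers:
        raise ValueError("n_bins must lie in [1, n_wavenumbers]")
    base, rem = divmod(s.n_wavenumbers, n_bins)
    sizes = np.full(n_bins, base)
    sizes[:rem] += 1  # remainder channels go to the leading bins
    edges = np.concatenate([[0], np.cumsum(sizes)])
    binned = np.empty((s.n_spectra, n_bins))
    centers = np.empty(n_bins)
    for b in range(n_bins):
        lo, hi = edges[b], edges[b + 1]
        binned[:, b] = s.intensities[:, lo:hi].mean(axis=1)
        centers[b] = 0.5 * (s.wavenumbers[lo] + s.wavenumbers[hi - 1])
    return s.with_intensities(binned, wavenumbers=centers)


def select_most_variable(train: RamanSpectrumSet, k: int) -> np.ndarray:
    """Indices of the ``k`` wavenumbers with the largest variability across
    cell types, defined as the variance of the per-class mean intensity.
    Deterministic; ties broken toward the lower index."""
    if k <= 0:
        raise ValueError("k must be positive")
    if k > train.n_wavenumbers:
        raise ValueError("k exceeds n_wavenumbers")
    classes = train.classes
    if classes.size < 2:
        raise ValueError("need at least 2 classes")
    class_means = np.vstack(
        [train.intensities[train.labels == c].mean(axis=0) for c in classes]
    )
    variability = class_means.var(axis=0)
    # stable sort on -variability keeps lower indices first among ties
    order = np.argsort(-variability, kind="stable")
    return np.sort(order[:k])


def select_random(n_wavenumbers: int, k: int, seed: int) -> np.ndarray:
    """Uniform sample of ``k`` wavenumber indices without replacement."""
    if k <= 0:
        raise ValueError("k must be positive")
    if k > n_wavenumbers:
        raise ValueError("k exceeds n_wavenumbers")
    rng = np.random.default_rng(seed)
    return np.sort(rng.choice(n_wavenumbers, size=k, replace=False))
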