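"""Bhattacharyya-bound filter optimization and maximum-likelihood classification.

The Bhattacharyya bound (BB) is a closed-form upper bound on the error of
maximum-likelihood classification, assembled from pairwise Bhattacharyya
coefficients between the class-conditional distributions of the filter
outputs::

    BB = sum_{j < j'} sqrt(P_j P_j') * rho_jj'

Two noise models are supported.  For simulated molecular spectra the filter
counts are multinomial (photon counting noise) and the pairwise coefficient
has the closed form ``rho = (sum_i sqrt(p_ij p_ij'))**N_phot``.  For measured
cell spectra — whose class variability is dominated by biology, not shot
noise — filter outputs are modeled as multivariate normal with per-class
means and covariances estimated from the data, and ``rho = exp(-B_jj')`` with
the Gaussian Bhattacharyya distance ``B_jj'``.

Filters are optimized by a swap walk that preserves each filter's number of
transmitting elements: propose exchanging a randomly chosen 0 with a randomly
chosen 1 within one filter, accept iff the bound strictly decreases.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .filters import FilterBank
from .spectra_data import RamanSpectrumSet
from .simulate import filter_outputs

__all__ = [
    "MultinomialClassModel",
    "GaussianClassModel",
    "bb_multinomial",
    "estimate_gaussian_model",
    "bb_gaussian",
    "optimize_filters_swap",
    "mlc_multinomial",
    "mlc_gaussian",
]


@dataclass(frozen=True)
class MultinomialClassModel:
    """Photon-counting noise model: normalized class spectra, priors, budget."""

    s: np.ndarray  # M x K, rows sum to 1
    priors: np.ndarray | None = None
    N_phot: int = 1000

    def __post_init__(self) -> None:
        s = np.atleast_2d(np.asarray(self.s, dtype=float))
        if np.any(s < 0) or not np.allclose(s.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("class spectra must be non-negative and sum to 1")
        priors = self.priors
        if priors is None:
            priors = np.full(s.shape[0], 1.0 / s.shape[0])
        priors = np.asarray(priors, dtype=float)
        if priors.shape != (s.shape[0],) or not np.isclose(priors.sum(), 1.0):
            raise ValueError("priors must be one per class and sum to 1")
        if self.N_phot < 1:
            raise ValueError("N_phot must be a positive integer")
        object.__setattr__(self, "s", s)
        object.__setattr__(self, "priors", priors)

    @property
    def n_classes(self) -> int:
        return self.s.shape[0]


@dataclass(frozen=True)
class GaussianClassModel:
    """Gaussian noise model of filter outputs: per-class means ``m_j`` (length
    N), covariances ``Sigma_j`` (N x N, ridge-regularized), priors ``P_j``."""

    means: np.ndarray  # M x N
    covariances: np.ndarray  # M x N x N
    priors: np.ndarray

    def __post_init__(self) -> None:
        means = np.atleast_2d(np.asarray(self.means, dtype=float))
        covs = np.asarray(self.covariances, dtype=float)
        priors = np.asarray(self.priors, dtype=float)
        M, N = means.shape
        if covs.shape != (M, N, N):
            raise ValueError("covariances must be M x N x N")
        if priors.shape != (M,) or not np.isclose(priors.sum(), 1.0):
            raise ValueError("priors must be one per class and sum to 1")
        for j in range(M):
            if not np.allclose(covs[j], covs[j].T):
                raise ValueError(f"covariance {j} is not symmetric")
            if np.linalg.eigvalsh(covs[j])[0] <= 0:
                raise ValueError(f"covariance {j} is not positive definite")
        object.__setattr__(self, "means", means)
        object.__setattr__(self, "covariances", covs)
        object.__setattr__(self, "priors", priors)

    @property
    def n_classes(self) -> int:
        return self.means.shape[0]


# ---------------------------------------------------------------------------
# Bounds


def _filter_probabilities(F: FilterBank, model: MultinomialClassModel) -> np.ndarray:
    """Per-class filter-output probabilities ``p_ij = mu_ij / sum_i mu_ij``
    (classes in rows)."""
    mu = filter_outputs(F, model.s)  # M x N
    totals = mu.sum(axis=1, keepdims=True)
    if np.any(totals <= 0):
        bad = np.flatnonzero(totals[:, 0] <= 0).tolist()
        raise ValueError(f"filter bank transmits nothing for classes {bad}")
    return mu / totals


def bb_multinomial(F: FilterBank, model: MultinomialClassModel) -> float:
    """Bhattacharyya bound on MLC error for multinomial filter counts.

    The pairwise coefficient between two multinomials sharing ``N_phot``
    trials factorizes: ``rho_jj' = (sum_i sqrt(p_ij p_ij'))**N_phot``.
    """
    p = _filter_probabilities(F, model)
    priors = model.priors
    bound = 0.0
    for j in range(model.n_classes):
        for jp in range(j + 1, model.n_classes):
            rho = float(np.sqrt(p[j] * p[jp]).sum()) ** model.N_phot
            bound += np.sqrt(priors[j] * priors[jp]) * rho
    return float(bound)


def estimate_gaussian_model(
    F: FilterBank, s: RamanSpectrumSet, ridge_rel: float = 1e-8
) -> GaussianClassModel:
    """Estimate per-class Gaussian filter-output statistics from measured spectra.

    Filter outputs ``F . spectrum`` are computed for every measurement; each
    class contributes its sample mean and sample covariance, with a relative
    ridge ``ridge_rel * trace(Sigma) / N`` added to the diagonal.  Priors are
    the class frequencies in the data set.
    """
    classes = s.classes
    N = F.n_filters
    outputs = filter_outputs(F, s.intensities)
    means = np.empty((classes.size, N))
    covs = np.empty((classes.size, N, N))
    priors = np.empty(classes.size)
    for j, cls in enumerate(classes):
        rows = outputs[s.labels == cls]
        if rows.shape[0] < N + 1:
            raise ValueError(f"class {cls!r} has fewer than N+1={N + 1} spectra")
        means[j] = rows.mean(axis=0)
        cov = np.cov(rows, rowvar=False).reshape(N, N)
        eps = ridge_rel * np.trace(cov) / N
        if eps <= 0:
            eps = ridge_rel
        cov = cov + eps * np.eye(N)
        if np.linalg.eigvalsh(cov)[0] <= 0:
            raise ValueError(f"covariance for class {cls!r} singular even after ridge")
        covs[j] = cov
        priors[j] = rows.shape[0] / s.n_spectra
    return GaussianClassModel(means=means, covariances=covs, priors=priors)


def _bhattacharyya_distance_gaussian(m1, S1, m2, S2) -> float:
    Sbar = 0.5 * (S1 + S2)
    diff = m1 - m2
    sign, logdet_bar = np.linalg.slogdet(Sbar)
    if sign <= 0:
        raise ValueError("averaged covariance is not positive definite")
    _, logdet1 = np.linalg.slogdet(S1)
    _, logdet2 = np.linalg.slogdet(S2)
    maha = float(diff @ np.linalg.solve(Sbar, diff))
    return 0.125 * maha + 0.5 * (logdet_bar - 0.5 * (logdet1 + logdet2))


def bb_gaussian(model: GaussianClassModel) -> float:
    """Bhattacharyya bound for Gaussian-distributed filter outputs:
    ``sum_{j<j'} sqrt(P_j P_j') exp(-B_jj')`` with
    ``B = 1/8 d^T Sbar^-1 d + 1/2 ln(det Sbar / sqrt(det S_j det S_j'))``."""
    bound = 0.0
    for j in range(model.n_classes):
        for jp in range(j + 1, model.n_classes):
            B = _bhattacharyya_distance_gaussian(
                model.means[j],
                model.covariances[j],
                model.means[jp],
                model.covariances[jp],
            )
            bound += np.sqrt(model.priors[j] * model.priors[jp]) * np.exp(-B)
    return float(bound)


# ---------------------------------------------------------------------------
# Swap optimizer


def optimize_filters_swap(
    objective,
    n_filters: int,
    K: int,
    frac_ones: float = 1.0 / 3.0,
    seed: int = 0,
    max_proposals: int | None = None,
    patience: int | None = None,
    wavenumbers: np.ndarray | None = None,
) -> tuple[FilterBank, list[float]]:
    """Minimize ``objective(FilterBank)`` by efficiency-preserving swaps.

    Each filter starts with ``round(K * frac_ones)`` transmitting elements at
    random positions.  A proposal exchanges a randomly chosen 0 with a
    randomly chosen 1 within one randomly chosen filter and is accepted iff
    the objective strictly decreases, so per-filter element counts never
    change and the objective trace is non-increasing.  The walk stops after
    ``patience`` consecutive rejections (default ``50 * n_filters * K``) or
    ``max_proposals`` proposals (default ``500 * n_filters * K``).

    Returns the final bank and the trace of objective values at the initial
    state and after each accepted swap.
    """
    if K < 3:
        raise ValueError("need K >= 3")
    if patience is None:
        patience = 50 * n_filters * K
    if max_proposals is None:
        max_proposals = 500 * n_filters * K
    rng = np.random.default_rng(seed)
    n_ones = max(int(round(K * frac_ones)), 1)
    B = np.zeros((n_filters, K))
    for i in range(n_filters):
        B[i, rng.choice(K, size=n_ones, replace=False)] = 1.0

    bank = FilterBank(B=B, wavenumbers=wavenumbers)
    current = objective(bank)
    trace = [current]
    rejected = 0
    for _ in range(max_proposals):
        if rejected >= patience:
            break
        i = rng.integers(n_filters)
        ones = np.flatnonzero(B[i] == 1.0)
        zeros = np.flatnonzero(B[i] == 0.0)
        if ones.size == 0 or zeros.size == 0:
            rejected += 1
            continue
        a, b = rng.choice(ones), rng.choice(zeros)
        B[i, a], B[i, b] = 0.0, 1.0
        candidate = FilterBank(B=B, wavenumbers=wavenumbers)
        value = objective(candidate)
        if value < current:
            current = value
            trace.append(current)
            rejected = 0
        else:
            B[i, a], B[i, b] = 1.0, 0.0
            rejected += 1
    return FilterBank(B=B.copy(), wavenumbers=wavenumbers), trace


# ---------------------------------------------------------------------------
# Maximum-likelihood classification


def mlc_multinomial(
    n: np.ndarray, F: FilterBank, model: MultinomialClassModel
) -> int | np.ndarray:
    """Assign filter counts ``n`` (one vector or a stack) to the class whose
    multinomial filter-output distribution gives them the largest likelihood;
    ties (including all-impossible outcomes) go to the lowest class index."""
    p = _filter_probabilities(F, model)
    n = np.asarray(n, dtype=float)
    single = n.ndim == 1
    n2 = np.atleast_2d(n)
    with np.errstate(divide="ignore", invalid="ignore"):
        logp = np.where(p > 0, np.log(np.where(p > 0, p, 1.0)), -np.inf)
        # counts on zero-probability filters give -inf; 0 * -inf -> 0 by convention
        ll = np.where(n2[:, None, :] > 0, n2[:, None, :] * logp[None, :, :], 0.0).sum(axis=2)
    labels = ll.argmax(axis=1)  # argmax takes the first (lowest) index on ties
    return int(labels[0]) if single else labels


def mlc_gaussian(
    spectrum: np.ndarray,
    F: FilterBank,
    model: GaussianClassModel,
    use_priors: bool = False,
) -> int | np.ndarray:
    """Maximum-likelihood classification of measured spectra.

    Computes the filter outputs ``mu = F . s`` and returns the class
    maximizing the multivariate-normal log-density ``N(mu; m_j, Sigma_j)``.
    ``use_priors=True`` adds ``log P_j`` (MAP rule); the default is the pure
    likelihood rule.
    """
    spectrum = np.asarray(spectrum, dtype=float)
    single = spectrum.ndim == 1
    mu = filter_outputs(F, np.atleast_2d(spectrum))
    scores = np.empty((mu.shape[0], model.n_classes))
    for j in range(model.n_classes):
        diff = mu - model.means[j]
        cov = model.covariances[j]
        _, logdet = np.linalg.slogdet(cov)
        maha = np.einsum("ni,ni->n", diff, np.linalg.solve(cov, diff.T).T)
        scores[:, j] = -0.5 * (maha + logdet)
        if use_priors:
            scores[:, j] += np.log(model.priors[j])
    labels = scores.argmax(axis=1)
    return int(labels[0]) if single else labels
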