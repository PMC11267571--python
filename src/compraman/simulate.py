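"""Synthetic Raman spectra with photon-counting noise, and a cell-like fixture
generator.

Two generators live here.  The *molecular* simulator produces reference
spectra for ``M`` species with a controllable correlation level and multinomial
shot noise: intensities at ``K`` wavenumbers are drawn from a unit-mean
exponential, sharpened by raising to the power ``alpha`` (peakier spectra for
larger ``alpha``), and sum-normalized.  Class spectra are convex mixtures of an
independent spectrum and a shared "common" spectrum; the mixing weight ``beta``
interpolates from fully independent (``beta = 0``) to identical classes
(``beta = 1``).  Photon counting distributes a fixed budget ``N_phot`` over
spectral channels (or filter outputs) multinomially.

The *cell fixture* generator emulates the structure of real single-cell
deposits — class-specific peak sets, smooth additive baselines, nested
cell-line x replicate x cell batch structure, per-cell intensity scaling and
Poisson counting noise — so the full pipeline can be exercised without any
download.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .filters import FilterBank
from .spectra_data import RamanSpectrumSet

__all__ = [
    "SimulationConfig",
    "SpectrumBasis",
    "CellFixtureConfig",
    "draw_reference_spectra",
    "mix_spectra",
    "sample_photon_counts",
    "filter_outputs",
    "sample_filter_counts",
    "simulate_species_dataset",
    "generate_cell_fixture",
]


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the molecular-spectrum simulator."""

    K: int = 50  # wavenumber channels
    M: int = 3  # molecular species / classes
    alpha: float = 3.0  # peak-sharpening exponent
    beta: float = 0.0  # correlation level in [0, 1]
    N_phot: int = 1000  # photons per measurement
    seed: int = 0

    def __post_init__(self) -> None:
        if self.K < 2 or self.M < 2:
            raise ValueError("need K >= 2 and M >= 2")
        if not 0 <= self.beta <= 1:
            raise ValueError("beta must lie in [0, 1]")
        if self.N_phot < 1:
            raise ValueError("N_phot must be a positive integer")


@dataclass(frozen=True)
class SpectrumBasis:
    """Reference spectra ``r`` ((M+1) x K, last row the common spectrum) and,
    once mixed, the class spectra ``s`` (M x K).  All rows sum to 1."""

    r: np.ndarray
    s: np.ndarray | None = None

    def __post_init__(self) -> None:
        for name, mat in (("r", self.r), ("s", self.s)):
            if mat is None:
                continue
            mat = np.asarray(mat, dtype=float)
            if np.any(mat < 0):
                raise ValueError(f"{name} must be non-negative")
            if not np.allclose(mat.sum(axis=1), 1.0, atol=1e-9):
                raise ValueError(f"rows of {name} must sum to 1")
            object.__setattr__(self, name, mat)


def draw_reference_spectra(cfg: SimulationConfig) -> SpectrumBasis:
    """Draw ``M + 1`` normalized reference spectra (the last is the common one).

    Each channel intensity is an independent draw from a unit-mean exponential,
    raised to ``alpha`` and row-normalized; larger ``alpha`` concentrates mass
    in fewer channels (sharper peaks).
    """
    rng = np.random.default_rng(cfg.seed)
    r = rng.exponential(scale=1.0, size=(cfg.M + 1, cfg.K)) ** cfg.alpha
    return SpectrumBasis(r=r / r.sum(axis=1, keepdims=True))


def mix_spectra(basis: SpectrumBasis, beta: float) -> SpectrumBasis:
    """Fill the class spectra ``s_j = (1 - beta) r_j + beta r_common``.

    A convex combination of normalized rows is normalized, so no
    renormalization is needed.  ``beta = 0`` returns the independent spectra;
    ``beta = 1`` makes every class identical to the common spectrum.
    """
    if not 0 <= beta <= 1:
        raise ValueError("beta must lie in [0, 1]")
    r, common = basis.r[:-1], basis.r[-1]
    return SpectrumBasis(r=basis.r, s=(1.0 - beta) * r + beta * common)


def sample_photon_counts(
    s_j: np.ndarray, N_phot: int, rng, size: int | None = None
) -> np.ndarray:
    """Photon counting noise on a spectrum: multinomial draw(s) with channel
    probabilities ``s_j`` and ``N_phot`` trials."""
    s_j = np.asarray(s_j, dtype=float)
    if np.any(s_j < 0):
        raise ValueError("spectrum probabilities must be non-negative")
    rng = np.random.default_rng(rng)
    return rng.multinomial(N_phot, s_j / s_j.sum(), size=size)


def filter_outputs(F: FilterBank, s: np.ndarray) -> np.ndarray:
    """Optical efficiencies ``mu_ij = F_i . s_j``: the fraction of the
    normalized spectrum ``s_j`` transmitted by binary filter ``i``.

    ``s`` may be one spectrum (returns a length-N vector) or a stack of
    spectra (returns ``n_spectra x N``).
    """
    s = np.asarray(s, dtype=float)
    if s.shape[-1] != F.n_wavenumbers:
        raise ValueError("spectrum length must equal the filter bank's K")
    return s @ F.B.T


def sample_filter_counts(
    mu_j: np.ndarray, N_phot: int, rng, size: int | None = None
) -> np.ndarray:
    """Photon counting noise at the filter level: multinomial draw(s) over the
    N filters with probabilities ``p_ij = mu_ij / sum_i mu_ij``."""
    mu_j = np.asarray(mu_j, dtype=float)
    total = mu_j.sum()
    if total <= 0:
        raise ValueError("all filter efficiencies are zero")
    rng = np.random.default_rng(rng)
    return rng.multinomial(N_phot, mu_j / total, size=size)


def simulate_species_dataset(
    cfg: SimulationConfig, n_per_class: int, rng=None
) -> tuple[np.ndarray, np.ndarray, SpectrumBasis]:
    """Noisy spectrum-level dataset for the simulation study.

    Returns ``(counts, labels, basis)`` where ``counts`` stacks
    ``n_per_class`` multinomial draws per species (each a full noisy spectrum
    of ``N_phot`` photons) and ``labels`` are integer class codes.
    """
    basis = mix_spectra(draw_reference_spectra(cfg), cfg.beta)
    rng = np.random.default_rng(cfg.seed + 1 if rng is None else rng)
    counts = np.vstack(
        [sample_photon_counts(sj, cfg.N_phot, rng, size=n_per_class) for sj in basis.s]
    )
    labels = np.repeat(np.arange(cfg.M), n_per_class)
    return counts.astype(float), labels, basis


# ---------------------------------------------------------------------------
# Cell-like fixture generator


@dataclass(frozen=True)
class CellFixtureConfig:
    """Structure and noise levels of the synthetic single-cell fixture.

    Defaults emulate a small neuron-differentiation-style study: 3 cell
    classes measured across 3 cell lines x 3 replicates with repeated
    measurements per cell, class-specific Raman peak sets on a fingerprint-
    region grid, a smooth additive baseline comparable in integrated intensity
    to the peaks, ~2-fold lognormal per-cell intensity spread, and mild
    multiplicative batch effects per cell line and replicate.
    """

    n_classes: int = 3
    n_cell_lines: int = 3
    n_replicates: int = 3
    cells_per_replicate: int = 4
    measurements_per_cell: int = 3
    n_wavenumbers: int = 200
    wavenumber_range: tuple[float, float] = (320.0, 1800.0)
    peaks_per_class: int = 2  # weak peaks unique to each class
    class_peak_amplitude: float = 0.2  # relative to the shared peaks
    shared_peaks: int = 12  # peak set common to all classes
    class_amp_variation: float = 0.25  # class-specific modulation of shared peaks
    peak_width_range: tuple[float, float] = (12.0, 40.0)  # cm^-1
    baseline_amplitude: float = 1.0  # relative to mean peak signal
    cell_scale_sigma: float = 0.35  # lognormal sigma of per-cell intensity
    line_effect: float = 0.0  # multiplicative sd of cell-line peak offsets
    replicate_effect: float = 0.0  # multiplicative sd of replicate offsets
    photon_budget: float = 2e4  # expected counts per spectrum
    seed: int = 0

    def __post_init__(self) -> None:
        counts = (
            self.n_classes,
            self.n_cell_lines,
            self.n_replicates,
            self.cells_per_replicate,
            self.measurements_per_cell,
            self.n_wavenumbers,
        )
        if any(c < 1 for c in counts):
            raise ValueError("all fixture counts must be >= 1")


def _class_templates(cfg: CellFixtureConfig, rng) -> np.ndarray:
    """Normalized peak templates, one per class.

    All classes share a dominant peak set (the common biochemistry) and
    differ only in class-specific modulations of those peak amplitudes plus a
    few weak class-exclusive peaks — so class-mean spectra are strongly
    correlated, as they are for real cell types.
    """
    lo, hi = cfg.wavenumber_range
    wn = np.linspace(lo, hi, cfg.n_wavenumbers)

    def gaussians(centers, widths, amps):
        return (
            amps[:, None] * np.exp(-0.5 * ((wn - centers[:, None]) / widths[:, None]) ** 2)
        ).sum(axis=0)

    shared_centers = rng.uniform(lo + 50, hi - 50, cfg.shared_peaks)
    shared_widths = rng.uniform(*cfg.peak_width_range, cfg.shared_peaks)
    shared_amps = rng.uniform(0.5, 1.5, cfg.shared_peaks)
    templates = np.empty((cfg.n_classes, cfg.n_wavenumbers))
    for c in range(cfg.n_classes):
        modulation = rng.uniform(
            1.0 - cfg.class_amp_variation, 1.0 + cfg.class_amp_variation, cfg.shared_peaks
        )
        spec = gaussians(shared_centers, shared_widths, shared_amps * modulation)
        if cfg.peaks_per_class:
            centers = rng.uniform(lo + 50, hi - 50, cfg.peaks_per_class)
            widths = rng.uniform(*cfg.peak_width_range, cfg.peaks_per_class)
            amps = cfg.class_peak_amplitude * rng.uniform(0.5, 1.5, cfg.peaks_per_class)
            spec = spec + gaussians(centers, widths, amps)
        templates[c] = spec / spec.sum()
    return templates


def generate_cell_fixture(cfg: CellFixtureConfig) -> RamanSpectrumSet:
    """Generate a raw-count fixture with full nested metadata.

    Each class is assigned to every cell line x replicate cell group so the
    output realizes exactly
    ``n_classes * n_cell_lines * n_replicates * cells_per_replicate *
    measurements_per_cell`` spectra.  Per spectrum, expected counts are
    ``cell_scale * photon_budget * (template + baseline)`` and the observed
    counts are Poisson.  Cell ids are replicate-nested (one cell never spans
    replicates), matching how repeated measurements arise in practice.
    """
    root = np.random.SeedSequence(cfg.seed)
    tmpl_rng, batch_rng, cell_rng, noise_rng = (
        np.random.default_rng(s) for s in root.spawn(4)
    )
    templates = _class_templates(cfg, tmpl_rng)
    lo, hi = cfg.wavenumber_range
    wn = np.linspace(lo, hi, cfg.n_wavenumbers)
    x = np.linspace(-1, 1, cfg.n_wavenumbers)

    # multiplicative batch fields: smooth per-line / per-replicate spectral tilts
    def batch_field(sd):
        coef = batch_rng.normal(0.0, sd, size=3)
        return np.exp(coef[0] * x + coef[1] * x**2 + coef[2] * np.sin(2 * np.pi * x))

    line_fields = [batch_field(cfg.line_effect) for _ in range(cfg.n_cell_lines)]
    rep_fields = [
        [batch_field(cfg.replicate_effect) for _ in range(cfg.n_replicates)]
        for _ in range(cfg.n_cell_lines)
    ]

    spectra, labels, lines, reps, cells = [], [], [], [], []
    for li in range(cfg.n_cell_lines):
        for ri in range(cfg.n_replicates):
            for ci in range(cfg.cells_per_replicate):
                for klass in range(cfg.n_classes):
                    cell_id = f"L{li + 1}_R{ri + 1}_C{ci + 1}_K{klass}"
                    scale = cell_rng.lognormal(0.0, cfg.cell_scale_sigma)
                    # per-cell smooth baseline, non-negative by construction
                    bcoef = cell_rng.uniform(0.2, 1.0, size=3)
                    baseline = (
                        cfg.baseline_amplitude
                        * (bcoef[0] + bcoef[1] * (1 - x) / 2 + bcoef[2] * (1 - x**2))
                        / cfg.n_wavenumbers
                    )
                    mean_spec = templates[klass] * line_fields[li] * rep_fields[li][ri]
                    for _ in range(cfg.measurements_per_cell):
                        lam = scale * cfg.photon_budget * (mean_spec + baseline)
                        spectra.append(noise_rng.poisson(lam).astype(float))
                        labels.append(f"class{klass}")
                        lines.append(f"line{li + 1}")
                        reps.append(f"rep{ri + 1}")
                        cells.append(cell_id)

    return RamanSpectrumSet(
        intensities=np.vstack(spectra),
        wavenumbers=wn,
        labels=np.asarray(labels),
        cell_line=np.asarray(lines),
        replicate=np.asarray(reps),
        cell_id=np.asarray(cells),
        stage="raw",
    )
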