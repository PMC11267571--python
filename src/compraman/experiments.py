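"""Scripted computational experiments.

Reproductions of the headline analyses on synthetic data (or, via the same
functions, on real deposits): the filter-count x normalization x constraint
sweep, the correlated-spectra simulation study comparing the network against
Bhattacharyya-bound-optimized filters, leave-one-replicate/cell-line-out
generalization, and the per-class filter-output encoding summary.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np
import pandas as pd

from .baselines import naive_accuracy, svm_fit_predict
from .bb_filters import (
    MultinomialClassModel,
    bb_multinomial,
    estimate_gaussian_model,
    mlc_gaussian,
    mlc_multinomial,
    optimize_filters_swap,
)
from .filter_nn import FilterNNConfig, TrainedFilterModel, select_model, train_two_stage
from .simulate import (
    SimulationConfig,
    filter_outputs,
    sample_filter_counts,
    simulate_species_dataset,
)
from .spectra_data import RamanSpectrumSet, grouped_split, stratified_split

__all__ = [
    "run_filter_sweep",
    "run_simulation_study",
    "run_generalization_splits",
    "filter_output_encoding",
]


def run_filter_sweep(
    data: RamanSpectrumSet,
    n_filters_grid=(1, 2, 3, 4, 5),
    normalizations=("layer", "batch"),
    constraints=("nonneg", "binary"),
    n_splits: int = 5,
    base_cfg: FilterNNConfig | None = None,
) -> pd.DataFrame:
    """Accuracy sweep over (n_filters, normalization, constraint).

    Every grid cell runs the full split/train/select protocol over the same
    ``n_splits`` stratified splits; reference rows record the raw-spectrum SVM
    and the naive majority model per split.  Returns a tidy table with one
    row per (grid cell, split).
    """
    if base_cfg is None:
        base_cfg = FilterNNConfig(n_classes=data.classes.size)
    rows = []
    for n_filters in n_filters_grid:
        for norm in normalizations:
            for constraint in constraints:
                cfg = replace(
                    base_cfg,
                    n_filters=n_filters,
                    normalization=norm,
                    constraint=constraint,
                )
                report = select_model(data, cfg, n_splits=n_splits)
                for split, acc in enumerate(report["test_accuracy"]):
                    rows.append(
                        {
                            "model": "filter_nn",
                            "n_filters": n_filters,
                            "normalization": norm,
                            "constraint": constraint,
                            "split": split,
                            "accuracy": acc,
                        }
                    )
    # reference lines, one per split on the same seeds
    for split in range(n_splits):
        train, test = stratified_split(data, 0.2, seed=base_cfg.seed + 1000 + split)
        svm_acc, _ = svm_fit_predict(train, test, standardize=False)
        for model_name, acc in (
            ("svm_raw", svm_acc),
            ("naive", naive_accuracy(train, test)),
        ):
            rows.append(
                {
                    "model": model_name,
                    "n_filters": None,
                    "normalization": None,
                    "constraint": None,
                    "split": split,
                    "accuracy": acc,
                }
            )
    return pd.DataFrame(rows)


def run_simulation_study(
    beta_grid=(0.0, 0.25, 0.5, 0.75, 1.0),
    cfg: SimulationConfig = SimulationConfig(),
    n_per_class: int = 10_000,
    n_filters: int = 3,
    nn_cfg: FilterNNConfig | None = None,
    optimizer_kwargs: dict | None = None,
) -> pd.DataFrame:
    """Correlated-spectra simulation study.

    For each correlation level ``beta``: draw ``n_per_class`` noisy spectra
    per species, train the simulated-data network preset on them, optimize a
    filter bank by minimizing the multinomial Bhattacharyya bound, and
    classify noisy filter counts by maximum likelihood.  Reports per-beta NN
    test accuracy, MLC accuracy, empirical MLC error with its Monte-Carlo
    standard error, and the bound.
    """
    optimizer_kwargs = optimizer_kwargs or {}
    rows = []
    for b_idx, beta in enumerate(beta_grid):
        scfg = replace(cfg, beta=beta)
        counts, labels, basis = simulate_species_dataset(scfg, n_per_class)
        dataset = RamanSpectrumSet(
            intensities=counts,
            wavenumbers=np.arange(1.0, cfg.K + 1),
            labels=labels.astype(str),
        )
        if nn_cfg is None:
            net_cfg = FilterNNConfig.simulated(n_classes=cfg.M, seed=cfg.seed + b_idx)
        else:
            net_cfg = replace(nn_cfg, seed=nn_cfg.seed + b_idx)
        train, test = stratified_split(dataset, 0.2, seed=cfg.seed + b_idx)
        model = train_two_stage(train, net_cfg)
        nn_acc = model.accuracy(test.intensities, test.labels)

        noise_model = MultinomialClassModel(s=basis.s, N_phot=cfg.N_phot)
        bank, _ = optimize_filters_swap(
            lambda F: bb_multinomial(F, noise_model),
            n_filters=n_filters,
            K=cfg.K,
            seed=cfg.seed + 10 * b_idx,
            **optimizer_kwargs,
        )
        bound = bb_multinomial(bank, noise_model)
        rng = np.random.default_rng(cfg.seed + 10 * b_idx + 5)
        correct = 0
        total = cfg.M * n_per_class
        for j in range(cfg.M):
            mu = filter_outputs(bank, basis.s[j])
            draws = sample_filter_counts(mu, cfg.N_phot, rng, size=n_per_class)
            correct += int(np.sum(mlc_multinomial(draws, bank, noise_model) == j))
        mlc_acc = correct / total
        mlc_err = 1.0 - mlc_acc
        rows.append(
            {
                "beta": beta,
                "nn_accuracy": nn_acc,
                "mlc_accuracy": mlc_acc,
                "mlc_error": mlc_err,
                "mlc_error_mc_sigma": float(np.sqrt(mlc_err * (1 - mlc_err) / total)),
                "bb_bound": bound,
            }
        )
    return pd.DataFrame(rows)


def run_generalization_splits(
    data: RamanSpectrumSet,
    key: str = "replicate",
    cfg: FilterNNConfig | None = None,
) -> pd.DataFrame:
    """Leave-one-``key``-level-out evaluation (``key`` in {replicate, cell_line}).

    Each fold trains the filter network on all remaining levels and evaluates
    on the held-out level; confusion matrices are row-normalized by true
    class.  Returns one row per fold with the accuracy and confusion matrix.
    """
    levels = np.unique(getattr(data, key))
    if levels.size < 3:
        raise ValueError(f"need >= 3 levels of {key!r} for leave-one-out folds")
    if cfg is None:
        cfg = FilterNNConfig(n_filters=5, normalization="layer", constraint="binary",
                             n_classes=data.classes.size)
    classes = data.classes
    rows = []
    for fold, level in enumerate(levels):
        train, test = grouped_split(data, key, level)
        model = train_two_stage(train, replace(cfg, seed=cfg.seed + fold))
        pred = model.predict(test.intensities)
        acc = float(np.mean(pred == test.labels))
        confusion = np.zeros((classes.size, classes.size))
        for i, true_cls in enumerate(classes):
            mask = test.labels == true_cls
            if mask.any():
                for k, pred_cls in enumerate(classes):
                    confusion[i, k] = np.mean(pred[mask] == pred_cls)
        rows.append(
            {"fold": fold, "held_out": level, "accuracy": acc, "confusion": confusion}
        )
    return pd.DataFrame(rows)


def filter_output_encoding(
    model: TrainedFilterModel, data: RamanSpectrumSet
) -> np.ndarray:
    """Per-class filter-activation code: the ``N x C`` matrix of filter/raw-
    spectrum dot products averaged per class, then standardized filter-wise
    and subsequently class-wise (two-pass)."""
    if model.config.constraint != "binary":
        raise ValueError("encoding is defined for the binary-constrained model")
    classes = data.classes
    outputs = data.intensities @ model.W1  # n_spectra x N
    enc = np.column_stack(
        [outputs[data.labels == c].mean(axis=0) for c in classes]
    )  # N x C

    def standardize(mat, axis):
        mu = mat.mean(axis=axis, keepdims=True)
        sd = mat.std(axis=axis, keepdims=True)
        return (mat - mu) / np.where(sd > 0, sd, 1.0)

    enc = standardize(enc, axis=1)  # per filter, across classes
    enc = standardize(enc, axis=0)  # per class, across filters
    return enc
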