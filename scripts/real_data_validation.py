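"""Optional validation against a locally downloaded single-cell Raman deposit.

The neuron-differentiation data set (iPSCs, NSCs, neurons; https://osf.io/9env5/)
is not bundled with this package and no network access is assumed: download
it yourself, export the spectra as a wide CSV (header row = wavenumbers, one
row per spectrum) with a metadata CSV (columns: label, and optionally
cell_line / replicate / cell_id), and point this script at the files.

It reproduces the headline experiment: restrict to the 320-1800 cm^-1
fingerprint region, drop failed (all-zero) spectra, then run the 4- and
5-filter layer-norm binary networks over 5 stratified splits next to the
raw-spectrum SVM and naive references.  With the full deposit, the best
split accuracies are expected to land within a few percentage points of 86%
(4 filters) and 90% (5 filters).

Usage:
    python scripts/real_data_validation.py spectra.csv metadata.csv \
        --orientation rows --seed 1
"""

from __future__ import annotations

import argparse

import numpy as np

from compraman import (
    FilterNNConfig,
    drop_failed,
    naive_accuracy,
    read_spectra,
    restrict_region,
    select_model,
    svm_fit_predict,
)
from compraman.spectra_data import stratified_split


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("table")
    parser.add_argument("metadata")
    parser.add_argument("--orientation", choices=["rows", "columns"], default="rows")
    parser.add_argument("--lo", type=float, default=320.0)
    parser.add_argument("--hi", type=float, default=1800.0)
    parser.add_argument("--seed", type=int, default=1)
    parser.add_argument("--n-splits", type=int, default=5)
    args = parser.parse_args()

    data = read_spectra(args.table, args.metadata, orientation=args.orientation)
    data = restrict_region(drop_failed(data), args.lo, args.hi)
    print(f"{data.n_spectra} spectra x {data.n_wavenumbers} wavenumbers, "
          f"classes: {dict(data.class_counts())}")

    for n_filters in (4, 5):
        cfg = FilterNNConfig(
            n_filters=n_filters,
            normalization="layer",
            constraint="binary",
            n_classes=data.classes.size,
            seed=args.seed,
        )
        report = select_model(data, cfg, n_splits=args.n_splits)
        accs = report["test_accuracy"]
        print(f"{n_filters} filters: test accuracies "
              f"{[round(a, 3) for a in accs]}, best {max(accs):.3f}")

    svm_accs, naive_accs = [], []
    for split in range(args.n_splits):
        train, test = stratified_split(data, 0.2, seed=args.seed + 1000 + split)
        svm_accs.append(svm_fit_predict(train, test, standardize=False)[0])
        naive_accs.append(naive_accuracy(train, test))
    print(f"raw-spectrum SVM: median {np.median(svm_accs):.3f}; "
          f"naive: {np.median(naive_accs):.3f}")


if __name__ == "__main__":
    main()
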