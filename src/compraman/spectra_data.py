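"""Container, I/O and splitting utilities for labeled single-cell Raman spectra.

A :class:`RamanSpectrumSet` holds an ``n_spectra x n_wavenumbers`` intensity
matrix together with the wavenumber axis (cm^-1) and per-spectrum metadata:
the class label (cell type or state), the cell line, the biological/technical
replicate, and a cell identifier grouping repeated measurements of the same
cell.  Every operation in this package consumes and produces this container,
filtering metadata in lockstep with the rows it keeps.

On disk a set is a wide delimited table (first row: wavenumbers; one row per
spectrum) plus a sidecar metadata table keyed by row index — the layout public
Raman deposits typically ship in.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "RamanSpectrumSet",
    "read_spectra",
    "write_spectra",
    "drop_failed",
    "restrict_region",
    "stratified_split",
    "grouped_split",
]

#: allowed processing stages, in pipeline order
STAGES = ("raw", "baseline_corrected", "normalized")

_META_COLUMNS = ("label", "cell_line", "replicate", "cell_id")


@dataclass(frozen=True)
class RamanSpectrumSet:
    """Labeled Raman spectra on a common wavenumber grid.

    Parameters
    ----------
    intensities
        ``(n_spectra, n_wavenumbers)`` array.  Photon counts for ``stage="raw"``,
        arbitrary units after baseline correction / normalization.
    wavenumbers
        Strictly increasing axis in cm^-1, length ``n_wavenumbers``.
    labels, cell_line, replicate, cell_id
        Per-spectrum metadata arrays of length ``n_spectra``.
    stage
        One of ``"raw"``, ``"baseline_corrected"``, ``"normalized"``.
    """

    intensities: np.ndarray
    wavenumbers: np.ndarray
    labels: np.ndarray = field(default=None)  # type: ignore[assignment]
    cell_line: np.ndarray = field(default=None)  # type: ignore[assignment]
    replicate: np.ndarray = field(default=None)  # type: ignore[assignment]
    cell_id: np.ndarray = field(default=None)  # type: ignore[assignment]
    stage: str = "raw"

    def __post_init__(self) -> None:
        intens = np.asarray(self.intensities, dtype=float)
        wn = np.asarray(self.wavenumbers, dtype=float)
        if intens.ndim != 2:
            raise ValueError("intensities must be a 2-D matrix")
        if wn.ndim != 1 or wn.size != intens.shape[1]:
            raise ValueError("wavenumbers length must equal n_wavenumbers")
        if not np.all(np.diff(wn) > 0):
            raise ValueError("wavenumbers must be strictly increasing")
        if not np.all(np.isfinite(intens)):
            raise ValueError("intensities contain non-finite values")
        if self.stage not in STAGES:
            raise ValueError(f"stage must be one of {STAGES}, got {self.stage!r}")
        if self.stage == "raw" and np.any(intens < 0):
            raise ValueError("raw intensities must be non-negative")

        n = intens.shape[0]
        object.__setattr__(self, "intensities", intens)
        object.__setattr__(self, "wavenumbers", wn)
        for name in _META_COLUMNS:
            attr = "labels" if name == "label" else name
            value = getattr(self, attr)
            if value is None:
                value = np.zeros(n, dtype=object)
                value[:] = "0"
            value = np.asarray(value)
            if value.shape != (n,):
                raise ValueError(f"{attr} must have one entry per spectrum")
            object.__setattr__(self, attr, value)

    # -- shape -------------------------------------------------------------
    @property
    def n_spectra(self) -> int:
        return self.intensities.shape[0]

    @property
    def n_wavenumbers(self) -> int:
        return self.intensities.shape[1]

    @property
    def classes(self) -> np.ndarray:
        return np.unique(self.labels)

    def __len__(self) -> int:
        return self.n_spectra

    # -- subsetting --------------------------------------------------------
    def take(self, rows: np.ndarray) -> "RamanSpectrumSet":
        """Return a new set containing ``rows`` (order preserved), metadata aligned."""
        rows = np.asarray(rows)
        return dataclasses.replace(
            self,
            intensities=self.intensities[rows],
            labels=self.labels[rows],
            cell_line=self.cell_line[rows],
            replicate=self.replicate[rows],
            cell_id=self.cell_id[rows],
        )

    def with_intensities(
        self,
        intensities: np.ndarray,
        wavenumbers: np.ndarray | None = None,
        stage: str | None = None,
    ) -> "RamanSpectrumSet":
        """Replace the intensity matrix (and optionally axis/stage), keeping metadata."""
        return dataclasses.replace(
            self,
            intensities=intensities,
            wavenumbers=self.wavenumbers if wavenumbers is None else wavenumbers,
            stage=self.stage if stage is None else stage,
        )

    def metadata(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "label": self.labels,
                "cell_line": self.cell_line,
                "replicate": self.replicate,
                "cell_id": self.cell_id,
            }
        )

    def class_counts(self) -> pd.Series:
        return pd.Series(self.labels).value_counts().sort_index()


# ---------------------------------------------------------------------------
# I/O


def read_spectra(
    table_path,
    metadata_path=None,
    *,
    orientation: str = "rows",
    stage: str = "raw",
) -> RamanSpectrumSet:
    """Read a spectrum table (and optional metadata sidecar) from delimited files.

    The table's header row carries the wavenumber axis; each subsequent row is
    one spectrum.  ``orientation="columns"`` transposes (spectra in columns,
    wavenumbers in the first column), accommodating deposits shipped either way.
    The metadata table must provide one row per spectrum with columns
    ``label`` (required) and optionally ``cell_line``, ``replicate``, ``cell_id``.
    """
    sep = "\t" if str(table_path).endswith((".tsv", ".txt")) else ","
    table = pd.read_csv(table_path, sep=sep)
    if orientation == "columns":
        wn = table.iloc[:, 0].to_numpy(dtype=float)
        intens = table.iloc[:, 1:].to_numpy(dtype=float).T
    elif orientation == "rows":
        wn = np.asarray([float(c) for c in table.columns], dtype=float)
        intens = table.to_numpy(dtype=float)
    else:
        raise ValueError("orientation must be 'rows' or 'columns'")

    meta = {}
    if metadata_path is not None:
        msep = "\t" if str(metadata_path).endswith((".tsv", ".txt")) else ","
        mtab = pd.read_csv(metadata_path, sep=msep)
        if len(mtab) != intens.shape[0]:
            raise ValueError(
                f"metadata has {len(mtab)} rows but table has {intens.shape[0]} spectra"
            )
        for col in _META_COLUMNS:
            if col in mtab.columns:
                meta["labels" if col == "label" else col] = mtab[col].to_numpy()

    return RamanSpectrumSet(intensities=intens, wavenumbers=wn, stage=stage, **meta)


def write_spectra(s: RamanSpectrumSet, table_path, metadata_path=None) -> None:
    """Write the wide intensity table and, optionally, the metadata sidecar."""
    table = pd.DataFrame(s.intensities, columns=[repr(float(w)) for w in s.wavenumbers])
    table.to_csv(table_path, index=False)
    if metadata_path is not None:
        s.metadata().to_csv(metadata_path, index=False)


# ---------------------------------------------------------------------------
# Quality filtering and region restriction


def drop_failed(s: RamanSpectrumSet) -> RamanSpectrumSet:
    """Remove failed measurements: spectra whose intensities are all exactly zero."""
    keep = np.flatnonzero(np.any(s.intensities != 0.0, axis=1))
    if keep.size == s.n_spectra:
        return s
    return s.take(keep)


def restrict_region(s: RamanSpectrumSet, lo: float, hi: float) -> RamanSpectrumSet:
    """Keep wavenumbers ``w`` with ``lo <= w <= hi`` (e.g. the 320-1800 cm^-1
    fingerprint region), preserving order."""
    if not lo < hi:
        raise ValueError("require lo < hi")
    cols = np.flatnonzero((s.wavenumbers >= lo) & (s.wavenumbers <= hi))
    if cols.size == 0:
        raise ValueError(f"no wavenumbers in [{lo}, {hi}]")
    return s.with_intensities(s.intensities[:, cols], wavenumbers=s.wavenumbers[cols])


# ---------------------------------------------------------------------------
# Splitting


def stratified_split(
    s: RamanSpectrumSet, test_frac: float, seed: int
) -> tuple[RamanSpectrumSet, RamanSpectrumSet]:
    """Stratified train/test split: per-class test proportions match ``test_frac``.

    Deterministic given ``seed``; train and test are disjoint and exhaustive.
    """
    if not 0 < test_frac < 1:
        raise ValueError("test_frac must lie in (0, 1)")
    counts = s.class_counts()
    if (counts < 2).any():
        bad = counts[counts < 2].index.tolist()
        raise ValueError(f"classes with fewer than 2 spectra cannot be split: {bad}")

    rng = np.random.default_rng(seed)
    test_rows: list[np.ndarray] = []
    for cls in s.classes:
        rows = np.flatnonzero(s.labels == cls)
        n_test = int(round(test_frac * rows.size))
        n_test = min(max(n_test, 1), rows.size - 1)
        test_rows.append(rng.choice(rows, size=n_test, replace=False))
    test_idx = np.sort(np.concatenate(test_rows))
    mask = np.zeros(s.n_spectra, dtype=bool)
    mask[test_idx] = True
    return s.take(np.flatnonzero(~mask)), s.take(test_idx)


def grouped_split(
    s: RamanSpectrumSet, holdout_key: str, holdout_value
) -> tuple[RamanSpectrumSet, RamanSpectrumSet]:
    """Leave-one-group-out split: hold out every spectrum whose ``holdout_key``
    metadata (``"replicate"`` or ``"cell_line"``) equals ``holdout_value``."""
    if holdout_key not in ("replicate", "cell_line"):
        raise ValueError("holdout_key must be 'replicate' or 'cell_line'")
    values = getattr(s, holdout_key)
    mask = values == holdout_value
    if not mask.any():
        raise ValueError(f"{holdout_key}={holdout_value!r} not present in metadata")
    return s.take(np.flatnonzero(~mask)), s.take(np.flatnonzero(mask))
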