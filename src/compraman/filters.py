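"""Binary spectral filter banks.

A filter bank is an ``N x K`` binary matrix: row ``i`` is the spectral
response of optical filter ``i`` over ``K`` wavenumbers, with 1 meaning the
wavenumber is transmitted to the detector.  Both filter-design routes (the
constrained neural network and the Bhattacharyya-bound swap optimizer)
produce this object; it is the artifact a spectrometer would implement, e.g.
on a digital micromirror device.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["FilterBank"]


@dataclass(frozen=True)
class FilterBank:
    """``N x K`` binary filter matrix plus the scale factor absorbed downstream.

    ``scale`` is the common nonzero first-layer weight value ``c`` of a
    binary-constrained network; physically the filters are 0/1 and ``c`` is
    folded into the downstream classifier.
    """

    B: np.ndarray
    scale: float = 1.0
    wavenumbers: np.ndarray | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        B = np.asarray(self.B)
        if B.ndim != 2:
            raise ValueError("filter bank must be a 2-D matrix")
        if not np.isin(B, (0, 1)).all():
            raise ValueError("filter bank entries must be binary (0 or 1)")
        if not self.scale > 0:
            raise ValueError("scale must be positive")
        empty = np.flatnonzero(B.sum(axis=1) == 0)
        if empty.size:
            warnings.warn(f"filters {empty.tolist()} transmit nothing", stacklevel=2)
        object.__setattr__(self, "B", B.astype(float))
        if self.wavenumbers is not None:
            wn = np.asarray(self.wavenumbers, dtype=float)
            if wn.size != B.shape[1]:
                raise ValueError("wavenumber axis length must equal K")
            object.__setattr__(self, "wavenumbers", wn)

    @property
    def n_filters(self) -> int:
        return self.B.shape[0]

    @property
    def n_wavenumbers(self) -> int:
        return self.B.shape[1]

    def element_fraction(self) -> np.ndarray:
        """Per-filter fraction of nonzero (transmitting) elements."""
        return self.B.mean(axis=1)

    def optical_efficiency(self, spectra: np.ndarray) -> np.ndarray:
        """Mean intensity-weighted efficiency of each filter over normalized
        ``spectra`` (rows summing to 1); distinct from :meth:`element_fraction`."""
        spectra = np.atleast_2d(np.asarray(spectra, dtype=float))
        return (spectra @ self.B.T).mean(axis=0)

    # -- I/O ---------------------------------------------------------------
    def to_csv(self, path) -> None:
        """Write the bank as CSV with a wavenumber header row."""
        if self.wavenumbers is not None:
            cols = [repr(float(w)) for w in self.wavenumbers]
        else:
            cols = [str(k) for k in range(self.n_wavenumbers)]
        pd.DataFrame(self.B.astype(int), columns=cols).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, scale: float = 1.0) -> "FilterBank":
        table = pd.read_csv(path)
        wn = np.asarray([float(c) for c in table.columns])
        return cls(B=table.to_numpy(), scale=scale, wavenumbers=wn)
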