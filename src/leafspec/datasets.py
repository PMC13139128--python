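"""Core containers for leaf reflectance spectra and nitrogen measurements.

A :class:`SpectraMatrix` holds an ``n_samples x n_wavelengths`` reflectance
table together with its wavelength grid (nm) and sample identifiers.  Leaf
nitrogen content is a plain 1-D float array in percent of dry mass
("nitrogen vector") and travels alongside the spectra.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["SpectraMatrix", "read_wide_csv", "write_wide_csv"]


@dataclass
class SpectraMatrix:
    """Reflectance spectra on an explicit wavelength grid.

    Parameters
    ----------
    reflectance : ndarray, shape (n, m)
        Unitless reflectance values, one row per sample.
    wavelengths : ndarray, shape (m,)
        Strictly increasing wavelength grid in nm.
    sample_ids : list of str
        One label per row.
    """

    reflectance: np.ndarray
    wavelengths: np.ndarray
    sample_ids: list = field(default_factory=list)

    def __post_init__(self) -> None:
        self.reflectance = np.asarray(self.reflectance, dtype=float)
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        if self.reflectance.ndim != 2:
            raise ValueError("reflectance must be 2-D (samples x wavelengths)")
        n, m = self.reflectance.shape
        if self.wavelengths.shape != (m,):
            raise ValueError(
                f"wavelength grid length {self.wavelengths.shape} does not match "
                f"{m} reflectance columns"
            )
        if m >= 2 and not np.all(np.diff(self.wavelengths) > 0):
            raise ValueError("wavelengths must be strictly increasing")
        if not np.all(np.isfinite(self.reflectance)):
            raise ValueError("reflectance contains non-finite values")
        if not self.sample_ids:
            self.sample_ids = [f"s{i:04d}" for i in range(n)]
        if len(self.sample_ids) != n:
            raise ValueError("sample_ids length does not match number of rows")

    @property
    def n_samples(self) -> int:
        return self.reflectance.shape[0]

    @property
    def n_wavelengths(self) -> int:
        return self.reflectance.shape[1]

    def copy(self, reflectance: np.ndarray | None = None) -> "SpectraMatrix":
        """Return a copy, optionally with replaced reflectance values."""
        r = self.reflectance.copy() if reflectance is None else np.asarray(reflectance, float)
        return SpectraMatrix(r, self.wavelengths.copy(), list(self.sample_ids))

    def take(self, indices) -> "SpectraMatrix":
        """Row subset by integer indices (keeps grid)."""
        idx = np.asarray(indices, dtype=int)
        return SpectraMatrix(
            self.reflectance[idx],
            self.wavelengths.copy(),
            [self.sample_ids[i] for i in idx],
        )

    def select_bands(self, band_indices) -> np.ndarray:
        """Return the (n, k) design matrix of selected wavelength columns."""
        return self.reflectance[:, np.asarray(band_indices, dtype=int)]

    def to_frame(self, nitrogen: np.ndarray | None = None) -> pd.DataFrame:
        cols = {f"r{int(round(w)):04d}": self.reflectance[:, j]
                for j, w in enumerate(self.wavelengths)}
        df = pd.DataFrame(cols, index=pd.Index(self.sample_ids, name="sample_id"))
        if nitrogen is not None:
            df.insert(0, "nitrogen", np.asarray(nitrogen, float))
        return df


def write_wide_csv(path, spectra: SpectraMatrix, nitrogen: np.ndarray,
                   meta: dict | None = None) -> None:
    """Write the wide CSV layout (sample_id, nitrogen, r0400...r2500).

    A sidecar ``<path>.meta.json`` is written when ``meta`` is given, holding
    the generator configuration and seed so a dataset can be regenerated.
    """
    path = Path(path)
    try:
        spectra.to_frame(nitrogen).to_csv(path)
    except OSError as exc:  # pragma: no cover - exercised via bad paths only
        raise OSError(f"cannot write dataset to {path!s}: {exc}") from exc
    if meta is not None:
        sidecar = path.with_suffix(path.suffix + ".meta.json")
        sidecar.write_text(json.dumps(meta, indent=1, sort_keys=True))


def read_wide_csv(path):
    """Read the wide CSV layout back into ``(SpectraMatrix, nitrogen)``."""
    df = pd.read_csv(path, index_col="sample_id")
    nitrogen = df.pop("nitrogen").to_numpy(dtype=float)
    wavelengths = np.array([float(c[1:]) for c in df.columns])
    spectra = SpectraMatrix(df.to_numpy(dtype=float), wavelengths,
                            [str(s) for s in df.index])
    return spectra, nitrogen
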