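"""The modeling table: one mean ROI spectrum per record with its chemistry.

A :class:`SpectraTable` wraps a pandas DataFrame whose leading columns are
``sample_id, origin, form, range, poly_pct, ergo_pct`` followed by one column
per band center (named by its wavelength in nm).  All spectra in a table
share one wavelength grid; analyte reference values are nonnegative
percentages by mass.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .hypercube import WavelengthGrid

__all__ = ["SpectraTable", "META_COLUMNS", "ANALYTES"]

META_COLUMNS = ["sample_id", "origin", "form", "range", "poly_pct", "ergo_pct"]
ANALYTES = {"polysaccharide": "poly_pct", "ergosterol": "ergo_pct"}


@dataclass
class SpectraTable:
    """Mean ROI spectra plus sample metadata and analyte reference values."""

    frame: pd.DataFrame
    grid: WavelengthGrid

    def __post_init__(self):
        missing = [c for c in META_COLUMNS if c not in self.frame.columns]
        if missing:
            raise ValueError(f"table missing metadata columns {missing}")
        if len(self.band_columns) != len(self.grid):
            raise ValueError(
                f"table has {len(self.band_columns)} band columns but grid has "
                f"{len(self.grid)} wavelengths"
            )
        chem = self.frame[["poly_pct", "ergo_pct"]].to_numpy(dtype=float)
        if (chem < 0).any():
            raise ValueError("analyte reference values must be nonnegative")

    @property
    def band_columns(self) -> list[str]:
        return [c for c in self.frame.columns if c not in META_COLUMNS]

    def __len__(self) -> int:
        return len(self.frame)

    @property
    def X(self) -> np.ndarray:
        """(n_records, n_bands) spectral matrix."""
        return self.frame[self.band_columns].to_numpy(dtype=float)

    def y(self, analyte: str) -> np.ndarray:
        """Reference values for ``analyte`` ('polysaccharide' or 'ergosterol')."""
        if analyte not in ANALYTES:
            raise ValueError(f"unknown analyte {analyte!r}; choose from {sorted(ANALYTES)}")
        return self.frame[ANALYTES[analyte]].to_numpy(dtype=float)

    def subset(self, **filters) -> "SpectraTable":
        """Rows matching every column == value filter (e.g. form='cap')."""
        keep = pd.Series(True, index=self.frame.index)
        for col, val in filters.items():
            keep &= self.frame[col] == val
        return SpectraTable(self.frame[keep].reset_index(drop=True), self.grid)

    def iloc(self, indices) -> "SpectraTable":
        return SpectraTable(self.frame.iloc[indices].reset_index(drop=True), self.grid)

    @classmethod
    def from_records(cls, records: list[dict], grid: WavelengthGrid) -> "SpectraTable":
        """Build a table from dicts with metadata keys plus a 'spectrum' vector."""
        rows = []
        for rec in records:
            spec = np.asarray(rec["spectrum"], dtype=float)
            if spec.size != len(grid):
                raise ValueError("spectrum length does not match the grid")
            row = {k: rec[k] for k in META_COLUMNS}
            row.update({f"{w:.1f}": v for w, v in zip(grid.band_centers, spec)})
            rows.append(row)
        return cls(pd.DataFrame(rows), grid)

    def to_csv(self, path: str | Path) -> Path:
        path = Path(path)
        self.frame.to_csv(path, index=False)
        return path

    @classmethod
    def from_csv(cls, path: str | Path, range_label: str | None = None) -> "SpectraTable":
        frame = pd.read_csv(path)
        band_cols = [c for c in frame.columns if c not in META_COLUMNS]
        centers = np.array([float(c) for c in band_cols])
        if range_label is None:
            labels = frame["range"].unique()
            if len(labels) != 1:
                raise ValueError("table mixes spectral ranges; pass range_label")
            range_label = str(labels[0])
        return cls(frame, WavelengthGrid(centers, range_label))
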