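"""Hyperspectral cube containers, reflectance calibration and ROI extraction.

A cube is a ``(rows, cols, bands)`` block of nonnegative values on a known
wavelength grid.  Raw sensor cubes are converted to reflectance with white
(high-reflectance panel) and dark (shutter-closed) reference frames:

    R = (I_raw - I_dark) / (I_white - I_dark)

Pixels where the white reference does not exceed the dark reference carry no
radiometric information and are masked rather than divided.  Reflectance
outside [0, 1] is retained (not clipped) but the fraction of such values is
recorded in the cube metadata, since downstream regressors are scale-tolerant.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "WavelengthGrid",
    "HyperCube",
    "ReferenceFrames",
    "ROISpec",
    "ShapeMismatchError",
    "EmptyResultError",
    "ROIError",
    "calibrate_reflectance",
    "extract_roi_mean",
    "average_replicates",
    "VNIR_RANGE",
    "SWIR_RANGE",
]

# Spectral coverage of the two camera ranges, nm.
VNIR_RANGE = (385.0, 1009.0)
SWIR_RANGE = (899.0, 1695.0)
_RANGES = {"VNIR": VNIR_RANGE, "SWIR": SWIR_RANGE}


class ShapeMismatchError(ValueError):
    """Cube and reference frames disagree in shape."""


class EmptyResultError(ValueError):
    """An operation produced no valid pixels."""


class ROIError(ValueError):
    """An ROI references an out-of-bounds or masked pixel."""


@dataclass(frozen=True)
class WavelengthGrid:
    """Strictly increasing band centers (nm) for one spectral range."""

    band_centers: np.ndarray
    range_label: str

    def __post_init__(self):
        centers = np.asarray(self.band_centers, dtype=float)
        object.__setattr__(self, "band_centers", centers)
        if centers.ndim != 1 or centers.size == 0:
            raise ValueError("band_centers must be a non-empty 1-D array")
        if not np.all(np.diff(centers) > 0):
            raise ValueError("band_centers must be strictly increasing")
        if self.range_label not in _RANGES:
            raise ValueError(f"unknown range_label {self.range_label!r}")
        lo, hi = _RANGES[self.range_label]
        if centers[0] < lo or centers[-1] > hi:
            raise ValueError(
                f"{self.range_label} grid must lie within [{lo}, {hi}] nm, "
                f"got [{centers[0]}, {centers[-1]}]"
            )

    def __len__(self) -> int:
        return self.band_centers.size

    def nearest_index(self, nm: float) -> int:
        """Index of the band center closest to ``nm``."""
        return int(np.argmin(np.abs(self.band_centers - float(nm))))

    def indices_within(self, nm: float, halfwidth: float) -> np.ndarray:
        """Indices of band centers within ``nm`` +/- ``halfwidth``."""
        return np.flatnonzero(np.abs(self.band_centers - float(nm)) <= halfwidth)


@dataclass
class HyperCube:
    """A (rows, cols, bands) block with its grid and a per-pixel validity mask.

    ``mask`` is a boolean (rows, cols) plane, True where the pixel is usable.
    """

    values: np.ndarray
    grid: WavelengthGrid
    kind: str = "raw"
    mask: np.ndarray | None = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 3:
            raise ValueError("cube values must be 3-D (rows, cols, bands)")
        if self.values.shape[2] != len(self.grid):
            raise ValueError(
                f"band axis has {self.values.shape[2]} planes but grid has "
                f"{len(self.grid)} wavelengths"
            )
        if self.kind not in ("raw", "reflectance"):
            raise ValueError(f"kind must be 'raw' or 'reflectance', got {self.kind!r}")
        if self.mask is None:
            self.mask = np.ones(self.values.shape[:2], dtype=bool)
        else:
            self.mask = np.asarray(self.mask, dtype=bool)
            if self.mask.shape != self.values.shape[:2]:
                raise ValueError("mask shape must match the spatial shape")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape

    @property
    def n_bands(self) -> int:
        return self.values.shape[2]


@dataclass
class ReferenceFrames:
    """White and dark reference blocks matching the raw cube's shape."""

    white: np.ndarray
    dark: np.ndarray

    def __post_init__(self):
        self.white = np.asarray(self.white, dtype=float)
        self.dark = np.asarray(self.dark, dtype=float)
        if self.white.shape != self.dark.shape:
            raise ShapeMismatchError("white and dark frames must share a shape")


@dataclass(frozen=True)
class ROISpec:
    """Pixel coordinates representing one sample on one photograph.

    Coordinates are 0-based (row, col), row-major.  The acquisition protocol
    uses three pixels per region whose mean spectrum represents the sample.
    """

    sample_id: str
    origin_code: str
    form: str
    pixels: tuple
    replicate: int = 1

    def __post_init__(self):
        if self.form not in ("cap", "powder"):
            raise ValueError(f"form must be 'cap' or 'powder', got {self.form!r}")
        pix = tuple((int(r), int(c)) for r, c in self.pixels)
        if not pix:
            raise ValueError("ROI must contain at least one pixel")
        object.__setattr__(self, "pixels", pix)


def calibrate_reflectance(raw: HyperCube, refs: ReferenceFrames) -> HyperCube:
    """Convert a raw cube to reflectance via white/dark references.

    R = (I_raw - I_dark) / (I_white - I_dark) element-wise.  A pixel is masked
    wherever the white frame fails to exceed the dark frame in any band.

    Raises
    ------
    ShapeMismatchError
        If the reference frames do not match the raw cube's shape.
    EmptyResultError
        If every pixel ends up masked.
    """
    if raw.kind != "raw":
        raise ValueError("calibrate_reflectance expects a raw cube")
    if refs.white.shape != raw.values.shape:
        raise ShapeMismatchError(
            f"reference shape {refs.white.shape} != cube shape {raw.values.shape}"
        )
    denom = refs.white - refs.dark
    pixel_ok = raw.mask & np.all(denom > 0, axis=2)
    if not pixel_ok.any():
        raise EmptyResultError("all pixels masked: white never exceeds dark")

    values = np.zeros_like(raw.values)
    np.divide(raw.values - refs.dark, denom, out=values, where=pixel_ok[:, :, None])

    out_of_range = values[pixel_ok]
    frac_outside = float(np.mean((out_of_range < 0) | (out_of_range > 1)))
    meta = dict(raw.metadata)
    meta["fraction_outside_unit_interval"] = frac_outside
    return HyperCube(values, raw.grid, kind="reflectance", mask=pixel_ok, metadata=meta)


def extract_roi_mean(cube: HyperCube, roi: ROISpec) -> np.ndarray:
    """Per-band arithmetic mean spectrum over the ROI's pixels.

    Raises :class:`ROIError` naming the offending pixel if any coordinate is
    outside the cube or masked invalid.
    """
    rows, cols, _ = cube.shape
    for r, c in roi.pixels:
        if not (0 <= r < rows and 0 <= c < cols):
            raise ROIError(f"ROI pixel ({r}, {c}) outside cube bounds {rows}x{cols}")
        if not cube.mask[r, c]:
            raise ROIError(f"ROI pixel ({r}, {c}) is masked invalid")
    rr = np.array([p[0] for p in roi.pixels])
    cc = np.array([p[1] for p in roi.pixels])
    return cube.values[rr, cc, :].mean(axis=0)


def average_replicates(spectra: Sequence[np.ndarray] | Iterable[np.ndarray]) -> np.ndarray:
    """Per-band mean across replicate spectra of one sample."""
    spectra = [np.asarray(s, dtype=float) for s in spectra]
    if not spectra:
        raise ValueError("average_replicates requires at least one spectrum")
    lengths = {s.shape for s in spectra}
    if len(lengths) != 1:
        raise ValueError(f"replicate spectra differ in shape: {sorted(lengths)}")
    return np.mean(spectra, axis=0)
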