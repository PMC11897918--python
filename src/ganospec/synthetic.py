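"""Synthetic hyperspectral scenes of *Ganoderma lucidum* caps and powder.

The generator emulates the statistical structure the downstream chemometrics
assumes, so every stage — calibration, ROI extraction, wavelength selection,
regression — is testable without the (unreleased) instrument data:

* 32 samples in two physical forms (intact cap, pressed powder), photographed
  three times, in two spectral ranges (VNIR 385-1009 nm, SWIR 899-1695 nm).
* A Beer-Lambert-style reflectance proxy: a smooth form-dependent baseline
  attenuated by Gaussian absorption features whose depth is linear in analyte
  concentration.  Ergosterol drives the 1200 nm trough; polysaccharide drives
  C-H / O-H overtone features at 1300, 1430 and 1520 nm (SWIR) with a 960 nm
  VNIR analogue; a concentration-independent matrix band sits at 1100 nm.
* Multiplicative scatter: each physical sample carries a random broadband
  gain and smooth spectral tilt (Legendre shape), the dominant nuisance in
  diffuse-reflectance imaging.  Cap patches additionally show larger
  pixel-to-pixel brightness variance than powder (surface texture).
* Cap baseline strictly above the powder baseline, so mean cap reflectance
  exceeds mean powder reflectance at equal composition.

Raw cubes are emitted by inverting the calibration equation,
``raw = R * (white - dark) + dark``, with synthetic white/dark frames, so
that reflectance calibration is genuinely exercised downstream.

All randomness flows from ``SceneSpec.seed`` through named substreams;
sample-level scatter is shared across the three replicate photographs of a
sample (it is a property of the specimen, not of the exposure).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
import pandas as pd
from numpy.polynomial import legendre

from ._rng import substream
from .hypercube import (
    SWIR_RANGE,
    VNIR_RANGE,
    HyperCube,
    ROISpec,
    ReferenceFrames,
    WavelengthGrid,
)

__all__ = [
    "AbsorptionBand",
    "SceneSpec",
    "AnalytePanel",
    "ChemistryTable",
    "Scene",
    "DEFAULT_BANDS",
    "default_grid",
    "generate_concentrations",
    "generate_spectrum",
    "generate_cube",
    "generate_reference_table",
    "generate_scene",
    "informative_band_centers",
]


@dataclass(frozen=True)
class AbsorptionBand:
    """One Gaussian absorption feature.

    ``strength`` is absorbance per unit concentration (% by mass) at the band
    center; ``analyte`` is 'polysaccharide', 'ergosterol' or 'matrix' (the
    latter concentration-independent, evaluated at unit concentration).
    """

    center: float
    width: float
    analyte: str
    strength: float

    def __post_init__(self):
        if self.width <= 0:
            raise ValueError("band width must be positive")
        if self.strength < 0:
            raise ValueError("band strength must be nonnegative")
        if self.analyte not in ("polysaccharide", "ergosterol", "matrix"):
            raise ValueError(f"unknown analyte {self.analyte!r}")


# Feature positions follow the observed cap/powder spectra: absorption peaks
# near 1100, 1300 and 1520 nm, troughs near 1200 (ergosterol) and 1430 nm
# (O-H first overtone).  VNIR analogues sit at 930/960 nm; 680 nm is pigment.
DEFAULT_BANDS: tuple[AbsorptionBand, ...] = (
    AbsorptionBand(1100.0, 22.0, "matrix", 0.080),
    AbsorptionBand(1300.0, 18.0, "polysaccharide", 0.022),
    AbsorptionBand(1430.0, 16.0, "polysaccharide", 0.032),
    AbsorptionBand(1520.0, 18.0, "polysaccharide", 0.024),
    AbsorptionBand(1200.0, 15.0, "ergosterol", 0.360),
    AbsorptionBand(840.0, 20.0, "polysaccharide", 0.020),
    AbsorptionBand(880.0, 15.0, "ergosterol", 0.300),
    AbsorptionBand(680.0, 28.0, "matrix", 0.050),
)


@dataclass(frozen=True)
class SceneSpec:
    """Configuration of one synthetic acquisition campaign."""

    n_samples: int = 32
    forms: tuple[str, ...] = ("cap", "powder")
    ranges: tuple[str, ...] = ("VNIR", "SWIR")
    replicates: int = 3
    noise_sd: float = 0.005
    seed: int = 0
    concentration_ranges: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: {
            "polysaccharide": (0.5, 3.5),
            "ergosterol": (0.01, 0.30),
        }
    )
    bands: tuple[AbsorptionBand, ...] = DEFAULT_BANDS
    assay_cv: float = 0.02
    gain_sd: float = 0.015
    scatter_coef_sd: tuple[float, ...] = (0.012, 0.008, 0.005, 0.003)
    # independent per-sample interferent absorptions (center nm, sigma nm,
    # absorbance sd), overlapping the analyte overtone regions the way water,
    # lipid and protein bands overlap them in real NIR spectra; they are what
    # makes combining several analyte features genuinely better than one
    interferent_bands: tuple[tuple[float, float, float], ...] = (
        (1310.0, 33.0, 0.012),
        (1445.0, 35.0, 0.012),
        (1532.0, 30.0, 0.012),
    )
    pixel_jitter_sd: Mapping[str, float] = field(
        default_factory=lambda: {"cap": 0.02, "powder": 0.005}
    )
    cap_above_powder: bool = True
    patch_size: int = 6
    roi_pixels: int = 3
    frame_shape: tuple[int, int] | None = None

    def __post_init__(self):
        if self.n_samples < 1 or self.replicates < 1 or self.roi_pixels < 1:
            raise ValueError("counts must be positive")
        if self.noise_sd < 0 or self.assay_cv < 0 or self.gain_sd < 0:
            raise ValueError("noise levels must be nonnegative")
        for lo, hi in self.concentration_ranges.values():
            if lo > hi:
                raise ValueError("concentration range must have low <= high")
        unknown = set(self.forms) - {"cap", "powder"}
        if unknown:
            raise ValueError(f"unknown forms {sorted(unknown)}")

    def noiseless(self) -> "SceneSpec":
        """Copy with every stochastic perturbation switched off."""
        return replace(
            self,
            noise_sd=0.0,
            assay_cv=0.0,
            gain_sd=0.0,
            scatter_coef_sd=(0.0,) * len(self.scatter_coef_sd),
            pixel_jitter_sd={f: 0.0 for f in self.pixel_jitter_sd},
            interferent_bands=tuple(
                (c, w, 0.0) for c, w, _ in self.interferent_bands
            ),
        )


@dataclass
class AnalytePanel:
    """True per-sample analyte concentrations (% by mass)."""

    frame: pd.DataFrame  # sample_id, polysaccharide, ergosterol

    def __len__(self) -> int:
        return len(self.frame)

    def concentrations(self, i: int) -> dict[str, float]:
        row = self.frame.iloc[i]
        return {
            "polysaccharide": float(row["polysaccharide"]),
            "ergosterol": float(row["ergosterol"]),
        }


@dataclass
class ChemistryTable:
    """Assay-reported analyte values: mean of three noisy replicates."""

    reported: pd.DataFrame  # sample_id, poly_pct, ergo_pct
    replicates: dict[str, np.ndarray]  # analyte -> (n_samples, 3)


def default_grid(range_label: str) -> WavelengthGrid:
    """Default instrument grids: VNIR 312 bands at 2 nm, SWIR 200 at 4 nm."""
    if range_label == "VNIR":
        return WavelengthGrid(VNIR_RANGE[0] + 2.0 * np.arange(312), "VNIR")
    if range_label == "SWIR":
        return WavelengthGrid(SWIR_RANGE[0] + 4.0 * np.arange(200), "SWIR")
    raise ValueError(f"unknown range label {range_label!r}")


def informative_band_centers(analyte: str, range_label: str,
                             bands: tuple[AbsorptionBand, ...] = DEFAULT_BANDS,
                             ) -> list[AbsorptionBand]:
    """Absorption bands of ``analyte`` lying inside ``range_label``'s grid."""
    grid = default_grid(range_label)
    lo, hi = grid.band_centers[0], grid.band_centers[-1]
    return [b for b in bands if b.analyte == analyte and lo <= b.center <= hi]


def generate_concentrations(spec: SceneSpec) -> AnalytePanel:
    """Uniform concentration draws within the configured ranges."""
    rng = substream(spec.seed, "concentrations")
    data = {"sample_id": [f"S{i + 1:02d}" for i in range(spec.n_samples)]}
    for analyte, (lo, hi) in spec.concentration_ranges.items():
        data[analyte] = rng.uniform(lo, hi, size=spec.n_samples)
    return AnalytePanel(pd.DataFrame(data))


def _baseline(form: str, x: np.ndarray, cap_above_powder: bool = True) -> np.ndarray:
    # x in [0, 1] along the grid; smooth, mildly sloped reflectance continuum
    cap = 0.58 - 0.05 * x + 0.02 * x * (1.0 - x)
    powder = 0.42 - 0.03 * x + 0.015 * x * (1.0 - x)
    if not cap_above_powder:
        cap, powder = powder, cap
    return cap if form == "cap" else powder


def _absorbance(concentrations: Mapping[str, float], grid: WavelengthGrid,
                bands: tuple[AbsorptionBand, ...]) -> np.ndarray:
    wl = grid.band_centers
    total = np.zeros_like(wl)
    for band in bands:
        conc = 1.0 if band.analyte == "matrix" else float(
            concentrations.get(band.analyte, 0.0)
        )
        total += band.strength * conc * np.exp(
            -0.5 * ((wl - band.center) / band.width) ** 2
        )
    return total


def generate_spectrum(concentrations: Mapping[str, float], grid: WavelengthGrid,
                      form: str, rng: np.random.Generator | None = None,
                      bands: tuple[AbsorptionBand, ...] = DEFAULT_BANDS,
                      noise_sd: float = 0.0,
                      scatter: np.ndarray | None = None,
                      extra_absorbance: np.ndarray | None = None,
                      cap_above_powder: bool = True) -> np.ndarray:
    """Reflectance spectrum for one sample patch.

    ``reflectance = baseline(form) * scatter * 10**(-absorbance)`` plus
    optional i.i.d. Gaussian noise.  ``scatter`` is a per-band multiplicative
    nuisance (default 1); ``extra_absorbance`` adds sample-specific
    interferent absorption on top of the analyte bands.
    """
    if form not in ("cap", "powder"):
        raise ValueError(f"unknown form {form!r}")
    x = (grid.band_centers - grid.band_centers[0]) / (
        grid.band_centers[-1] - grid.band_centers[0]
    )
    absorbance = _absorbance(concentrations, grid, bands)
    if extra_absorbance is not None:
        absorbance = absorbance + extra_absorbance
    spectrum = _baseline(form, x, cap_above_powder) * np.power(10.0, -absorbance)
    if scatter is not None:
        spectrum = spectrum * scatter
    if noise_sd > 0:
        if rng is None:
            raise ValueError("noise_sd > 0 requires an rng")
        spectrum = spectrum + rng.normal(0.0, noise_sd, size=spectrum.shape)
    return spectrum


def _sample_scatter(spec: SceneSpec, range_label: str, form: str, sample_idx: int,
                    grid: WavelengthGrid) -> np.ndarray:
    """Broadband gain x smooth Legendre tilt, fixed per physical specimen."""
    rng = substream(spec.seed, "scatter", range_label, form, sample_idx)
    gain = rng.normal(1.0, spec.gain_sd)
    coefs = np.concatenate(
        [[0.0], rng.normal(0.0, spec.scatter_coef_sd, size=len(spec.scatter_coef_sd))]
    )
    x = np.linspace(-1.0, 1.0, len(grid))
    return gain * np.exp(legendre.legval(x, coefs))


def _sample_interferents(spec: SceneSpec, sample_idx: int,
                         grid: WavelengthGrid) -> np.ndarray:
    """Interferent absorbance for one specimen: chemistry, so shared across
    forms, ranges and replicate photographs."""
    rng = substream(spec.seed, "interferents", sample_idx)
    z = rng.normal(0.0, 1.0, size=len(spec.interferent_bands))
    wl = grid.band_centers
    total = np.zeros_like(wl)
    for (center, width, sd), zi in zip(spec.interferent_bands, z):
        total += sd * zi * np.exp(-0.5 * ((wl - center) / width) ** 2)
    return total


class LayoutError(ValueError):
    """Too many sample patches for the requested frame size."""


def _patch_layout(spec: SceneSpec) -> tuple[int, int, int]:
    n_patches = spec.n_samples * len(spec.forms)
    grid_cols = math.ceil(math.sqrt(n_patches))
    grid_rows = math.ceil(n_patches / grid_cols)
    rows = grid_rows * spec.patch_size
    cols = grid_cols * spec.patch_size
    if spec.frame_shape is not None:
        fr, fc = spec.frame_shape
        if fr < rows or fc < cols:
            raise LayoutError(
                f"{n_patches} patches of {spec.patch_size}px need a frame of at "
                f"least {rows}x{cols}, got {fr}x{fc}"
            )
        rows, cols = fr, fc
    return rows, cols, grid_cols


def generate_cube(spec: SceneSpec, panel: AnalytePanel, range_label: str = None,
                  replicate: int = 1,
                  ) -> tuple[HyperCube, ReferenceFrames, list[ROISpec]]:
    """One raw cube (all sample patches), its reference frames, and its ROIs.

    The raw cube is built by inverting the calibration equation from the
    intended reflectance, so ``calibrate_reflectance`` recovers the planted
    spectra exactly at zero noise.
    """
    if range_label is None:
        range_label = spec.ranges[0]
    grid = default_grid(range_label)
    rows, cols, grid_cols = _patch_layout(spec)
    p = spec.patch_size

    reflect = np.full((rows, cols, len(grid)), 0.25)  # background mat
    rois: list[ROISpec] = []
    patch = 0
    for form in spec.forms:
        for i in range(spec.n_samples):
            r0 = (patch // grid_cols) * p
            c0 = (patch % grid_cols) * p
            scatter = _sample_scatter(spec, range_label, form, i, grid)
            base = generate_spectrum(
                panel.concentrations(i), grid, form, bands=spec.bands,
                scatter=scatter,
                extra_absorbance=_sample_interferents(spec, i, grid),
                cap_above_powder=spec.cap_above_powder,
            )
            prng = substream(spec.seed, "pixels", range_label, form, i, replicate)
            jitter_sd = spec.pixel_jitter_sd.get(form, 0.0)
            jitter = 1.0 + prng.normal(0.0, jitter_sd, size=(p, p, 1))
            block = base[None, None, :] * jitter
            if spec.noise_sd > 0:
                block = block + prng.normal(0.0, spec.noise_sd, size=block.shape)
            reflect[r0:r0 + p, c0:c0 + p, :] = block

            center = (r0 + p // 2, c0 + p // 2)
            offsets = [(0, 0), (0, 1), (1, 0), (1, 1), (-1, 0), (0, -1)]
            pixels = [
                (center[0] + dr, center[1] + dc)
                for dr, dc in offsets[: spec.roi_pixels]
            ]
            rois.append(
                ROISpec(
                    sample_id=panel.frame["sample_id"].iloc[i],
                    origin_code="SYN",
                    form=form,
                    pixels=tuple(pixels),
                    replicate=replicate,
                )
            )
            patch += 1

    rrng = substream(spec.seed, "references", range_label, replicate)
    rr, cc = np.meshgrid(np.arange(rows), np.arange(cols), indexing="ij")
    ripple = 0.01 * np.sin(2 * np.pi * rr / max(rows, 1) + rrng.uniform(0, 2 * np.pi))
    band_prof = 1.0 + 0.01 * np.sin(np.linspace(0, np.pi, len(grid)))
    white = (0.95 + ripple)[:, :, None] * band_prof[None, None, :]
    dark = np.full((rows, cols, len(grid)), 0.03) + 0.002 * ripple[:, :, None]

    raw_values = reflect * (white - dark) + dark
    raw = HyperCube(
        raw_values, grid, kind="raw",
        metadata={"range": range_label, "replicate": replicate, "synthetic": True},
    )
    return raw, ReferenceFrames(white=white, dark=dark), rois


def generate_reference_table(panel: AnalytePanel, assay_cv: float,
                             rng: np.random.Generator) -> ChemistryTable:
    """Assay-reported chemistry: mean of 3 noisy replicates around truth.

    Replicate noise is Gaussian with standard deviation ``assay_cv`` times the
    true value (a constant coefficient of variation), floored at zero.
    """
    if assay_cv < 0:
        raise ValueError("assay_cv must be nonnegative")
    reported = {"sample_id": panel.frame["sample_id"].to_numpy()}
    reps: dict[str, np.ndarray] = {}
    for analyte, col in (("polysaccharide", "poly_pct"), ("ergosterol", "ergo_pct")):
        truth = panel.frame[analyte].to_numpy(dtype=float)
        draws = rng.normal(
            truth[:, None], assay_cv * truth[:, None], size=(truth.size, 3)
        )
        draws = np.clip(draws, 0.0, None)
        reps[analyte] = draws
        reported[col] = draws.mean(axis=1)
    return ChemistryTable(reported=pd.DataFrame(reported), replicates=reps)


@dataclass
class Scene:
    """A full synthetic campaign: cubes per (range, replicate), plus chemistry."""

    spec: SceneSpec
    panel: AnalytePanel
    chemistry: ChemistryTable
    cubes: dict  # (range_label, replicate) -> (raw, refs, rois)


def generate_scene(spec: SceneSpec) -> Scene:
    """Generate every cube, reference frame, ROI list and the chemistry table."""
    panel = generate_concentrations(spec)
    chemistry = generate_reference_table(
        panel, spec.assay_cv, substream(spec.seed, "assay")
    )
    cubes = {}
    for range_label in spec.ranges:
        for rep in range(1, spec.replicates + 1):
            cubes[(range_label, rep)] = generate_cube(spec, panel, range_label, rep)
    return Scene(spec=spec, panel=panel, chemistry=chemistry, cubes=cubes)
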