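"""Cube I/O: ENVI header + binary pairs, and a native .npz container.

The ENVI dialect understood here is the plain-text ``.hdr`` with the keys
``samples`` (columns), ``lines`` (rows), ``bands``, ``data type``,
``interleave`` (bsq / bil / bip) and a ``wavelength`` list, next to a raw
binary block.  Whatever the on-disk interleave, cubes are always presented in
memory as (row, col, band); the interleave is converted on read so only one
axis convention exists inside the package.

The native container is a NumPy ``.npz`` holding values, mask, wavelengths
and a JSON metadata blob; round-trips are bit-exact.
"""

from __future__ import annotations

import json
import re
from pathlib import Path

import numpy as np

from .hypercube import HyperCube, ReferenceFrames, WavelengthGrid

__all__ = ["read_cube", "write_cube", "read_envi", "write_envi"]

# ENVI "data type" codes actually used by the two cameras' software.
_DTYPES = {4: np.float32, 5: np.float64, 12: np.uint16, 2: np.int16}
_DTYPE_CODES = {np.dtype(v): k for k, v in _DTYPES.items()}

# on-disk axis order per interleave, as a transpose of (row, col, band)
_INTERLEAVE_AXES = {"bsq": (2, 0, 1), "bil": (0, 2, 1), "bip": (0, 1, 2)}


class ENVIFormatError(ValueError):
    """Malformed or inconsistent ENVI header."""


def _parse_header(text: str) -> dict:
    if not text.lstrip().lower().startswith("envi"):
        raise ENVIFormatError("missing ENVI magic line")
    fields: dict[str, str] = {}
    # join { ... } blocks (possibly multi-line) before splitting into fields
    body = text.split("\n", 1)[1]
    for match in re.finditer(r"^\s*([\w ]+?)\s*=\s*(\{[^}]*\}|[^\n]*)", body, re.M | re.S):
        key = match.group(1).strip().lower()
        val = match.group(2).strip()
        fields[key] = val
    return fields


def _parse_list(raw: str) -> list[float]:
    inner = raw.strip().lstrip("{").rstrip("}")
    return [float(tok) for tok in inner.replace("\n", " ").split(",") if tok.strip()]


def write_envi(cube: HyperCube, path: str | Path, interleave: str = "bsq",
               dtype: str | np.dtype = "float64") -> Path:
    """Write ``cube`` as ``path``.hdr / ``path``.img; returns the header path."""
    interleave = interleave.lower()
    if interleave not in _INTERLEAVE_AXES:
        raise ENVIFormatError(f"unknown interleave {interleave!r}")
    base = Path(path)
    if base.suffix in (".hdr", ".img"):
        base = base.with_suffix("")
    dtype = np.dtype(dtype)
    if dtype not in _DTYPE_CODES:
        raise ENVIFormatError(f"unsupported data type {dtype}")
    rows, cols, bands = cube.shape
    wl = ", ".join(f"{w:.4f}" for w in cube.grid.band_centers)
    header = (
        "ENVI\n"
        "description = {ganospec cube}\n"
        f"samples = {cols}\n"
        f"lines = {rows}\n"
        f"bands = {bands}\n"
        "header offset = 0\n"
        "file type = ENVI Standard\n"
        f"data type = {_DTYPE_CODES[dtype]}\n"
        f"interleave = {interleave}\n"
        "byte order = 0\n"
        f"wavelength units = nm\n"
        f"range label = {cube.grid.range_label}\n"
        f"cube kind = {cube.kind}\n"
        f"wavelength = {{ {wl} }}\n"
    )
    base.with_suffix(".hdr").write_text(header)
    block = np.ascontiguousarray(
        cube.values.transpose(_INTERLEAVE_AXES[interleave]).astype(dtype)
    )
    block.tofile(base.with_suffix(".img"))
    return base.with_suffix(".hdr")


def read_envi(path: str | Path) -> HyperCube:
    """Read an ENVI .hdr/.img pair into a (row, col, band) cube."""
    base = Path(path)
    if base.suffix in (".hdr", ".img"):
        base = base.with_suffix("")
    fields = _parse_header(base.with_suffix(".hdr").read_text())
    try:
        cols = int(fields["samples"])
        rows = int(fields["lines"])
        bands = int(fields["bands"])
        code = int(fields["data type"])
        interleave = fields["interleave"].lower()
    except KeyError as exc:
        raise ENVIFormatError(f"header missing required key: {exc}") from exc
    if interleave not in _INTERLEAVE_AXES:
        raise ENVIFormatError(f"unknown interleave {interleave!r}")
    if code not in _DTYPES:
        raise ENVIFormatError(f"unsupported data type code {code}")
    if "wavelength" not in fields:
        raise ENVIFormatError("header missing wavelength list")
    wavelengths = _parse_list(fields["wavelength"])
    if len(wavelengths) != bands:
        raise ENVIFormatError(
            f"header declares {bands} bands but lists {len(wavelengths)} wavelengths"
        )
    offset = int(fields.get("header offset", 0))
    data = np.fromfile(base.with_suffix(".img"), dtype=_DTYPES[code], offset=offset)
    if data.size != rows * cols * bands:
        raise ENVIFormatError(
            f"binary block has {data.size} values, header implies {rows * cols * bands}"
        )
    axes = _INTERLEAVE_AXES[interleave]
    disk_shape = tuple((rows, cols, bands)[a] for a in axes)
    values = data.reshape(disk_shape).transpose(np.argsort(axes))
    grid = WavelengthGrid(np.asarray(wavelengths), fields.get("range label", "VNIR"))
    kind = fields.get("cube kind", "raw")
    return HyperCube(values.astype(float), grid, kind=kind,
                     metadata={"source": str(base.with_suffix(".hdr"))})


def write_cube(cube: HyperCube, path: str | Path, interleave: str = "bsq") -> Path:
    """Write a cube; ``.npz`` selects the native container, else ENVI."""
    path = Path(path)
    if path.suffix == ".npz":
        np.savez(
            path,
            values=cube.values,
            mask=cube.mask,
            wavelengths=cube.grid.band_centers,
            meta=np.array(
                json.dumps(
                    {
                        "range_label": cube.grid.range_label,
                        "kind": cube.kind,
                        "metadata": cube.metadata,
                    }
                )
            ),
        )
        return path
    return write_envi(cube, path, interleave=interleave)


def read_cube(path: str | Path) -> HyperCube:
    """Read a cube from the native ``.npz`` container or an ENVI pair."""
    path = Path(path)
    if path.suffix == ".npz":
        with np.load(path, allow_pickle=False) as npz:
            meta = json.loads(str(npz["meta"]))
            grid = WavelengthGrid(npz["wavelengths"], meta["range_label"])
            return HyperCube(
                npz["values"], grid, kind=meta["kind"], mask=npz["mask"],
                metadata=meta.get("metadata", {}),
            )
    return read_envi(path)
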