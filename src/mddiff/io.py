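"""Reading and writing planar dose grids.

The primary interchange is a self-describing plain-text format
("dgrid-text"): a short ``key=value`` header followed by one
whitespace-delimited row of doses (cGy) per grid row (axis 0 = x).
Example::

    format=dgrid/1
    shape=3 4
    spacing=1.0 1.0
    origin=0.0 0.0
    unit=cGy
    0 0 0 0
    0 100 100 0
    0 0 0 0

Bare CSV matrices are accepted when the pixel spacing is supplied by the
caller. DICOM RT Dose import (via pydicom, optional dependency) is
exposed behind the same interface.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

from .dose_model import DoseGrid, make_grid

__all__ = ["ParseError", "read_dose_grid", "write_dose_grid"]

_FORMAT_TAG = "dgrid/1"
_REQUIRED_KEYS = ("format", "shape", "spacing", "origin", "unit")


class ParseError(ValueError):
    """A dose-grid file could not be parsed; the message names the location."""


def write_dose_grid(grid: DoseGrid, path: str | Path) -> None:
    """Write a grid in dgrid-text. Round-trips geometry exactly and dose
    to far better than 1e-6 cGy."""
    path = Path(path)
    nx, ny = grid.shape
    lines = [
        f"format={_FORMAT_TAG}",
        f"shape={nx} {ny}",
        f"spacing={grid.spacing[0]!r} {grid.spacing[1]!r}",
        f"origin={grid.origin[0]!r} {grid.origin[1]!r}",
        "unit=cGy",
    ]
    for row in grid.values:
        lines.append(" ".join(f"{v:.10g}" for v in row))
    path.write_text("\n".join(lines) + "\n")


def _parse_pair(text: str, key: str, line_no: int) -> tuple[float, float]:
    parts = text.split()
    if len(parts) != 2:
        raise ParseError(f"line {line_no}: header '{key}' needs two values, got {text!r}")
    try:
        return float(parts[0]), float(parts[1])
    except ValueError as exc:
        raise ParseError(f"line {line_no}: header '{key}': {exc}") from None


def _read_dgrid_text(path: Path) -> DoseGrid:
    lines = path.read_text().splitlines()
    header: dict[str, str] = {}
    header_lines: dict[str, int] = {}
    i = 0
    while i < len(lines) and "=" in lines[i]:
        key, _, value = lines[i].partition("=")
        header[key.strip()] = value.strip()
        header_lines[key.strip()] = i + 1
        i += 1
    for key in _REQUIRED_KEYS:
        if key not in header:
            raise ParseError(f"{path}: missing header key '{key}'")
    if header["format"] != _FORMAT_TAG:
        raise ParseError(
            f"line {header_lines['format']}: unsupported format {header['format']!r}"
        )
    if header["unit"].lower() != "cgy":
        raise ParseError(f"line {header_lines['unit']}: unsupported unit {header['unit']!r}")
    try:
        nx, ny = (int(v) for v in header["shape"].split())
    except ValueError:
        raise ParseError(
            f"line {header_lines['shape']}: shape must be two integers, got "
            f"{header['shape']!r}"
        ) from None
    spacing = _parse_pair(header["spacing"], "spacing", header_lines["spacing"])
    origin = _parse_pair(header["origin"], "origin", header_lines["origin"])

    data_lines = [(i + k + 1, ln) for k, ln in enumerate(lines[i:]) if ln.strip()]
    if len(data_lines) != nx:
        raise ParseError(
            f"{path}: header declares {nx} rows but file has {len(data_lines)} data rows"
        )
    rows = []
    for line_no, ln in data_lines:
        try:
            row = np.array([float(v) for v in ln.split()])
        except ValueError as exc:
            raise ParseError(f"line {line_no}: {exc}") from None
        if row.size != ny:
            raise ParseError(
                f"line {line_no}: expected {ny} values per row, got {row.size}"
            )
        if np.any(row < 0) or not np.all(np.isfinite(row)):
            col = int(np.flatnonzero((row < 0) | ~np.isfinite(row))[0]) + 1
            raise ParseError(f"line {line_no}, column {col}: invalid dose value")
        rows.append(row)
    return make_grid(np.vstack(rows), spacing, origin)


def _read_csv(path: Path, spacing, origin) -> DoseGrid:
    if spacing is None:
        raise ParseError(
            f"{path}: CSV carries no geometry; pixel spacing must be supplied"
        )
    try:
        values = np.loadtxt(path, delimiter=",", ndmin=2)
    except ValueError as exc:
        raise ParseError(f"{path}: {exc}") from None
    if np.isscalar(spacing):
        spacing = (float(spacing), float(spacing))
    return make_grid(values, spacing, origin or (0.0, 0.0))


def _read_dicom(path: Path) -> DoseGrid:
    import pydicom  # optional dependency

    ds = pydicom.dcmread(path)
    if getattr(ds, "Modality", None) != "RTDOSE":
        raise ParseError(f"{path}: not an RT Dose object (Modality={getattr(ds, 'Modality', None)!r})")
    arr = ds.pixel_array
    if arr.ndim == 3:
        if arr.shape[0] != 1:
            raise ParseError(f"{path}: multi-frame dose grids are not supported (2D only)")
        arr = arr[0]
    scaling = float(getattr(ds, "DoseGridScaling", 1.0))
    unit = getattr(ds, "DoseUnits", "GY").upper()
    to_cgy = 100.0 if unit == "GY" else 1.0
    # DICOM pixel_array is (row=y, col=x); our axis 0 is x
    values = (arr.T.astype(float)) * scaling * to_cgy
    row_sp, col_sp = (float(v) for v in ds.PixelSpacing)  # (y, x) pitch
    ipp = getattr(ds, "ImagePositionPatient", [0.0, 0.0, 0.0])
    return make_grid(values, (col_sp, row_sp), (float(ipp[0]), float(ipp[1])))


def read_dose_grid(
    path: str | Path,
    format: str = "dgrid-text",
    spacing=None,
    origin=None,
) -> DoseGrid:
    """Read a dose grid from ``path``.

    ``format`` is ``"dgrid-text"`` (default), ``"csv"`` (requires
    ``spacing``, mm, scalar or pair), or ``"dicom"`` (RT Dose, requires
    pydicom).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format == "dgrid-text":
        return _read_dgrid_text(path)
    if format == "csv":
        return _read_csv(path, spacing, origin)
    if format == "dicom":
        return _read_dicom(path)
    raise ParseError(f"unknown format {format!r}")
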