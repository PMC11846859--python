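"""Text interchange formats for maps and reference spectra, plus resampling.

Two delimited map layouts are supported:

* ``wide`` — row 1 is ``x,y,<w1>,<w2>,...`` (wavenumbers in cm^-1), every
  further row is one pixel record ``x,y,intensities...``.
* ``long`` — header ``x,y,wavenumber,intensity``, one row per (pixel, point).

Reference spectra are two-column ``wavenumber,intensity`` files preceded by a
``# label: <name>`` header line.  All files are comma-delimited UTF-8; grids
are sorted ascending on load regardless of file order.
"""

from __future__ import annotations

import csv
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import (
    DegenerateInputError,
    HyperspectralMap,
    ReferenceSpectrum,
    SchemaError,
    Spectrum,
    WavenumberGrid,
)

__all__ = [
    "read_map",
    "write_map",
    "read_reference",
    "write_reference",
    "resample",
    "resample_reference",
    "common_window",
    "FINGERPRINT_RANGE",
]

#: fingerprint window (cm^-1) used as the default analysis range
FINGERPRINT_RANGE = (600.0, 1900.0)


class ParseError(ValueError):
    """A file row could not be interpreted; the message names the line."""


def read_map(path: str | Path, format: str = "wide") -> HyperspectralMap:
    """Read a hyperspectral map from a delimited text file.

    Parameters
    ----------
    path
        Input file.
    format
        ``"wide"`` or ``"long"`` (see module docstring).
    """
    path = Path(path)
    if format == "wide":
        return _read_wide(path)
    if format == "long":
        return _read_long(path)
    raise ValueError(f"unknown map format {format!r}")


def _read_wide(path: Path) -> HyperspectralMap:
    with path.open(newline="", encoding="utf-8") as fh:
        rows = list(csv.reader(fh))
    rows = [r for r in rows if r and not r[0].startswith("#")]
    if len(rows) < 2:
        raise ParseError(f"{path}: need a header and at least one pixel row")
    header = rows[0]
    if len(header) < 4 or header[0].strip() != "x" or header[1].strip() != "y":
        raise ParseError(f"{path} line 1: header must be 'x,y,<wavenumbers...>'")
    try:
        wavenumbers = np.array([float(v) for v in header[2:]])
    except ValueError as exc:
        raise ParseError(f"{path} line 1: non-numeric wavenumber ({exc})") from None
    order = np.argsort(wavenumbers)
    grid = WavenumberGrid(wavenumbers[order])
    pixels = []
    for lineno, row in enumerate(rows[1:], start=2):
        if len(row) != len(header):
            raise ParseError(f"{path} line {lineno}: expected {len(header)} fields, "
                             f"got {len(row)}")
        try:
            x, y = int(row[0]), int(row[1])
            intensity = np.array([float(v) for v in row[2:]])
        except ValueError as exc:
            raise ParseError(f"{path} line {lineno}: {exc}") from None
        pixels.append((x, y, intensity[order]))
    return HyperspectralMap.from_pixels(grid, pixels)


def _read_long(path: Path) -> HyperspectralMap:
    try:
        frame = pd.read_csv(path, comment="#")
    except Exception as exc:  # pandas raises several parser types
        raise ParseError(f"{path}: {exc}") from None
    expected = ["x", "y", "wavenumber", "intensity"]
    if list(frame.columns[:4]) != expected:
        raise ParseError(f"{path}: header must be {','.join(expected)}")
    grids = {}
    pixels = []
    for (x, y), sub in frame.groupby(["x", "y"], sort=True):
        w = sub["wavenumber"].to_numpy(float)
        order = np.argsort(w)
        grids[tuple(np.round(w[order], 9))] = None
        if len(grids) > 1:
            raise SchemaError(f"{path}: pixel ({x}, {y}) uses a different "
                              "wavenumber grid than earlier pixels")
        pixels.append((int(x), int(y), sub["intensity"].to_numpy(float)[order]))
    if not pixels:
        raise ParseError(f"{path}: no pixel rows")
    grid = WavenumberGrid(np.array(next(iter(grids))))
    return HyperspectralMap.from_pixels(grid, pixels)


def write_map(hsmap: HyperspectralMap, path: str | Path, format: str = "wide") -> Path:
    """Write a map in the requested text layout; returns the path."""
    path = Path(path)
    coords = hsmap.coordinates()
    values = hsmap.intensities()
    w = hsmap.grid.values
    with path.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        if format == "wide":
            writer.writerow(["x", "y", *(f"{v:.6g}" for v in w)])
            for (x, y), row in zip(coords, values):
                writer.writerow([x, y, *(f"{v:.8g}" for v in row)])
        elif format == "long":
            writer.writerow(["x", "y", "wavenumber", "intensity"])
            for (x, y), row in zip(coords, values):
                for wv, inten in zip(w, row):
                    writer.writerow([x, y, f"{wv:.6g}", f"{inten:.8g}"])
        else:
            raise ValueError(f"unknown map format {format!r}")
    return path


def read_reference(path: str | Path) -> ReferenceSpectrum:
    """Read a two-column reference spectrum with a ``# label:`` header."""
    path = Path(path)
    label = None
    rows = []
    with path.open(encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                body = line.lstrip("#").strip()
                if body.lower().startswith("label:"):
                    label = body.split(":", 1)[1].strip()
                continue
            if line.lower().replace(" ", "").startswith("wavenumber,"):
                continue
            parts = line.split(",")
            if len(parts) != 2:
                raise ParseError(f"{path} line {lineno}: expected 2 columns")
            try:
                rows.append((float(parts[0]), float(parts[1])))
            except ValueError:
                raise ParseError(
                    f"{path} line {lineno}: non-numeric cell {parts!r}") from None
    if label is None:
        raise ParseError(f"{path}: missing '# label: <name>' header")
    if len(rows) < 8:
        raise DegenerateInputError(
            f"{path}: reference needs >= 8 points, got {len(rows)}")
    arr = np.array(rows)
    order = np.argsort(arr[:, 0])
    w = arr[order, 0]
    dup = np.flatnonzero(np.diff(w) == 0)
    if dup.size:
        raise ParseError(f"{path}: duplicated wavenumber {w[dup[0]]:g}")
    return ReferenceSpectrum(label, WavenumberGrid(w), arr[order, 1])


def write_reference(ref: ReferenceSpectrum, path: str | Path) -> Path:
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        fh.write(f"# label: {ref.label}\n")
        fh.write("wavenumber,intensity\n")
        for w, i in zip(ref.grid.values, ref.intensity):
            fh.write(f"{w:.6g},{i:.6g}\n")
    return path


def resample(spectrum: Spectrum, target: WavenumberGrid) -> Spectrum:
    """Linearly interpolate a spectrum onto ``target``.

    Reference spectra and tissue maps are usually measured on different grids;
    linear interpolation is used because it is monotone and introduces no
    ringing at sharp Raman bands.  No extrapolation: the target range must lie
    inside the source range.
    """
    src = spectrum.grid.values
    tgt = target.values
    if tgt[0] < src[0] or tgt[-1] > src[-1]:
        raise ValueError(
            f"target range [{tgt[0]:g}, {tgt[-1]:g}] extends beyond source "
            f"range [{src[0]:g}, {src[-1]:g}]")
    return Spectrum(target, np.interp(tgt, src, spectrum.intensity))


def resample_reference(ref: ReferenceSpectrum, target: WavenumberGrid
                       ) -> ReferenceSpectrum:
    res = resample(ref.spectrum, target)
    return ReferenceSpectrum(ref.label, target, res.intensity)


def common_window(map_grid: WavenumberGrid, *reference_grids: WavenumberGrid,
                  lo: float = FINGERPRINT_RANGE[0],
                  hi: float = FINGERPRINT_RANGE[1]) -> WavenumberGrid:
    """Map-grid points inside every reference range, clipped to the fingerprint
    window (600-1900 cm^-1 by default)."""
    for g in reference_grids:
        lo = max(lo, g.range[0])
        hi = min(hi, g.range[1])
    return map_grid.window(lo, hi)
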