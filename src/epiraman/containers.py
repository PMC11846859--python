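"""Core data containers for Raman hyperspectral map analysis.

The central objects are :class:`HyperspectralMap` (per-pixel spectra on a shared
wavenumber grid with integer raster coordinates), :class:`ReferenceSpectrum`
(a labeled wavenumber/intensity curve for one molecular species or DNA
conformation) and :class:`ClassMap` (per-pixel tissue-class labels produced by
the convolutional classifier: 0 = stroma/empty, 1 = nucleus, 2 = cytoplasm).

Coordinates are 0-based pixel indices with ``x`` the column and ``y`` the row,
origin top-left; the physical pixel pitch (step size, µm) is carried only as
metadata.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any, Mapping

import numpy as np

__all__ = [
    "WavenumberGrid",
    "Spectrum",
    "HyperspectralMap",
    "ReferenceSpectrum",
    "ClassMap",
    "SchemaError",
    "DegenerateInputError",
    "STROMA",
    "NUCLEUS",
    "CYTOPLASM",
    "CLASS_NAMES",
]

#: tissue-class label codes used throughout the package
STROMA, NUCLEUS, CYTOPLASM = 0, 1, 2
CLASS_NAMES = {STROMA: "stroma/empty", NUCLEUS: "nucleus", CYTOPLASM: "cytoplasm"}


class SchemaError(ValueError):
    """A container violates a structural contract (grids, shapes, labels)."""


class DegenerateInputError(ValueError):
    """Input is too small or too flat for the requested operation."""


@dataclass(frozen=True)
class WavenumberGrid:
    """Strictly ascending, finite, positive wavenumber axis in cm^-1."""

    values: np.ndarray

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        if values.ndim != 1 or values.size < 2:
            raise SchemaError("wavenumber grid must be a 1-D array of >= 2 points")
        if not np.all(np.isfinite(values)) or np.any(values <= 0):
            raise SchemaError("wavenumbers must be finite and positive")
        if not np.all(np.diff(values) > 0):
            raise SchemaError("wavenumber grid must be strictly ascending")

    def __len__(self) -> int:
        return int(self.values.size)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, WavenumberGrid):
            return NotImplemented
        return self.values.shape == other.values.shape and np.array_equal(
            self.values, other.values
        )

    def __hash__(self) -> int:  # frozen dataclass with array field
        return hash((self.values.size, float(self.values[0]), float(self.values[-1])))

    @property
    def range(self) -> tuple[float, float]:
        return float(self.values[0]), float(self.values[-1])

    def window(self, lo: float, hi: float) -> "WavenumberGrid":
        """Sub-grid restricted to ``[lo, hi]`` cm^-1."""
        mask = (self.values >= lo) & (self.values <= hi)
        if mask.sum() < 2:
            raise SchemaError(f"window [{lo}, {hi}] leaves fewer than 2 grid points")
        return WavenumberGrid(self.values[mask])


@dataclass(frozen=True)
class Spectrum:
    """A single intensity vector on a :class:`WavenumberGrid`."""

    grid: WavenumberGrid
    intensity: np.ndarray

    def __post_init__(self) -> None:
        intensity = np.asarray(self.intensity, dtype=float)
        object.__setattr__(self, "intensity", intensity)
        if intensity.ndim != 1 or intensity.size != len(self.grid):
            raise SchemaError(
                f"intensity length {intensity.size} != grid length {len(self.grid)}"
            )
        if not np.all(np.isfinite(intensity)):
            raise SchemaError("intensity contains non-finite values")


@dataclass(frozen=True)
class ReferenceSpectrum:
    """Labeled reference curve for one species or DNA conformation.

    Canonical labels are ``DNA, DNA-m, Lys, Lys-m, Lys-a, Arg, Arg-m, B-DNA,
    Z-DNA``; user-defined labels are allowed.
    """

    label: str
    grid: WavenumberGrid
    intensity: np.ndarray

    def __post_init__(self) -> None:
        if not self.label:
            raise SchemaError("reference label must be non-empty")
        intensity = np.asarray(self.intensity, dtype=float)
        object.__setattr__(self, "intensity", intensity)
        if intensity.ndim != 1 or intensity.size != len(self.grid):
            raise SchemaError("reference intensity length != grid length")
        if not np.all(np.isfinite(intensity)):
            raise SchemaError("reference intensity contains non-finite values")

    @property
    def spectrum(self) -> Spectrum:
        return Spectrum(self.grid, self.intensity)


class HyperspectralMap:
    """Raster of Raman spectra sharing one wavenumber grid.

    Internally stores a dense ``(height, width, n_wavenumbers)`` cube plus a
    boolean occupancy mask, which keeps the per-pixel correlation and
    preprocessing operations vectorizable over the ~10^4 pixels a tissue map
    typically holds.
    """

    def __init__(
        self,
        grid: WavenumberGrid,
        cube: np.ndarray,
        mask: np.ndarray | None = None,
        step_size: float = 1.0,
        metadata: Mapping[str, Any] | None = None,
    ) -> None:
        cube = np.asarray(cube, dtype=float)
        if cube.ndim != 3 or cube.shape[2] != len(grid):
            raise SchemaError(
                "cube must be (height, width, n_wavenumbers) matching the grid"
            )
        if mask is None:
            mask = np.ones(cube.shape[:2], dtype=bool)
        mask = np.asarray(mask, dtype=bool)
        if mask.shape != cube.shape[:2]:
            raise SchemaError("mask shape must match cube (height, width)")
        if not np.all(np.isfinite(cube[mask])):
            raise SchemaError("map contains non-finite intensities at occupied pixels")
        self.grid = grid
        self.cube = cube
        self.mask = mask
        self.step_size = float(step_size)
        self.metadata: dict[str, Any] = dict(metadata or {})

    @classmethod
    def from_pixels(
        cls,
        grid: WavenumberGrid,
        pixels: list[tuple[int, int, np.ndarray]],
        step_size: float = 1.0,
        metadata: Mapping[str, Any] | None = None,
    ) -> "HyperspectralMap":
        """Build from ``(x, y, intensity)`` records; duplicates are rejected."""
        if not pixels:
            raise SchemaError("empty pixel list")
        xs = np.array([p[0] for p in pixels], dtype=int)
        ys = np.array([p[1] for p in pixels], dtype=int)
        if xs.min() < 0 or ys.min() < 0:
            raise SchemaError("pixel coordinates must be non-negative")
        width, height = int(xs.max()) + 1, int(ys.max()) + 1
        cube = np.zeros((height, width, len(grid)))
        mask = np.zeros((height, width), dtype=bool)
        for x, y, intensity in pixels:
            if mask[y, x]:
                raise SchemaError(f"pixel ({x}, {y}) listed more than once")
            intensity = np.asarray(intensity, dtype=float)
            if intensity.size != len(grid):
                raise SchemaError(
                    f"pixel ({x}, {y}): intensity length {intensity.size} "
                    f"!= grid length {len(grid)}"
                )
            cube[y, x] = intensity
            mask[y, x] = True
        return cls(grid, cube, mask, step_size=step_size, metadata=metadata)

    @property
    def width(self) -> int:
        return self.cube.shape[1]

    @property
    def height(self) -> int:
        return self.cube.shape[0]

    @property
    def n_pixels(self) -> int:
        return int(self.mask.sum())

    def coordinates(self) -> np.ndarray:
        """Occupied ``(x, y)`` pairs in row-major (y, then x) order."""
        ys, xs = np.nonzero(self.mask)
        return np.column_stack([xs, ys])

    def intensities(self) -> np.ndarray:
        """``(n_pixels, n_wavenumbers)`` matrix in row-major pixel order."""
        return self.cube[self.mask]

    def with_intensities(self, values: np.ndarray, grid: WavenumberGrid | None = None
                         ) -> "HyperspectralMap":
        """Copy of the map with occupied-pixel spectra replaced."""
        grid = grid or self.grid
        values = np.asarray(values, dtype=float)
        if values.shape != (self.n_pixels, len(grid)):
            raise SchemaError("replacement intensity matrix has the wrong shape")
        cube = np.zeros((self.height, self.width, len(grid)))
        cube[self.mask] = values
        return HyperspectralMap(grid, cube, self.mask.copy(),
                                step_size=self.step_size, metadata=self.metadata)

    def pixel(self, x: int, y: int) -> Spectrum:
        if not self.mask[y, x]:
            raise KeyError(f"no spectrum at ({x}, {y})")
        return Spectrum(self.grid, self.cube[y, x])

    def __repr__(self) -> str:
        lo, hi = self.grid.range
        return (f"HyperspectralMap({self.width}x{self.height}, "
                f"{self.n_pixels} pixels, {len(self.grid)} points "
                f"{lo:.0f}-{hi:.0f} cm-1)")


@dataclass
class ClassMap:
    """Per-pixel tissue-class labels in {0, 1, 2} over a map raster."""

    labels: np.ndarray
    mask: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        if self.labels.ndim != 2:
            raise SchemaError("class labels must form a 2-D raster")
        if self.mask is None:
            self.mask = np.ones_like(self.labels, dtype=bool)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.shape != self.labels.shape:
            raise SchemaError("class-map mask shape mismatch")
        occupied = self.labels[self.mask]
        if occupied.size and not np.isin(occupied, (STROMA, NUCLEUS, CYTOPLASM)).all():
            raise SchemaError("class labels must lie in {0, 1, 2}")

    @property
    def width(self) -> int:
        return self.labels.shape[1]

    @property
    def height(self) -> int:
        return self.labels.shape[0]

    def flat(self) -> np.ndarray:
        """Labels of occupied pixels in row-major order (matches map order)."""
        return self.labels[self.mask]

    def fraction(self, label: int) -> float:
        flat = self.flat()
        return float(np.mean(flat == label)) if flat.size else 0.0
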