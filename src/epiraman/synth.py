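"""Synthetic reference spectra and hyperspectral tissue maps with known truth.

The generator emulates the statistical structure the analysis pipeline
assumes: fingerprint-range spectra (600-1900 cm^-1, 2 cm^-1 steps), tissue
scenes with connected nucleus blobs surrounded by cytoplasm inside a stromal
matrix, and per-pixel spectra formed as nonnegative mixtures of reference
components plus a cubic baseline, Gaussian noise and sparse single-bin cosmic
ray spikes.  Every map carries recoverable ground truth: the tissue-class
raster, the per-species mixing coefficients, and scalar "modification level"
multipliers per simulated subtype group.

Peak positions of the built-in species are loosely modeled on common Raman
band assignments (DNA backbone ~785/1094 cm^-1, phenylalanine ~1003 cm^-1,
CH2 deformation ~1450 cm^-1, amide I ~1660 cm^-1) but make no claim of
spectroscopic accuracy; modified species share most bands with their base
species and differ in a few, mirroring the differentiating-feature structure
the correlation analysis must resolve.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter

from .containers import (
    ClassMap,
    CYTOPLASM,
    DegenerateInputError,
    HyperspectralMap,
    NUCLEUS,
    ReferenceSpectrum,
    SchemaError,
    STROMA,
    WavenumberGrid,
)

__all__ = [
    "SpeciesModel",
    "TissueScene",
    "NoiseModel",
    "SceneSpec",
    "LayoutError",
    "default_grid",
    "default_species",
    "make_reference",
    "make_scene",
    "render_map",
    "MODIFICATIONS",
    "BASE_OF",
]

#: epigenetic-modification labels and their base species
BASE_OF = {"DNA-m": "DNA", "Lys-m": "Lys", "Lys-a": "Lys", "Arg-m": "Arg"}
MODIFICATIONS = tuple(BASE_OF)


class LayoutError(ValueError):
    """Requested nuclei cannot be placed in the scene."""


@dataclass(frozen=True)
class SpeciesModel:
    """Peak-list model of one molecular species.

    ``peaks`` are ``(center cm^-1, FWHM-like width cm^-1, height)`` triples;
    ``shape`` selects the line profile (Lorentzian is the typical Raman
    lineshape, Gaussian is kept for robustness checks).
    """

    label: str
    peaks: tuple[tuple[float, float, float], ...]
    shape: str = "lorentzian"

    def __post_init__(self) -> None:
        if self.shape not in ("lorentzian", "gaussian"):
            raise ValueError(f"unknown peak shape {self.shape!r}")
        for c, w, h in self.peaks:
            if w <= 0 or h < 0:
                raise ValueError("peak widths must be > 0 and heights >= 0")


#: built-in species peak tables (center, width, height)
_SPECIES_TABLE: dict[str, tuple[tuple[float, float, float], ...]] = {
    "DNA": ((785, 12, 1.0), (1094, 10, 0.7), (1255, 14, 0.5), (1375, 12, 0.6),
            (1490, 12, 0.55), (1578, 12, 0.8), (1668, 14, 0.4)),
    "DNA-m": ((785, 12, 1.0), (1005, 10, 0.55), (1094, 10, 0.7),
              (1270, 14, 0.5), (1375, 12, 0.6), (1440, 12, 0.45),
              (1490, 12, 0.5), (1578, 12, 0.8)),
    "Lys": ((850, 12, 0.5), (1003, 8, 0.4), (1062, 12, 0.6), (1128, 12, 0.5),
            (1304, 14, 0.7), (1445, 14, 1.0), (1608, 12, 0.3)),
    "Lys-m": ((760, 10, 0.6), (850, 12, 0.5), (978, 10, 0.45), (1003, 8, 0.4),
              (1128, 12, 0.5), (1304, 14, 0.7), (1415, 10, 0.55),
              (1445, 14, 1.0)),
    "Lys-a": ((850, 12, 0.5), (920, 10, 0.45), (1003, 8, 0.4),
              (1240, 12, 0.55), (1304, 14, 0.7), (1445, 14, 1.0),
              (1608, 12, 0.3), (1650, 12, 0.65)),
    "Arg": ((1002, 8, 0.5), (1086, 12, 0.6), (1176, 12, 0.4), (1340, 14, 0.6),
            (1460, 14, 0.8), (1585, 12, 0.5)),
    "Arg-m": ((890, 10, 0.5), (1002, 8, 0.5), (1086, 12, 0.6),
              (1196, 12, 0.45), (1340, 14, 0.6), (1460, 14, 0.8),
              (1532, 12, 0.5)),
    "B-DNA": ((790, 10, 1.0), (835, 10, 0.6), (1094, 10, 0.8),
              (1255, 12, 0.4), (1578, 12, 0.7), (1668, 12, 0.5)),
    "Z-DNA": ((745, 10, 0.6), (810, 10, 0.9), (1094, 10, 0.8),
              (1318, 12, 0.7), (1578, 12, 0.6), (1625, 12, 0.45)),
    "Protein": ((1003, 8, 0.9), (1126, 12, 0.4), (1250, 16, 0.5),
                (1450, 16, 1.0), (1657, 16, 0.8)),
    "Collagen": ((856, 12, 0.8), (938, 12, 0.7), (1246, 16, 0.6),
                 (1270, 14, 0.5), (1450, 16, 0.7), (1668, 14, 0.8)),
}


def default_grid(step: float = 2.0) -> WavenumberGrid:
    """Fingerprint-range grid, 600-1900 cm^-1 at the given step."""
    return WavenumberGrid(np.arange(600.0, 1900.0 + step / 2, step))


def default_species(shape: str = "lorentzian") -> dict[str, SpeciesModel]:
    """The built-in species set: 7 EM-analysis species, the two DNA
    conformers, and generic Protein/Collagen matrix components."""
    return {label: SpeciesModel(label, peaks, shape)
            for label, peaks in _SPECIES_TABLE.items()}


def make_reference(model: SpeciesModel, grid: WavenumberGrid
                   ) -> ReferenceSpectrum:
    """Evaluate a species model on a grid, min-max scaled to [0, 1]."""
    if not model.peaks:
        raise DegenerateInputError(f"species {model.label!r} has no peaks")
    w = grid.values
    y = np.zeros_like(w)
    for center, width, height in model.peaks:
        if model.shape == "lorentzian":
            half = width / 2.0
            y += height * half**2 / ((w - center) ** 2 + half**2)
        else:
            sigma = width / 2.3548  # FWHM -> sigma
            y += height * np.exp(-0.5 * ((w - center) / sigma) ** 2)
    y = (y - y.min()) / (y.max() - y.min())
    return ReferenceSpectrum(model.label, grid, y)


@dataclass(frozen=True)
class SceneSpec:
    """Parameters of a simulated tissue scene.

    ``truth`` maps modification labels (``DNA-m``, ``Lys-m``, ``Lys-a``,
    ``Arg-m``) to levels in [0, 1] that scale the modified species' mixing
    coefficients inside nuclei; ``z_level`` plays the same role for the
    Z-DNA conformer relative to B-DNA.
    """

    width: int = 48
    height: int = 48
    n_nuclei: int = 5
    nucleus_radius: tuple[float, float] = (3.5, 6.0)
    group_label: str = "CTRL"
    truth: dict[str, float] = field(default_factory=dict)
    z_level: float = 0.15

    def __post_init__(self) -> None:
        if self.width < 16 or self.height < 16:
            raise ValueError("scene must be at least 16x16 pixels")
        for label, level in self.truth.items():
            if label not in BASE_OF:
                raise ValueError(f"unknown modification label {label!r}")
            if not 0.0 <= level <= 1.0:
                raise ValueError(f"truth level for {label} must lie in [0, 1]")


@dataclass
class TissueScene:
    """A realized scene: class raster plus per-species mixing coefficients."""

    width: int
    height: int
    regions: np.ndarray                 # (H, W) int in {0,1,2}
    mixing: dict[str, np.ndarray]       # label -> (H, W) nonnegative coeffs
    group_label: str
    truth: dict[str, float]
    z_level: float
    nucleus_ids: np.ndarray | None = None   # (H, W) blob index, -1 outside
    nucleus_factors: dict[str, np.ndarray] | None = None  # per-blob factors

    def nucleus_fraction(self) -> float:
        return float(np.mean(self.regions == NUCLEUS))


@dataclass(frozen=True)
class NoiseModel:
    """Measurement-artifact model applied when rendering a scene.

    ``baseline_coeffs`` — if given, a fixed cubic ``(c0, c1, c2, c3)`` in the
    normalized coordinate t in [-1, 1] applied to every pixel; otherwise
    per-pixel coefficients are drawn uniformly in ``±baseline_scale``
    (tapering for higher orders).  ``spike_rate`` is the expected number of
    cosmic-ray spikes per spectrum (Poisson); each spike is a single-bin
    excursion of ``spike_height`` times the pixel's maximum signal, which
    keeps despiking unambiguous.
    """

    baseline_coeffs: tuple[float, float, float, float] | None = None
    baseline_scale: float = 0.3
    noise_sd: float = 0.02
    spike_rate: float = 0.02
    spike_height: float = 6.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_sd < 0 or self.spike_rate < 0:
            raise ValueError("noise_sd and spike_rate must be >= 0")


#: convenience presets
def quiet_noise(seed: int = 0) -> NoiseModel:
    return NoiseModel(baseline_coeffs=(0, 0, 0, 0), baseline_scale=0.0,
                      noise_sd=0.0, spike_rate=0.0, seed=seed)


def make_scene(spec: SceneSpec, seed: int) -> TissueScene:
    """Lay out nuclei, cytoplasm and stroma and draw mixing coefficients.

    Nuclei are irregular connected blobs: Gaussian bumps at rejection-sampled
    centers plus a smoothed random field, thresholded.  Raises
    :class:`LayoutError` when the requested nuclei cannot be placed without
    crowding.
    """
    rng = np.random.default_rng(seed)
    H, W = spec.height, spec.width
    rmin, rmax = spec.nucleus_radius
    radii = rng.uniform(rmin, rmax, spec.n_nuclei)
    margin = rmax + 1
    centers: list[tuple[float, float]] = []
    for r in radii:
        for _ in range(500):
            cy = rng.uniform(margin, H - margin)
            cx = rng.uniform(margin, W - margin)
            if all((cy - oy) ** 2 + (cx - ox) ** 2 > (2.2 * rmax) ** 2
                   for oy, ox in centers):
                centers.append((cy, cx))
                break
        else:
            raise LayoutError(
                f"could not place {spec.n_nuclei} nuclei of radius <= {rmax} "
                f"in a {W}x{H} scene")

    yy, xx = np.mgrid[0:H, 0:W].astype(float)
    bumps = np.stack([np.exp(-0.5 * (((yy - cy) ** 2 + (xx - cx) ** 2) / r**2))
                      for (cy, cx), r in zip(centers, radii)])
    bump = bumps.max(axis=0)
    nucleus_ids = bumps.argmax(axis=0)
    texture = gaussian_filter(rng.standard_normal((H, W)), sigma=2.0)
    texture *= 0.12 / max(texture.std(), 1e-12)
    fieldmap = bump + texture
    nucleus = fieldmap > np.exp(-0.5)          # bump value at one radius
    cytoplasm = (fieldmap > 0.12) & ~nucleus   # halo around each nucleus
    regions = np.full((H, W), STROMA, dtype=int)
    regions[cytoplasm] = CYTOPLASM
    regions[nucleus] = NUCLEUS

    truth = {m: float(spec.truth.get(m, 0.0)) for m in MODIFICATIONS}
    mixing = {label: np.zeros((H, W)) for label in _SPECIES_TABLE}
    u = rng.uniform  # noqa: E731 - terse alias for coefficient draws

    # cell-to-cell heterogeneity: each nucleus carries its own multiplier per
    # modification, so some nuclei are (say) Lys-a-dominant and others
    # DNA-m-dominant — the structure exclusive-spectra extraction relies on
    factors = {m: u(0.15, 1.0, spec.n_nuclei) for m in MODIFICATIONS}
    factors["Z-DNA"] = u(0.5, 1.0, spec.n_nuclei)

    n = nucleus
    ids = nucleus_ids[n]
    dna = u(0.7, 1.0, n.sum())
    lys = u(0.35, 0.6, n.sum())
    arg = u(0.25, 0.45, n.sum())
    mixing["DNA"][n] = dna
    mixing["Lys"][n] = lys
    mixing["Arg"][n] = arg
    mixing["Protein"][n] = u(0.05, 0.2, n.sum())
    base_coeff = {"DNA-m": dna, "Lys-m": lys, "Lys-a": lys, "Arg-m": arg}
    for m in MODIFICATIONS:
        mixing[m][n] = (truth[m] * base_coeff[m] * factors[m][ids]
                        * u(0.6, 1.0, n.sum()))
    bdna = 0.55 * dna * u(0.8, 1.2, n.sum())
    mixing["B-DNA"][n] = bdna
    mixing["Z-DNA"][n] = (spec.z_level * bdna * factors["Z-DNA"][ids]
                          * u(0.6, 1.0, n.sum()))

    c = cytoplasm
    mixing["Protein"][c] = u(0.7, 1.0, c.sum())
    mixing["Collagen"][c] = u(0.0, 0.1, c.sum())
    mixing["Lys"][c] = u(0.0, 0.08, c.sum())

    s = regions == STROMA
    mixing["Collagen"][s] = u(0.5, 0.9, s.sum())
    mixing["Protein"][s] = u(0.0, 0.15, s.sum())

    ids_raster = np.where(nucleus, nucleus_ids, -1)
    return TissueScene(W, H, regions, mixing, spec.group_label, truth,
                       spec.z_level, ids_raster, factors)


def render_map(scene: TissueScene, species: dict[str, SpeciesModel],
               noise: NoiseModel, grid: WavenumberGrid
               ) -> tuple[HyperspectralMap, ClassMap]:
    """Render a scene into a hyperspectral map plus its ground-truth classes.

    Each pixel spectrum is the coefficient-weighted sum of the species
    reference curves, plus a cubic baseline, Gaussian noise, and
    Poisson-count single-bin spikes.  The spike positions and baseline
    coefficients are logged in the map's metadata so preprocessing can be
    audited against the truth.
    """
    missing = set(scene.mixing) - set(species)
    if missing:
        raise SchemaError(f"scene mixes species with no model: {sorted(missing)}")
    rng = np.random.default_rng(noise.seed)
    L = len(grid)
    refs = {label: make_reference(species[label], grid).intensity
            for label in scene.mixing}
    H, W = scene.height, scene.width
    npix = H * W
    coeffs = np.stack([scene.mixing[label].reshape(npix)
                       for label in scene.mixing])        # (S, npix)
    basis = np.stack([refs[label] for label in scene.mixing])  # (S, L)
    signal = coeffs.T @ basis                              # (npix, L)

    t = np.linspace(-1.0, 1.0, L)
    if noise.baseline_coeffs is not None:
        bc = np.tile(np.asarray(noise.baseline_coeffs, float), (npix, 1))
    else:
        scale = noise.baseline_scale
        bc = rng.uniform(-1, 1, (npix, 4)) * np.array(
            [scale, scale, 0.5 * scale, 0.25 * scale])
    baseline = bc @ np.vander(t, 4, increasing=True).T     # (npix, L)
    spectra = signal + baseline
    if noise.noise_sd > 0:
        spectra = spectra + rng.normal(0.0, noise.noise_sd, (npix, L))

    spike_log: list[tuple[int, int]] = []
    if noise.spike_rate > 0:
        counts = rng.poisson(noise.spike_rate, npix)
        peak = np.maximum(signal.max(axis=1), 1.0)
        for i in np.flatnonzero(counts):
            pos = rng.choice(L, size=counts[i], replace=False)
            spectra[i, pos] += noise.spike_height * peak[i]
            spike_log.extend((int(i), int(p)) for p in pos)

    cube = spectra.reshape(H, W, L)
    metadata = {
        "group": scene.group_label,
        "truth": dict(scene.truth),
        "z_level": scene.z_level,
        "spikes": spike_log,
        "baseline_coeffs": bc,
    }
    hsmap = HyperspectralMap(grid, cube, metadata=metadata)
    classmap = ClassMap(scene.regions.copy())
    return hsmap, classmap
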