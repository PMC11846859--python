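"""Binary modification-status calling and exclusive-spectra extraction.

A nucleus pixel is called *positive* for a species when its Pearson score
against that species' reference reaches the species' cutoff — by default the
3rd quartile (0.75) of the scores over nucleus pixels only, estimated per
map and per species with the linear-interpolation quantile convention; ties
at the cutoff count as positive.

The *exclusive* spectra of a modification are the nucleus pixels positive
for that modification AND its base species (DNA for DNA-m, Lys for
Lys-m/Lys-a, Arg for Arg-m) while negative for every other modification;
multi-positive pixels are deliberately discarded, so exclusive sets of
different modifications are pairwise disjoint.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import ClassMap, HyperspectralMap, NUCLEUS, SchemaError
from .correlate import CorrelationMap
from .synth import BASE_OF, MODIFICATIONS

__all__ = [
    "STATUS_LABELS",
    "StatusTable",
    "ExclusiveSet",
    "call_status",
    "extract_exclusive",
    "overlay_multiplex",
    "MultiplexOverlay",
]

#: the seven species a status table covers
STATUS_LABELS = ("DNA", "DNA-m", "Lys", "Lys-m", "Lys-a", "Arg", "Arg-m")


@dataclass
class StatusTable:
    """Per-nucleus-pixel binary modification status.

    ``table`` has one row per nucleus pixel (columns ``x``, ``y``, then one
    0/1 column per label); ``cutoffs`` records the per-label threshold used.
    """

    table: pd.DataFrame
    cutoffs: dict[str, float]
    quantile: float
    degenerate_labels: tuple[str, ...] = ()

    @property
    def n_pixels(self) -> int:
        return len(self.table)

    def positives(self, label: str) -> pd.DataFrame:
        return self.table[self.table[label] == 1]


@dataclass
class ExclusiveSet:
    """Nucleus pixels exclusively positive for one modification."""

    modification_label: str
    member_pixels: np.ndarray                 # (n, 2) of (x, y)
    spectra: np.ndarray | None = None         # (n, L) if a map was supplied

    def __len__(self) -> int:
        return int(self.member_pixels.shape[0])


def call_status(corr_maps: dict[str, CorrelationMap], classmap: ClassMap,
                quantile: float = 0.75, labels: tuple[str, ...] = STATUS_LABELS
                ) -> StatusTable:
    """Threshold Pearson scores at the per-label nucleus-only quantile.

    ``corr_maps`` must contain one map per label in ``labels``; cutoffs are
    the linear-interpolation quantile of raw scores over pixels the class
    map marks as nucleus; a pixel is positive iff score >= cutoff.
    """
    if not 0.0 < quantile < 1.0:
        raise ValueError("quantile must lie in (0, 1)")
    missing = [lbl for lbl in labels if lbl not in corr_maps]
    if missing:
        raise SchemaError(f"missing correlation maps for {missing}")
    first = corr_maps[labels[0]]
    if classmap.labels.shape != first.raw.shape:
        raise SchemaError("class map raster does not match correlation maps")
    nucleus = (classmap.labels == NUCLEUS) & classmap.mask
    if not nucleus.any():
        raise ValueError("no nucleus pixels: status calling has empty domain")
    ys, xs = np.nonzero(nucleus)
    data: dict[str, np.ndarray] = {"x": xs, "y": ys}
    cutoffs: dict[str, float] = {}
    degenerate = []
    for lbl in labels:
        cmap = corr_maps[lbl]
        if cmap.raw.shape != first.raw.shape:
            raise SchemaError(f"correlation map {lbl!r} has a different raster")
        scores = cmap.raw[nucleus]
        if np.isnan(scores).any():
            raise ValueError(f"undefined scores among nucleus pixels for {lbl!r}")
        cutoff = float(np.quantile(scores, quantile))
        cutoffs[lbl] = cutoff
        if scores.min() == scores.max():
            degenerate.append(lbl)
        data[lbl] = (scores >= cutoff).astype(int)
    return StatusTable(pd.DataFrame(data), cutoffs, quantile,
                       tuple(degenerate))


def extract_exclusive(status: StatusTable, modification: str,
                      hsmap: HyperspectralMap | None = None) -> ExclusiveSet:
    """Select pixels positive for ``modification`` and its base species and
    negative for all other modifications."""
    if modification not in BASE_OF:
        raise ValueError(
            f"unknown modification {modification!r}; one of {MODIFICATIONS}")
    base = BASE_OF[modification]
    others = [m for m in MODIFICATIONS if m != modification]
    t = status.table
    keep = (t[modification] == 1) & (t[base] == 1)
    for other in others:
        keep &= t[other] == 0
    members = t.loc[keep, ["x", "y"]].to_numpy(int)
    spectra = None
    if hsmap is not None and members.size:
        spectra = np.stack([hsmap.cube[y, x] for x, y in members])
    elif hsmap is not None:
        spectra = np.empty((0, len(hsmap.grid)))
    return ExclusiveSet(modification, members, spectra)


@dataclass
class MultiplexOverlay:
    """A DNA base heatmap with per-modification opacity layers.

    ``alphas[mod]`` is an (H, W) opacity raster: the modification's
    normalized score on pixels positive for both the modification and its
    base species, zero elsewhere — color dots fading from transparent to
    opaque with the modification level.
    """

    base: np.ndarray                          # (H, W) normalized DNA scores
    alphas: dict[str, np.ndarray] = field(default_factory=dict)
    colors: dict[str, tuple[float, float, float]] = field(default_factory=dict)

    def composite(self) -> np.ndarray:
        """Flatten to an (H, W, 3) RGB float image (gray base + color dots)."""
        img = np.repeat(np.nan_to_num(self.base)[:, :, None], 3, axis=2)
        for mod, alpha in self.alphas.items():
            color = np.array(self.colors.get(mod, (0.0, 0.8, 0.0)))
            a = alpha[:, :, None]
            img = img * (1 - a) + color[None, None, :] * a
        return img


_DEFAULT_COLORS = {
    "DNA-m": (0.1, 0.4, 1.0),
    "Lys-m": (1.0, 0.6, 0.0),
    "Lys-a": (0.0, 0.8, 0.2),
    "Arg-m": (0.8, 0.0, 0.8),
}


def overlay_multiplex(base_corr: CorrelationMap, em_status: StatusTable,
                      em_levels: dict[str, CorrelationMap],
                      colors: dict[str, tuple[float, float, float]] | None = None
                      ) -> MultiplexOverlay:
    """Build the multiplexed overlay: modification dots on the DNA heatmap,
    opacity scaling with the normalized modification score, restricted to
    pixels positive for the modification and its base species."""
    colors = {**_DEFAULT_COLORS, **(colors or {})}
    overlay = MultiplexOverlay(base_corr.norm.copy(), colors=colors)
    t = em_status.table
    for mod, cmap in em_levels.items():
        if mod not in BASE_OF:
            raise ValueError(f"unknown modification {mod!r}")
        alpha = np.zeros_like(base_corr.norm)
        keep = (t[mod] == 1) & (t[BASE_OF[mod]] == 1)
        for _, row in t.loc[keep].iterrows():
            x, y = int(row["x"]), int(row["y"])
            alpha[y, x] = cmap.norm[y, x]
        overlay.alphas[mod] = alpha
    return overlay
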