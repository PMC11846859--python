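"""Reference-spectrum similarity scoring and correlation heatmaps.

Every pixel spectrum is scored against a reference spectrum with one of five
similarity metrics — Pearson R (the pipeline default), Spearman rho,
unit-normalized Euclidean distance, squared cosine similarity, and squared
first-difference cosine similarity — over the common fingerprint window.
Per-map scores are min-max normalized to [0, 1]; distance-type metrics are
sign-flipped before normalization so a higher normalized score always means
more similar.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .containers import (
    ClassMap,
    HyperspectralMap,
    NUCLEUS,
    ReferenceSpectrum,
    Spectrum,
)
from .spectral_io import FINGERPRINT_RANGE, common_window, resample_reference

__all__ = [
    "METRICS",
    "UndefinedCorrelationError",
    "CorrelationMap",
    "similarity",
    "correlation_map",
    "compare_metrics",
]

METRICS = (
    "pearson",
    "spearman",
    "euclidean-unit-norm",
    "cosine-squared",
    "first-difference-cosine-squared",
)

#: metrics whose raw value is a distance (lower = more similar)
_DISTANCE_METRICS = {"euclidean-unit-norm"}


class UndefinedCorrelationError(ValueError):
    """Pearson/Spearman are undefined for a constant input."""


def _raw_scores(x: np.ndarray, ref: np.ndarray, metric: str) -> np.ndarray:
    """Vectorized metric of each row of ``x`` against ``ref``.

    Constant rows yield NaN under pearson/spearman (callers decide whether
    that is an error or a flagged pixel).
    """
    if metric == "spearman":
        x = stats.rankdata(x, axis=1)
        ref = stats.rankdata(ref)
        metric = "pearson"
    if metric == "pearson":
        xc = x - x.mean(axis=1, keepdims=True)
        rc = ref - ref.mean()
        denom = np.linalg.norm(xc, axis=1) * np.linalg.norm(rc)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(denom > 0, xc @ rc / denom, np.nan)
    if metric == "euclidean-unit-norm":
        xn = x / np.maximum(np.linalg.norm(x, axis=1, keepdims=True), 1e-300)
        rn = ref / max(np.linalg.norm(ref), 1e-300)
        return np.linalg.norm(xn - rn, axis=1)
    if metric == "cosine-squared":
        denom = np.maximum(np.linalg.norm(x, axis=1) * np.linalg.norm(ref),
                           1e-300)
        return (x @ ref / denom) ** 2
    if metric == "first-difference-cosine-squared":
        return _raw_scores(np.diff(x, axis=1), np.diff(ref), "cosine-squared")
    raise ValueError(f"unknown metric {metric!r}; choose from {METRICS}")


def similarity(a: Spectrum, b: Spectrum, metric: str = "pearson") -> float:
    """Score two spectra on a shared grid with the chosen metric.

    Pearson/Spearman lie in [-1, 1]; the cosine-squared variants in [0, 1];
    ``euclidean-unit-norm`` is returned as a distance (lower = more similar).
    """
    if a.grid != b.grid:
        raise ValueError("spectra must share one grid (resample first)")
    score = _raw_scores(a.intensity[None, :], b.intensity, metric)[0]
    if np.isnan(score) and metric in ("pearson", "spearman"):
        raise UndefinedCorrelationError(
            f"{metric} undefined for a constant spectrum")
    return float(score)


@dataclass
class CorrelationMap:
    """Per-pixel similarity against one reference over a map raster."""

    reference_label: str
    metric: str
    raw: np.ndarray            # (H, W); NaN where undefined/unoccupied
    norm: np.ndarray           # (H, W) in [0, 1]
    mask: np.ndarray           # occupied pixels
    grid_range: tuple[float, float]
    degenerate: bool = False   # all raw scores identical

    def raw_flat(self) -> np.ndarray:
        return self.raw[self.mask]

    def norm_flat(self) -> np.ndarray:
        return self.norm[self.mask]


def correlation_map(hsmap: HyperspectralMap, reference: ReferenceSpectrum,
                    metric: str = "pearson",
                    window: tuple[float, float] = FINGERPRINT_RANGE
                    ) -> CorrelationMap:
    """Score every occupied pixel against a reference.

    The reference is resampled onto the map grid restricted to the common
    fingerprint window; raw scores are min-max normalized per map (distances
    sign-flipped first).  A map whose scores are all identical is flagged
    degenerate and its normalized scores set to 0.5.
    """
    if metric not in METRICS:
        raise ValueError(f"unknown metric {metric!r}; choose from {METRICS}")
    grid = common_window(hsmap.grid, reference.grid, lo=window[0],
                         hi=window[1])
    idx = np.searchsorted(hsmap.grid.values, grid.values)
    ref = resample_reference(reference, grid)
    x = hsmap.intensities()[:, idx]
    scores = _raw_scores(x, ref.intensity, metric)

    oriented = -scores if metric in _DISTANCE_METRICS else scores
    finite = oriented[np.isfinite(oriented)]
    if finite.size == 0:
        raise UndefinedCorrelationError(
            "no pixel yields a defined score (all spectra constant)")
    lo, hi = finite.min(), finite.max()
    degenerate = hi == lo
    with np.errstate(invalid="ignore"):
        norm_scores = (np.full_like(oriented, 0.5) if degenerate
                       else (oriented - lo) / (hi - lo))

    shape = (hsmap.height, hsmap.width)
    raw = np.full(shape, np.nan)
    norm = np.full(shape, np.nan)
    raw[hsmap.mask] = scores
    norm[hsmap.mask] = norm_scores
    return CorrelationMap(reference.label, metric, raw, norm,
                          hsmap.mask.copy(), grid.range, degenerate)


def compare_metrics(hsmap: HyperspectralMap, reference: ReferenceSpectrum,
                    truth: ClassMap) -> pd.DataFrame:
    """Quantitative replacement for choosing the metric by eye.

    For each of the five metrics, reports the nucleus/background contrast:
    the difference of mean normalized scores between ground-truth nucleus
    pixels and all other occupied pixels.
    """
    if truth.labels.shape != (hsmap.height, hsmap.width):
        raise ValueError("ground-truth class map does not match the map raster")
    rows = []
    nucleus = (truth.labels == NUCLEUS) & hsmap.mask
    other = (truth.labels != NUCLEUS) & hsmap.mask
    if not nucleus.any() or not other.any():
        raise ValueError("contrast needs both nucleus and non-nucleus pixels")
    for metric in METRICS:
        cmap = correlation_map(hsmap, reference, metric)
        separation = (np.nanmean(cmap.norm[nucleus])
                      - np.nanmean(cmap.norm[other]))
        rows.append({"metric": metric, "separation": float(separation)})
    return pd.DataFrame(rows)
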