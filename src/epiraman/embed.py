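"""Group-structure analyses: PCA with loadings and t-SNE embedding.

PCA runs on mean-centered (not variance-scaled) normalized spectra —
intensities share units, so scaling is off by default — and reports scores,
orthonormal loadings, explained-variance fractions and per-group median
coordinates along each component.  t-SNE uses PCA initialization for
stability and is reproducible for a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA
from sklearn.manifold import TSNE

from .containers import WavenumberGrid

__all__ = [
    "EmbeddingResult",
    "pca_embed",
    "tsne_embed",
    "loading_interpretation",
]


@dataclass
class EmbeddingResult:
    method: str                          # "pca" or "tsne"
    coordinates: np.ndarray              # (n, k)
    group_labels: np.ndarray             # (n,) str
    loadings: np.ndarray | None = None   # (k, n_wavenumbers), pca only
    explained_variance_ratio: np.ndarray | None = None
    grid: WavenumberGrid | None = None

    def group_medians(self) -> pd.DataFrame:
        """Median coordinate of each group along each component."""
        rows = []
        for group in pd.unique(self.group_labels):
            sel = self.coordinates[self.group_labels == group]
            rows.append({"group": group,
                         **{f"dim{i + 1}": float(np.median(sel[:, i]))
                            for i in range(sel.shape[1])}})
        return pd.DataFrame(rows)

    def to_frame(self) -> pd.DataFrame:
        frame = pd.DataFrame(
            self.coordinates,
            columns=[f"dim{i + 1}" for i in range(self.coordinates.shape[1])])
        frame.insert(0, "group", self.group_labels)
        return frame


def _as_matrix(spectra) -> np.ndarray:
    if isinstance(spectra, np.ndarray):
        return np.asarray(spectra, dtype=float)
    return np.stack([s.intensity for s in spectra]).astype(float)


def pca_embed(spectra, group_labels, k: int = 2,
              grid: WavenumberGrid | None = None) -> EmbeddingResult:
    """Principal component scores and loadings of labeled spectra."""
    x = _as_matrix(spectra)
    labels = np.asarray(group_labels)
    if labels.size != x.shape[0]:
        raise ValueError("one group label per spectrum required")
    max_rank = min(x.shape[0] - 1, x.shape[1])
    if not 1 <= k <= max_rank:
        raise ValueError(f"k={k} exceeds the data rank bound ({max_rank})")
    pca = PCA(n_components=k, svd_solver="full")
    scores = pca.fit_transform(x)
    return EmbeddingResult("pca", scores, labels, pca.components_,
                           pca.explained_variance_ratio_, grid)


def tsne_embed(spectra, group_labels, perplexity: float = 30.0,
               seed: int = 0, n_iter: int = 1000) -> EmbeddingResult:
    """2-D t-SNE embedding, deterministic for a fixed seed."""
    x = _as_matrix(spectra)
    labels = np.asarray(group_labels)
    if x.shape[0] <= 3 * perplexity:
        raise ValueError(
            f"perplexity {perplexity} too large for n={x.shape[0]} "
            "(need n > 3*perplexity)")
    tsne = TSNE(n_components=2, perplexity=perplexity, init="pca",
                random_state=int(seed), max_iter=n_iter)
    coords = tsne.fit_transform(x)
    return EmbeddingResult("tsne", np.asarray(coords, float), labels)


def loading_interpretation(result: EmbeddingResult, top_n: int,
                           grid: WavenumberGrid | None = None) -> pd.DataFrame:
    """Top-|weight| wavenumbers per principal component.

    Returns a (component, wavenumber, weight) table, sorted within each
    component by absolute weight descending; ``top_n`` larger than the grid
    is clipped with a warning.
    """
    if result.method != "pca" or result.loadings is None:
        raise ValueError("loading interpretation requires a PCA result")
    grid = grid or result.grid
    if grid is None:
        raise ValueError("a wavenumber grid is required to name loadings")
    w = grid.values
    n_points = result.loadings.shape[1]
    if top_n > n_points:
        import warnings

        warnings.warn(f"top_n={top_n} exceeds grid length {n_points}; clipped",
                      stacklevel=2)
        top_n = n_points
    rows = []
    for comp, loading in enumerate(result.loadings, start=1):
        order = np.argsort(-np.abs(loading), kind="stable")[:top_n]
        for idx in order:
            rows.append({"component": comp, "wavenumber": float(w[idx]),
                         "weight": float(loading[idx])})
    return pd.DataFrame(rows, columns=["component", "wavenumber", "weight"])
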