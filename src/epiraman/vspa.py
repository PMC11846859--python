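"""Volcano-plot-based spectral peak analysis (VSPA).

Two groups of spectra (typically the exclusive spectra of a modification
versus its base species) are compared position by position: the fold change
is the ratio of group mean intensities (log2-transformed, modified group
over base group) and significance comes from a two-sided Mann-Whitney U test
on the per-spectrum intensities at that position, flagged at raw p < alpha
(0.01 by default, no multiple-testing correction — an optional
Benjamini-Hochberg mode is provided but off by default).

Tested positions are either the local maxima of the pooled mean spectrum
with relative prominence >= 5% of its range ("peaks" mode) or every grid
point ("exhaustive" mode).  The U test enumerates the exact null for small
tie-free groups (both n <= 12) and otherwise uses the midrank normal
approximation with tie correction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.signal import find_peaks
from statsmodels.stats.multitest import multipletests

from .containers import WavenumberGrid

__all__ = [
    "VolcanoResult",
    "detect_test_positions",
    "volcano",
    "significant_peaks_plot",
]


def _as_matrix(group) -> np.ndarray:
    if isinstance(group, np.ndarray):
        return np.asarray(group, dtype=float)
    return np.stack([s.intensity for s in group]).astype(float)


@dataclass
class VolcanoResult:
    """Per-position fold change and significance for one group contrast."""

    positions: np.ndarray          # tested wavenumbers (cm^-1), ascending
    log2_fold_change: np.ndarray
    p_values: np.ndarray
    significant: np.ndarray        # boolean, p < alpha
    alpha: float
    group_sizes: tuple[int, int]
    excluded: list[dict] = field(default_factory=list)  # undefined positions
    adjusted: bool = False

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "wavenumber": self.positions,
            "log2fc": self.log2_fold_change,
            "p_value": self.p_values,
            "significant": self.significant.astype(int),
        })


def detect_test_positions(group_a, group_b, grid: WavenumberGrid,
                          mode: str = "peaks",
                          prominence_fraction: float = 0.05) -> np.ndarray:
    """Wavenumbers at which the two groups will be compared."""
    a, b = _as_matrix(group_a), _as_matrix(group_b)
    if a.shape[0] < 3 or b.shape[0] < 3:
        raise ValueError("need >= 3 spectra per group")
    if a.shape[1] != len(grid) or b.shape[1] != len(grid):
        raise ValueError("spectra do not match the grid length")
    if mode == "exhaustive":
        return grid.values.copy()
    if mode != "peaks":
        raise ValueError("mode must be 'peaks' or 'exhaustive'")
    pooled = np.concatenate([a, b]).mean(axis=0)
    span = pooled.max() - pooled.min()
    if span == 0:
        return np.array([])
    idx, _ = find_peaks(pooled, prominence=prominence_fraction * span)
    return grid.values[idx]


def _mwu_p(a: np.ndarray, b: np.ndarray) -> float:
    if np.ptp(np.concatenate([a, b])) == 0:
        return 1.0
    pooled = np.concatenate([a, b])
    exact = (a.size <= 12 and b.size <= 12
             and np.unique(pooled).size == pooled.size)
    res = stats.mannwhitneyu(a, b, alternative="two-sided",
                             method="exact" if exact else "asymptotic")
    return float(min(res.pvalue, 1.0))


def volcano(group_a, group_b, grid: WavenumberGrid,
            positions: np.ndarray | None = None, alpha: float = 0.01,
            mode: str = "peaks", adjust: bool = False) -> VolcanoResult:
    """Fold change (group_a over group_b) and Mann-Whitney p per position.

    Positions where either group's mean intensity is non-positive have an
    undefined log fold change; they are excluded and logged.  ``adjust=True``
    applies Benjamini-Hochberg before flagging (off by default).
    """
    a, b = _as_matrix(group_a), _as_matrix(group_b)
    if a.shape[1] != b.shape[1] or a.shape[1] != len(grid):
        raise ValueError("groups must share the analysis grid")
    if positions is None:
        positions = detect_test_positions(a, b, grid, mode=mode)
    positions = np.sort(np.asarray(positions, dtype=float))
    w = grid.values
    kept, log2fc, pvals, excluded = [], [], [], []
    for pos in positions:
        j = int(np.argmin(np.abs(w - pos)))
        if not np.isclose(w[j], pos):
            raise ValueError(f"position {pos:g} not on the grid")
        ma, mb = a[:, j].mean(), b[:, j].mean()
        if ma <= 0 or mb <= 0:
            excluded.append({"wavenumber": float(pos),
                             "reason": "non-positive group mean"})
            continue
        kept.append(pos)
        log2fc.append(np.log2(ma / mb))
        pvals.append(_mwu_p(a[:, j], b[:, j]))
    pvals_arr = np.array(pvals)
    if adjust and pvals_arr.size:
        _, qvals, _, _ = multipletests(pvals_arr, method="fdr_bh")
        flag_on = qvals
    else:
        flag_on = pvals_arr
    return VolcanoResult(np.array(kept), np.array(log2fc), pvals_arr,
                         flag_on < alpha, alpha, (a.shape[0], b.shape[0]),
                         excluded, adjusted=adjust)


def significant_peaks_plot(result: VolcanoResult) -> pd.DataFrame:
    """Plot data for the significant-peaks view: log2 fold change against
    Raman shift, significant positions flagged (the red dots)."""
    frame = result.to_frame().sort_values("wavenumber", ignore_index=True)
    frame["flagged"] = frame["significant"].astype(bool)
    return frame
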