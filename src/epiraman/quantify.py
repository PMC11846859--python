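"""Group-level semi-quantification of modification levels and the Z-DNA score.

A group's *level* of a modification is the median of per-spectrum Pearson
scores collected from nucleus pixels positive for the modification's base
species (DNA for DNA-m and the conformers, Lys for Lys-m/Lys-a, Arg for
Arg-m), pooled across the group's maps.  Levels are reported as a ratio to
the control group, whose own ratio is exactly 1 by construction.  The Z-DNA
score is the group's Z-level over B-level ratio, again expressed relative to
control (control = 1.00).

Group differences are tested with the Kruskal-Wallis H omnibus (with tie
correction) followed by Dunn's pairwise post hoc z tests, p values adjusted
with the Holm step-down over the full pairwise family.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .exclusive import StatusTable
from .correlate import CorrelationMap
from .synth import BASE_OF

__all__ = [
    "GroupLevels",
    "RelativeLevel",
    "ZDNAScore",
    "GroupTestResult",
    "MapBundle",
    "collect_levels",
    "relative_levels",
    "zdna_score",
    "group_tests",
    "dunn_posthoc",
]


@dataclass
class MapBundle:
    """One analyzed map: its correlation maps and nucleus status table."""

    corr: dict[str, CorrelationMap]
    status: StatusTable


@dataclass
class GroupLevels:
    group_label: str
    modification: str
    scores: np.ndarray

    @property
    def n(self) -> int:
        return int(self.scores.size)

    def level(self, center: str = "median") -> float:
        return float(np.median(self.scores) if center == "median"
                     else np.mean(self.scores))


@dataclass
class RelativeLevel:
    group_label: str
    modification: str
    ratio_to_ctrl: float
    dispersion: float      # interquartile range of the group's scores
    n: int


@dataclass
class ZDNAScore:
    group_label: str
    score: float           # (Z/B) / (Z/B of control)
    n: int


@dataclass
class GroupTestResult:
    h_statistic: float
    p_omnibus: float
    pairwise: pd.DataFrame     # group1, group2, dunn_z, p, q


def _base_species(modification: str) -> str:
    if modification in BASE_OF:
        return BASE_OF[modification]
    if modification in ("Z-DNA", "B-DNA", "DNA"):
        return "DNA"
    if modification in ("Lys", "Arg"):
        return modification
    raise ValueError(f"no base-positivity rule for label {modification!r}")


def collect_levels(group_maps: dict[str, list[MapBundle]], modification: str,
                   score: str = "raw") -> dict[str, GroupLevels]:
    """Pool qualifying per-spectrum scores per group.

    Qualifying pixels are nucleus pixels (the status table's domain) that
    are positive for the modification's base species.  Raises when a group
    ends up with zero qualifying spectra.
    """
    base = _base_species(modification)
    out: dict[str, GroupLevels] = {}
    for group, bundles in group_maps.items():
        pooled = []
        for bundle in bundles:
            cmap = bundle.corr[modification]
            t = bundle.status.table
            keep = t[base] == 1
            xs = t.loc[keep, "x"].to_numpy(int)
            ys = t.loc[keep, "y"].to_numpy(int)
            values = (cmap.raw if score == "raw" else cmap.norm)[ys, xs]
            pooled.append(values)
        scores = (np.concatenate(pooled) if pooled
                  else np.empty(0))
        if scores.size == 0:
            raise ValueError(
                f"group {group!r} has no {base}-positive nucleus spectra")
        out[group] = GroupLevels(group, modification, scores)
    return out


def relative_levels(groups: dict[str, GroupLevels], ctrl_label: str = "CTRL",
                    center: str = "median") -> dict[str, RelativeLevel]:
    """Per-group level expressed as a ratio to the control group's level."""
    if ctrl_label not in groups:
        raise ValueError(f"control group {ctrl_label!r} missing")
    ctrl_level = groups[ctrl_label].level(center)
    if ctrl_level == 0:
        raise ZeroDivisionError("control level is zero; ratio undefined")
    out = {}
    for label, gl in groups.items():
        ratio = 1.0 if label == ctrl_label else gl.level(center) / ctrl_level
        iqr = float(np.subtract(*np.percentile(gl.scores, [75, 25])))
        out[label] = RelativeLevel(label, gl.modification, ratio, iqr, gl.n)
    return out


def zdna_score(z_groups: dict[str, GroupLevels],
               b_groups: dict[str, GroupLevels],
               ctrl_label: str = "CTRL", center: str = "median"
               ) -> dict[str, ZDNAScore]:
    """Z/B conformation ratio per group, relative to control (control = 1)."""
    if ctrl_label not in z_groups or ctrl_label not in b_groups:
        raise ValueError(f"control group {ctrl_label!r} missing")

    def zb(label: str) -> float:
        b = b_groups[label].level(center)
        if b == 0:
            raise ZeroDivisionError(f"group {label!r} has zero B-DNA level")
        return z_groups[label].level(center) / b

    ctrl = zb(ctrl_label)
    if ctrl == 0:
        raise ZeroDivisionError("control Z/B ratio is zero; score undefined")
    out = {}
    for label in z_groups:
        score = 1.0 if label == ctrl_label else zb(label) / ctrl
        out[label] = ZDNAScore(label, score, z_groups[label].n)
    return out


def dunn_posthoc(samples: dict[str, np.ndarray]) -> pd.DataFrame:
    """All pairwise Dunn z tests on pooled midranks with tie correction;
    Holm-adjusted q over the full pairwise family."""
    labels = list(samples)
    values = [np.asarray(samples[lbl], dtype=float) for lbl in labels]
    pooled = np.concatenate(values)
    n_total = pooled.size
    ranks = stats.rankdata(pooled)
    mean_ranks, sizes = {}, {}
    start = 0
    for lbl, v in zip(labels, values):
        mean_ranks[lbl] = ranks[start:start + v.size].mean()
        sizes[lbl] = v.size
        start += v.size
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = np.sum(counts**3 - counts) / (12.0 * (n_total - 1))
    base_var = n_total * (n_total + 1) / 12.0 - tie_term
    rows = []
    for i in range(len(labels)):
        for j in range(i + 1, len(labels)):
            a, b = labels[i], labels[j]
            se = np.sqrt(base_var * (1.0 / sizes[a] + 1.0 / sizes[b]))
            z = (mean_ranks[a] - mean_ranks[b]) / se if se > 0 else 0.0
            p = 2.0 * stats.norm.sf(abs(z))
            rows.append({"group1": a, "group2": b, "dunn_z": float(z),
                         "p": float(min(p, 1.0))})
    frame = pd.DataFrame(rows)
    _, qvals, _, _ = multipletests(frame["p"].to_numpy(), method="holm")
    frame["q"] = qvals
    return frame


def group_tests(groups: dict[str, GroupLevels]) -> GroupTestResult:
    """Kruskal-Wallis omnibus plus Dunn/Holm pairwise comparisons."""
    if len(groups) < 2:
        raise ValueError("need >= 2 groups")
    samples = {lbl: gl.scores for lbl, gl in groups.items()}
    for lbl, v in samples.items():
        if v.size < 2:
            raise ValueError(f"group {lbl!r} has fewer than 2 observations")
    pooled = np.concatenate(list(samples.values()))
    if np.ptp(pooled) == 0:
        raise ValueError("all observations identical; tests degenerate")
    h, p = stats.kruskal(*samples.values())
    pairwise = dunn_posthoc(samples)
    return GroupTestResult(float(h), float(p), pairwise)
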