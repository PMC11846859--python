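"""Group levels, control ratios, Z-DNA score and nonparametric tests."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from epiraman import quantify
from epiraman.correlate import CorrelationMap
from epiraman.exclusive import STATUS_LABELS, StatusTable
from epiraman.quantify import (
    GroupLevels,
    MapBundle,
    collect_levels,
    dunn_posthoc,
    group_tests,
    relative_levels,
    zdna_score,
)


def toy_bundle(scores_by_label: dict[str, list[float]],
               status_rows: pd.DataFrame) -> MapBundle:
    """Build a MapBundle over a 1-row raster of n pixels."""
    n = len(status_rows)
    corr = {}
    for lbl, values in scores_by_label.items():
        raw = np.asarray(values, dtype=float)[None, :]
        corr[lbl] = CorrelationMap(lbl, "pearson", raw, raw.copy(),
                                   np.ones_like(raw, dtype=bool), (600, 1900))
    return MapBundle(corr, StatusTable(status_rows, {}, 0.75))


def status_frame(base_flags: list[int], label: str = "DNA") -> pd.DataFrame:
    n = len(base_flags)
    frame = pd.DataFrame({"x": np.arange(n), "y": np.zeros(n, dtype=int)})
    for lbl in STATUS_LABELS:
        frame[lbl] = 0
    frame[label] = base_flags
    return frame


class TestCollectLevels:
    def test_base_positive_filter_matches_predicate_oracle(self):
        scores = [0.1, 0.2, 0.3, 0.4, 0.5]
        flags = [1, 0, 1, 1, 0]
        bundle = toy_bundle({"DNA-m": scores, "DNA": scores},
                            status_frame(flags))
        levels = collect_levels({"G": [bundle]}, "DNA-m")
        expected = [s for s, f in zip(scores, flags) if f == 1]
        np.testing.assert_allclose(np.sort(levels["G"].scores),
                                   np.sort(expected))
        assert levels["G"].n == 3

    def test_pooling_across_maps(self):
        b1 = toy_bundle({"DNA-m": [0.1, 0.2, 0.3], "DNA": [1, 1, 1]},
                        status_frame([1, 1, 1]))
        b2 = toy_bundle({"DNA-m": [0.4, 0.5, 0.6, 0.7], "DNA": [1] * 4},
                        status_frame([1, 1, 1, 1]))
        levels = collect_levels({"G": [b1, b2]}, "DNA-m")
        assert levels["G"].n == 7

    def test_all_base_negative_is_error(self):
        bundle = toy_bundle({"DNA-m": [0.1, 0.2], "DNA": [0.1, 0.2]},
                            status_frame([0, 0]))
        with pytest.raises(ValueError, match="'G'"):
            collect_levels({"G": [bundle]}, "DNA-m")


class TestRelativeLevels:
    def groups(self, ctrl, other):
        return {"CTRL": GroupLevels("CTRL", "Lys-a", np.asarray(ctrl, float)),
                "X": GroupLevels("X", "Lys-a", np.asarray(other, float))}

    def test_ctrl_ratio_exactly_one(self):
        rel = relative_levels(self.groups([1, 2, 3], [2, 3, 4]))
        assert rel["CTRL"].ratio_to_ctrl == 1.0

    def test_doubled_scores_double_ratio(self):
        ctrl = [0.2, 0.3, 0.4]
        rel = relative_levels(self.groups(ctrl, [0.4, 0.6, 0.8]))
        assert rel["X"].ratio_to_ctrl == pytest.approx(2.0)

    def test_invariant_under_common_rescaling(self):
        ctrl, other = [0.2, 0.3, 0.5], [0.3, 0.4, 0.6]
        r1 = relative_levels(self.groups(ctrl, other))["X"].ratio_to_ctrl
        r2 = relative_levels(self.groups([7 * c for c in ctrl],
                                         [7 * o for o in other]))["X"].ratio_to_ctrl
        assert r1 == pytest.approx(r2, abs=1e-12)

    def test_missing_ctrl_rejected(self):
        groups = {"X": GroupLevels("X", "Lys-a", np.array([1.0, 2.0]))}
        with pytest.raises(ValueError, match="CTRL"):
            relative_levels(groups)


class TestZdnaScore:
    def make(self, z_ctrl, b_ctrl, z_x, b_x):
        z = {"CTRL": GroupLevels("CTRL", "Z-DNA", np.asarray(z_ctrl, float)),
             "X": GroupLevels("X", "Z-DNA", np.asarray(z_x, float))}
        b = {"CTRL": GroupLevels("CTRL", "B-DNA", np.asarray(b_ctrl, float)),
             "X": GroupLevels("X", "B-DNA", np.asarray(b_x, float))}
        return z, b

    def test_symmetric_case_is_one(self):
        z, b = self.make([1, 2, 3], [1, 2, 3], [4, 5, 6], [4, 5, 6])
        scores = zdna_score(z, b)
        assert scores["CTRL"].score == 1.0
        assert scores["X"].score == pytest.approx(1.0)

    def test_invariant_under_common_positive_scaling(self):
        z, b = self.make([1, 2], [2, 3], [2, 4], [2, 3])
        s1 = zdna_score(z, b)["X"].score
        z2, b2 = self.make([5, 10], [10, 15], [10, 20], [10, 15])
        s2 = zdna_score(z2, b2)["X"].score
        assert s1 == pytest.approx(s2, abs=1e-12)

    def test_zero_b_level_rejected(self):
        z, b = self.make([1, 2], [0, 0], [1, 2], [1, 2])
        with pytest.raises(ZeroDivisionError):
            zdna_score(z, b)


class TestGroupTests:
    def test_kruskal_h_matches_rank_sum_formula(self):
        """3x3 toy of distinct values: H computed from the rank-sum formula
        by hand equals the module's omnibus statistic."""
        data = {"A": np.array([1.0, 4.0, 7.0]),
                "B": np.array([2.0, 5.0, 8.0]),
                "C": np.array([3.0, 6.0, 9.0])}
        groups = {k: GroupLevels(k, "m", v) for k, v in data.items()}
        result = group_tests(groups)
        pooled = np.concatenate(list(data.values()))
        ranks = stats.rankdata(pooled)
        n_total = pooled.size
        h = 0.0
        start = 0
        for v in data.values():
            r = ranks[start:start + v.size]
            h += r.sum() ** 2 / v.size
            start += v.size
        h = 12.0 / (n_total * (n_total + 1)) * h - 3 * (n_total + 1)
        assert result.h_statistic == pytest.approx(h, abs=1e-12)

    def test_separated_groups_strongly_flagged(self):
        groups = {"A": GroupLevels("A", "m", np.arange(10.0)),
                  "B": GroupLevels("B", "m", np.arange(10.0) + 100)}
        result = group_tests(groups)
        assert result.pairwise["q"].iloc[0] < 0.01

    def test_dunn_matches_hand_formula(self):
        rng = np.random.default_rng(0)
        samples = {"A": rng.uniform(0, 1, 6), "B": rng.uniform(0, 1, 5),
                   "C": rng.uniform(0.5, 1.5, 7)}
        frame = dunn_posthoc(samples)
        pooled = np.concatenate(list(samples.values()))
        ranks = stats.rankdata(pooled)
        n_total = pooled.size
        mean_rank, sizes, start = {}, {}, 0
        for k, v in samples.items():
            mean_rank[k] = ranks[start:start + v.size].mean()
            sizes[k] = v.size
            start += v.size
        var = n_total * (n_total + 1) / 12.0      # tie-free data
        row = frame[(frame.group1 == "A") & (frame.group2 == "C")].iloc[0]
        z = ((mean_rank["A"] - mean_rank["C"])
             / np.sqrt(var * (1 / sizes["A"] + 1 / sizes["C"])))
        assert row["dunn_z"] == pytest.approx(z, abs=1e-12)
        assert row["p"] == pytest.approx(2 * stats.norm.sf(abs(z)), abs=1e-12)

    def test_holm_q_dominates_p_and_is_monotone(self):
        rng = np.random.default_rng(1)
        samples = {k: rng.normal(i * 0.3, 1, 12)
                   for i, k in enumerate("ABCD")}
        frame = dunn_posthoc(samples)
        assert (frame["q"] >= frame["p"] - 1e-15).all()
        ordered = frame.sort_values("p")
        assert (np.diff(ordered["q"]) >= -1e-15).all()

    def test_identical_observations_degenerate(self):
        groups = {k: GroupLevels(k, "m", np.full(5, 2.0)) for k in "AB"}
        with pytest.raises(ValueError, match="identical"):
            group_tests(groups)

    def test_omnibus_type_i_error_controlled(self):
        """Three null groups: rejection rate at alpha=0.05 stays near
        nominal over 200 simulations."""
        rng = np.random.default_rng(42)
        rejections = 0
        n_sim = 200
        for _ in range(n_sim):
            groups = {k: GroupLevels(k, "m", rng.normal(0, 1, 15))
                      for k in "ABC"}
            if group_tests(groups).p_omnibus < 0.05:
                rejections += 1
        assert 0.025 <= rejections / n_sim <= 0.085
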