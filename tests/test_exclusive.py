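"""Quartile-cutoff status calling and exclusive-spectra extraction."""

import numpy as np
import pandas as pd
import pytest

from epiraman import exclusive, synth
from epiraman.containers import ClassMap, HyperspectralMap, WavenumberGrid
from epiraman.correlate import CorrelationMap
from epiraman.exclusive import STATUS_LABELS, call_status, extract_exclusive


def toy_corr_maps(score_rows: dict[str, np.ndarray], classmap: ClassMap
                  ) -> dict[str, CorrelationMap]:
    """Build correlation maps from per-label score rasters."""
    out = {}
    for lbl, raw in score_rows.items():
        raw = np.asarray(raw, dtype=float)
        span = raw.max() - raw.min()
        norm = (raw - raw.min()) / span if span else np.full_like(raw, 0.5)
        out[lbl] = CorrelationMap(lbl, "pearson", raw, norm,
                                  np.ones_like(raw, dtype=bool), (600, 1900))
    return out


@pytest.fixture()
def eight_pixel_setup():
    """8 nucleus pixels in a 2x4 raster with known scores per label."""
    labels = np.ones((2, 4), dtype=int)   # all nucleus
    classmap = ClassMap(labels)
    rng = np.random.default_rng(0)
    scores = {lbl: rng.uniform(0, 1, (2, 4)) for lbl in STATUS_LABELS}
    scores["DNA-m"] = np.array([[0.1, 0.2, 0.3, 0.4], [0.5, 0.6, 0.7, 0.8]])
    return classmap, scores


class TestCallStatus:
    def test_cutoff_matches_sort_based_oracle(self, eight_pixel_setup):
        classmap, scores = eight_pixel_setup
        status = call_status(toy_corr_maps(scores, classmap), classmap)
        values = np.sort(scores["DNA-m"].ravel())
        # linear-interpolation quantile: h = (n-1)*q
        h = (len(values) - 1) * 0.75
        lo, frac = int(np.floor(h)), h - np.floor(h)
        expected_cutoff = values[lo] + frac * (values[lo + 1] - values[lo])
        assert status.cutoffs["DNA-m"] == pytest.approx(expected_cutoff)
        expected_pos = int(np.sum(values >= expected_cutoff))
        assert status.table["DNA-m"].sum() == expected_pos

    def test_all_tied_scores_all_positive(self):
        classmap = ClassMap(np.ones((2, 2), dtype=int))
        scores = {lbl: np.full((2, 2), 0.5) for lbl in STATUS_LABELS}
        status = call_status(toy_corr_maps(scores, classmap), classmap)
        assert status.table[list(STATUS_LABELS)].to_numpy().min() == 1
        assert set(status.degenerate_labels) == set(STATUS_LABELS)

    def test_cutoff_over_nucleus_pixels_only(self):
        labels = np.array([[1, 1], [0, 2]])
        classmap = ClassMap(labels)
        scores = {lbl: np.array([[0.9, 0.8], [0.1, 0.2]])
                  for lbl in STATUS_LABELS}
        status = call_status(toy_corr_maps(scores, classmap), classmap)
        # only the two nucleus pixels enter the quantile
        assert status.n_pixels == 2
        assert status.cutoffs["DNA"] == pytest.approx(
            np.quantile([0.9, 0.8], 0.75))

    def test_no_nucleus_pixels_is_error(self):
        classmap = ClassMap(np.zeros((2, 2), dtype=int))
        scores = {lbl: np.ones((2, 2)) for lbl in STATUS_LABELS}
        with pytest.raises(ValueError, match="nucleus"):
            call_status(toy_corr_maps(scores, classmap), classmap)

    def test_rank_invariance_under_monotone_transform(self, eight_pixel_setup):
        classmap, scores = eight_pixel_setup
        status_a = call_status(toy_corr_maps(scores, classmap), classmap)
        warped = {lbl: np.exp(3.0 * s) for lbl, s in scores.items()}
        status_b = call_status(toy_corr_maps(warped, classmap), classmap)
        pd.testing.assert_frame_equal(status_a.table, status_b.table)

    def test_monotone_in_quantile(self, eight_pixel_setup):
        classmap, scores = eight_pixel_setup
        maps = toy_corr_maps(scores, classmap)
        sizes = []
        for q in (0.5, 0.75, 0.9):
            status = call_status(maps, classmap, quantile=q)
            sizes.append(len(extract_exclusive(status, "DNA-m")))
        assert sizes[0] >= sizes[1] >= sizes[2]


class TestExtractExclusive:
    def make_status(self, rows: list[dict]) -> exclusive.StatusTable:
        frame = pd.DataFrame(rows).fillna(0)
        for lbl in STATUS_LABELS:
            if lbl not in frame.columns:
                frame[lbl] = 0
        frame[list(STATUS_LABELS)] = frame[list(STATUS_LABELS)].astype(int)
        return exclusive.StatusTable(frame, {lbl: 0.5 for lbl in STATUS_LABELS},
                                     0.75)

    def test_membership_rule(self):
        status = self.make_status([
            {"x": 0, "y": 0, "Lys": 1, "Lys-a": 1},                  # member
            {"x": 1, "y": 0, "Lys": 1, "Lys-a": 1, "DNA-m": 1},      # excluded
            {"x": 2, "y": 0, "Lys": 0, "Lys-a": 1},                  # no base
            {"x": 3, "y": 0, "Lys": 1, "Lys-m": 1},                  # other mod
        ])
        members = extract_exclusive(status, "Lys-a").member_pixels
        np.testing.assert_array_equal(members, [[0, 0]])

    def test_matches_row_by_row_predicate_oracle(self, status_table):
        others = {"DNA-m": ["Lys-m", "Lys-a", "Arg-m"],
                  "Lys-a": ["DNA-m", "Lys-m", "Arg-m"]}
        for mod, rest in others.items():
            base = synth.BASE_OF[mod]
            got = {tuple(p) for p in
                   extract_exclusive(status_table, mod).member_pixels}
            expected = set()
            for _, row in status_table.table.iterrows():
                if (row[mod] == 1 and row[base] == 1
                        and all(row[o] == 0 for o in rest)):
                    expected.add((int(row["x"]), int(row["y"])))
            assert got == expected

    def test_exclusive_sets_pairwise_disjoint(self, status_table):
        sets = {m: {tuple(p) for p in
                    extract_exclusive(status_table, m).member_pixels}
                for m in synth.MODIFICATIONS}
        mods = list(sets)
        for i in range(len(mods)):
            for j in range(i + 1, len(mods)):
                assert not (sets[mods[i]] & sets[mods[j]])

    def test_empty_set_is_valid(self):
        status = self.make_status([{"x": 0, "y": 0, "Lys": 1}])
        result = extract_exclusive(status, "Arg-m")
        assert len(result) == 0

    def test_unknown_modification_rejected(self, status_table):
        with pytest.raises(ValueError, match="unknown"):
            extract_exclusive(status_table, "Ser-p")

    def test_spectra_attached_when_map_given(self, status_table, processed):
        hsmap, _ = processed
        result = extract_exclusive(status_table, "Lys-a", hsmap)
        assert result.spectra is not None
        assert result.spectra.shape == (len(result), len(hsmap.grid))


class TestOverlay:
    def make_level_map(self, norm: np.ndarray) -> CorrelationMap:
        return CorrelationMap("Lys-a", "pearson", norm.copy(), norm.copy(),
                              np.ones_like(norm, dtype=bool), (600, 1900))

    def base(self, shape=(2, 3)):
        rng = np.random.default_rng(0)
        return self.make_level_map(rng.uniform(0, 1, shape))

    def test_zero_level_fully_transparent(self):
        status = TestExtractExclusive().make_status(
            [{"x": 0, "y": 0, "Lys": 1, "Lys-a": 1}])
        levels = {"Lys-a": self.make_level_map(np.zeros((2, 3)))}
        overlay = exclusive.overlay_multiplex(self.base(), status, levels)
        assert np.all(overlay.alphas["Lys-a"] == 0)

    def test_single_positive_pixel(self):
        status = TestExtractExclusive().make_status(
            [{"x": 1, "y": 1, "Lys": 1, "Lys-a": 1},
             {"x": 0, "y": 0, "Lys": 1, "Lys-a": 0}])
        norm = np.full((2, 3), 0.7)
        overlay = exclusive.overlay_multiplex(
            self.base(), status, {"Lys-a": self.make_level_map(norm)})
        alpha = overlay.alphas["Lys-a"]
        assert alpha[1, 1] == 0.7
        assert np.count_nonzero(alpha) == 1

    def test_opacity_rank_equals_score_rank(self):
        rng = np.random.default_rng(5)
        norm = rng.uniform(0.1, 1.0, (2, 3))
        rows = [{"x": x, "y": y, "Lys": 1, "Lys-a": 1}
                for y in range(2) for x in range(3)]
        status = TestExtractExclusive().make_status(rows)
        overlay = exclusive.overlay_multiplex(
            self.base(), status, {"Lys-a": self.make_level_map(norm)})
        alpha = overlay.alphas["Lys-a"].ravel()
        np.testing.assert_array_equal(np.argsort(alpha),
                                      np.argsort(norm.ravel()))
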