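"""Similarity metrics, correlation heatmaps and the metric comparison."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from epiraman import correlate, synth
from epiraman.containers import HyperspectralMap, Spectrum, WavenumberGrid
from epiraman.correlate import METRICS, UndefinedCorrelationError
from epiraman.preprocess import normalize01

from conftest import small_scene_spec


@pytest.fixture()
def g16():
    return WavenumberGrid(np.arange(600.0, 632.0, 2.0))


class TestSimilarity:
    def test_self_correlation_is_one(self, references):
        s = references["DNA"].spectrum
        assert correlate.similarity(s, s, "pearson") == pytest.approx(1.0)
        assert correlate.similarity(s, s, "spearman") == pytest.approx(1.0)
        assert correlate.similarity(s, s, "cosine-squared") == pytest.approx(1.0)
        assert correlate.similarity(s, s, "euclidean-unit-norm") == pytest.approx(0.0)

    def test_pearson_affine_invariance(self, g16):
        rng = np.random.default_rng(1)
        a = Spectrum(g16, rng.uniform(0, 1, 16))
        b = Spectrum(g16, 3.5 * a.intensity + 2.0)
        assert correlate.similarity(a, b, "pearson") == pytest.approx(1.0)

    def test_pearson_matches_formula_oracle(self, g16):
        rng = np.random.default_rng(2)
        x = rng.uniform(0, 1, 16)
        y = rng.uniform(0, 1, 16)
        r = correlate.similarity(Spectrum(g16, x), Spectrum(g16, y))
        # direct covariance / sigma*sigma computation
        expected = (np.mean((x - x.mean()) * (y - y.mean()))
                    / (x.std() * y.std()))
        assert r == pytest.approx(expected, abs=1e-12)

    def test_spearman_matches_rank_oracle(self, g16):
        rng = np.random.default_rng(3)
        x = rng.uniform(0, 1, 16)
        y = rng.uniform(0, 1, 16)
        rho = correlate.similarity(Spectrum(g16, x), Spectrum(g16, y),
                                   "spearman")
        rx = np.argsort(np.argsort(x)).astype(float)
        ry = np.argsort(np.argsort(y)).astype(float)
        expected = (np.mean((rx - rx.mean()) * (ry - ry.mean()))
                    / (rx.std() * ry.std()))
        assert rho == pytest.approx(expected, abs=1e-12)

    def test_constant_input_undefined(self, g16):
        flat = Spectrum(g16, np.full(16, 2.0))
        varying = Spectrum(g16, np.arange(16.0))
        with pytest.raises(UndefinedCorrelationError):
            correlate.similarity(flat, varying, "pearson")

    def test_grid_mismatch_rejected(self, g16):
        other = WavenumberGrid(np.arange(600.0, 664.0, 4.0))
        with pytest.raises(ValueError, match="grid"):
            correlate.similarity(Spectrum(g16, np.arange(16.0)),
                                 Spectrum(other, np.arange(16.0)))


class TestCorrelationMap:
    def test_norm_scores_attain_bounds(self, corr_maps):
        cmap = corr_maps["DNA"]
        scores = cmap.norm_flat()
        assert scores.min() == 0.0 and scores.max() == 1.0

    def test_rank_order_matches_per_pixel_oracle(self, processed, references):
        hsmap, _ = processed
        cmap = correlate.correlation_map(hsmap, references["Lys"])
        # independent loop using the scalar similarity API
        from epiraman.spectral_io import common_window, resample_reference

        grid = common_window(hsmap.grid, references["Lys"].grid)
        ref = resample_reference(references["Lys"], grid).spectrum
        idx = np.searchsorted(hsmap.grid.values, grid.values)
        oracle = np.array([
            correlate.similarity(
                Spectrum(grid, row[idx]), ref, "pearson")
            for row in hsmap.intensities()[:200]])
        np.testing.assert_allclose(cmap.raw_flat()[:200], oracle, atol=1e-12)

    def test_noiseless_pure_dna_pixel_is_map_maximum(self, clean_rendered,
                                                     references, scene):
        hsmap, _ = clean_rendered
        cmap = correlate.correlation_map(hsmap, references["DNA"])
        nucleus = scene.regions == 1
        assert np.nanmax(cmap.norm[nucleus]) == 1.0

    def test_degenerate_map_flagged(self, g16, references):
        ref = synth.make_reference(
            synth.SpeciesModel("X", ((610, 6, 1.0),)), g16)
        row = np.sin(np.arange(16.0))
        cube = np.tile(row, (2, 2, 1))
        cmap = correlate.correlation_map(
            HyperspectralMap(g16, cube), ref, window=(600, 640))
        assert cmap.degenerate
        assert np.all(cmap.norm_flat() == 0.5)

    def test_monotone_in_mixing_coefficient(self, references, grid):
        """Raw Pearson against DNA rises with the DNA mixing coefficient
        when the other components are held fixed (noiseless pixels)."""
        dna = references["DNA"].intensity
        protein = synth.make_reference(
            synth.default_species()["Protein"], grid).intensity
        scores = []
        for coeff in np.linspace(0.1, 1.0, 8):
            pixel = Spectrum(grid, coeff * dna + 0.5 * protein)
            scores.append(correlate.similarity(
                pixel, references["DNA"].spectrum))
        assert np.all(np.diff(scores) > 0)

    @settings(deadline=None, max_examples=20)
    @given(st.integers(min_value=0, max_value=2**31 - 1))
    def test_pearson_invariant_under_normalize01(self, seed):
        rng = np.random.default_rng(seed)
        g = WavenumberGrid(np.arange(600.0, 664.0, 2.0))
        a = Spectrum(g, rng.uniform(0, 1, len(g)) + 1e-3 * np.arange(len(g)))
        b = Spectrum(g, rng.uniform(0, 1, len(g)))
        before = correlate.similarity(a, b)
        after = correlate.similarity(normalize01(a), b)
        assert after == pytest.approx(before, abs=1e-12)


class TestCompareMetrics:
    def test_five_rows_positive_separation_noiseless(self, clean_rendered,
                                                     references):
        hsmap, truth = clean_rendered
        table = correlate.compare_metrics(hsmap, references["DNA"], truth)
        assert len(table) == 5
        assert set(table["metric"]) == set(METRICS)
        assert (table["separation"] > 0).all()

    def test_pure_noise_map_has_no_contrast(self, references, rendered, grid):
        _, truth = rendered
        rng = np.random.default_rng(8)
        cube = rng.normal(0, 1, (truth.height, truth.width, len(grid)))
        noise_map = HyperspectralMap(grid, cube)
        table = correlate.compare_metrics(noise_map, references["DNA"], truth)
        assert np.all(np.abs(table["separation"]) < 0.05)
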