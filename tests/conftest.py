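"""Shared fixtures: one small rendered tissue scene and its analysis products.

Everything is generated programmatically at test time from the synthetic
module with fixed seeds; session scope keeps the expensive renders and the
one classifier training shared across test modules.
"""

from __future__ import annotations

import numpy as np
import pytest

from epiraman import classify, correlate, exclusive, preprocess, quantify, synth

REF_LABELS = ("DNA", "DNA-m", "Lys", "Lys-m", "Lys-a", "Arg", "Arg-m",
              "B-DNA", "Z-DNA")


@pytest.fixture(scope="session")
def grid():
    return synth.default_grid()


@pytest.fixture(scope="session")
def species():
    return synth.default_species()


@pytest.fixture(scope="session")
def references(species, grid):
    return {lbl: synth.make_reference(species[lbl], grid)
            for lbl in REF_LABELS}


def small_scene_spec(level: float = 0.4, z_level: float = 0.15,
                     group: str = "CTRL", **kw) -> synth.SceneSpec:
    defaults = dict(width=28, height=28, n_nuclei=3,
                    nucleus_radius=(2.5, 4.0), group_label=group,
                    truth={m: level for m in synth.MODIFICATIONS},
                    z_level=z_level)
    defaults.update(kw)
    return synth.SceneSpec(**defaults)


@pytest.fixture(scope="session")
def scene():
    return synth.make_scene(small_scene_spec(), seed=42)


@pytest.fixture(scope="session")
def rendered(scene, species, grid):
    """(noisy map, ground-truth class map) under default noise."""
    return synth.render_map(scene, species, synth.NoiseModel(seed=7), grid)


@pytest.fixture(scope="session")
def clean_rendered(scene, species, grid):
    """Noiseless twin of ``rendered`` (same scene, zero noise)."""
    return synth.render_map(scene, species, synth.quiet_noise(), grid)


@pytest.fixture(scope="session")
def processed(rendered):
    hsmap, _ = rendered
    out, reports = preprocess.preprocess_map(hsmap)
    return out, reports


@pytest.fixture(scope="session")
def corr_maps(processed, references):
    hsmap, _ = processed
    return {lbl: correlate.correlation_map(hsmap, references[lbl])
            for lbl in REF_LABELS}


@pytest.fixture(scope="session")
def status_table(corr_maps, rendered):
    _, classmap = rendered
    return exclusive.call_status(corr_maps, classmap)


@pytest.fixture(scope="session")
def trained_classifier(processed, rendered):
    """One classifier trained on the small scene (shared; ~10 s)."""
    hsmap, _ = processed
    _, classmap = rendered
    model, report = classify.train_classifier(
        hsmap.intensities(), classmap.flat(),
        classify.ClassifierSpec(seed=5))
    return model, report


def build_group_bundles(label: str, level: float, z_level: float, seed: int,
                        references, species, grid, n_maps: int = 3,
                        size: int = 32, n_nuclei: int = 5
                        ) -> list[quantify.MapBundle]:
    """Render, preprocess and score a group of maps with truth class maps."""
    bundles = []
    for i in range(n_maps):
        spec = small_scene_spec(level=level, z_level=z_level, group=label,
                                width=size, height=size, n_nuclei=n_nuclei,
                                nucleus_radius=(2.2, 3.4))
        sc = synth.make_scene(spec, seed=seed + i)
        hsmap, cm = synth.render_map(sc, species,
                                     synth.NoiseModel(seed=seed + 100 + i),
                                     grid)
        proc, _ = preprocess.preprocess_map(hsmap)
        corr = {lbl: correlate.correlation_map(proc, references[lbl])
                for lbl in REF_LABELS}
        bundles.append(quantify.MapBundle(corr, exclusive.call_status(corr, cm)))
    return bundles
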