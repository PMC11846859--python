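"""End-to-end pipeline driver and the synthetic demo corpus.

:func:`make_demo_corpus` writes a self-contained file tree — reference
spectra for the seven EM-analysis species plus the B-/Z-DNA conformers,
several simulated subtype groups with two maps each, ground-truth class maps
and a truth JSON — readable back through the package's text formats.

:func:`run_pipeline` chains every stage (preprocess, classify, correlate,
status calling, exclusive extraction, VSPA, quantification, embedding) from
a single config mapping, writes all numeric artifacts as CSV, and returns a
manifest of artifact paths with SHA-256 checksums; identical config and
seeds reproduce identical checksums.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import classify, correlate, exclusive, preprocess, quantify, vspa
from .containers import ClassMap, NUCLEUS
from .embed import pca_embed, tsne_embed
from .spectral_io import read_map, read_reference, write_map, write_reference
from .synth import (
    BASE_OF,
    MODIFICATIONS,
    NoiseModel,
    SceneSpec,
    default_grid,
    default_species,
    make_reference,
    make_scene,
    render_map,
)

__all__ = ["make_demo_corpus", "run_pipeline", "default_config",
           "PipelineConfigError"]

#: reference species shipped with the demo corpus
REFERENCE_LABELS = ("DNA", "DNA-m", "Lys", "Lys-m", "Lys-a", "Arg", "Arg-m",
                    "B-DNA", "Z-DNA")

#: demo subtype groups: modification truth levels and Z-DNA level
DEMO_GROUPS: dict[str, tuple[float, float]] = {
    "TUM-A": (0.8, 0.30),
    "TUM-B": (0.4, 0.15),
    "CTRL": (0.4, 0.15),
}


class PipelineConfigError(ValueError):
    """The config fails validation before any computation starts."""


def make_demo_corpus(out_dir: str | Path, seed: int = 0,
                     groups: dict[str, tuple[float, float]] | None = None,
                     maps_per_group: int = 2, size: int = 32,
                     n_nuclei: int = 5,
                     nucleus_radius: tuple[float, float] = (2.2, 3.4)) -> dict:
    """Write a synthetic corpus; returns its truth manifest."""
    out = Path(out_dir)
    (out / "references").mkdir(parents=True, exist_ok=True)
    (out / "maps").mkdir(exist_ok=True)
    (out / "labels").mkdir(exist_ok=True)
    groups = groups or DEMO_GROUPS
    grid = default_grid()
    species = default_species()
    for label in REFERENCE_LABELS:
        ref = make_reference(species[label], grid)
        write_reference(ref, out / "references" / f"{_slug(label)}.csv")

    rng = np.random.default_rng(seed)
    truth: dict = {"seed": int(seed), "groups": {}}
    for group, (level, z_level) in groups.items():
        truth["groups"][group] = {"levels": {m: level for m in MODIFICATIONS},
                                  "z_level": z_level, "maps": []}
        for i in range(maps_per_group):
            map_seed = int(rng.integers(0, 2**31 - 1))
            spec = SceneSpec(width=size, height=size, n_nuclei=n_nuclei,
                             nucleus_radius=nucleus_radius, group_label=group,
                             truth={m: level for m in MODIFICATIONS},
                             z_level=z_level)
            scene = make_scene(spec, seed=map_seed)
            noise = NoiseModel(seed=map_seed + 1)
            hsmap, classmap = render_map(scene, species, noise, grid)
            name = f"{_slug(group)}_{i}"
            write_map(hsmap, out / "maps" / f"{name}.csv")
            ys, xs = np.nonzero(classmap.mask)
            pd.DataFrame({"x": xs, "y": ys,
                          "label": classmap.labels[ys, xs]}).to_csv(
                out / "labels" / f"{name}.csv", index=False)
            truth["groups"][group]["maps"].append(
                {"name": name, "seed": map_seed})
    (out / "truth.json").write_text(json.dumps(truth, indent=1))
    return truth


def _slug(label: str) -> str:
    return label.replace("-", "_").replace("/", "_")


def default_config(corpus_dir: str | Path, output_dir: str | Path,
                   seed: int = 0) -> dict:
    return {
        "corpus_dir": str(corpus_dir),
        "output_dir": str(output_dir),
        "seed": int(seed),
        "ctrl_group": "CTRL",
        "preprocess": {"despike_threshold": 8.0, "baseline_degree": 3,
                       "autoencoder": {"enabled": False, "epochs": 42,
                                       "batch_size": 105,
                                       "loss": "crossentropy"}},
        "classify": {"n_train": 900, "min_epochs": 10, "max_epochs": 38,
                     "batch_size": 105},
        "correlate": {"metric": "pearson"},
        "exclusive": {"quantile": 0.75},
        "vspa": {"alpha": 0.01, "mode": "peaks", "modification": "Lys-a"},
        "quantify": {"modifications": list(MODIFICATIONS), "enabled": True},
        "embed": {"k": 2, "perplexity": 20.0, "max_spectra": 400},
    }


def _validate(config: dict, truth: dict) -> None:
    for key in ("corpus_dir", "output_dir", "seed"):
        if key not in config:
            raise PipelineConfigError(f"config missing required key {key!r}")
    if config["exclusive"]["quantile"] <= 0 or config["exclusive"]["quantile"] >= 1:
        raise PipelineConfigError("exclusive.quantile must lie in (0, 1)")
    if config["correlate"]["metric"] not in correlate.METRICS:
        raise PipelineConfigError(
            f"unknown metric {config['correlate']['metric']!r}")
    if config["vspa"]["modification"] not in BASE_OF:
        raise PipelineConfigError(
            f"unknown VSPA modification {config['vspa']['modification']!r}")
    if (config["quantify"].get("enabled", True)
            and config["ctrl_group"] not in truth["groups"]):
        raise PipelineConfigError(
            f"quantify enabled but control group {config['ctrl_group']!r} "
            "is absent from the corpus")


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _save(frame: pd.DataFrame, path: Path, manifest: dict) -> None:
    frame.to_csv(path, index=False, float_format="%.8g")
    manifest["artifacts"][str(path)] = _sha256(path)


def run_pipeline(config: dict) -> dict:
    """Run every stage on a corpus tree; returns the run manifest."""
    corpus = Path(config["corpus_dir"])
    out = Path(config["output_dir"])
    out.mkdir(parents=True, exist_ok=True)
    truth = json.loads((corpus / "truth.json").read_text())
    _validate(config, truth)
    seed = int(config["seed"])
    manifest: dict = {"artifacts": {}, "log": [], "seed": seed}
    log = manifest["log"].append
    log(f"defaults in effect: metric={config['correlate']['metric']}, "
        f"quantile={config['exclusive']['quantile']}, "
        f"alpha={config['vspa']['alpha']}")

    references = {ref.label: ref for ref in
                  (read_reference(p) for p in
                   sorted((corpus / "references").glob("*.csv")))}

    # ---- load + preprocess -------------------------------------------------
    maps, truth_classes, groups_of = {}, {}, {}
    for group, ginfo in truth["groups"].items():
        for entry in ginfo["maps"]:
            name = entry["name"]
            hsmap = read_map(corpus / "maps" / f"{name}.csv")
            frame = pd.read_csv(corpus / "labels" / f"{name}.csv")
            labels = np.zeros((hsmap.height, hsmap.width), dtype=int)
            labels[frame["y"], frame["x"]] = frame["label"]
            truth_classes[name] = ClassMap(labels, hsmap.mask.copy())
            pcfg = config["preprocess"]
            processed, _ = preprocess.preprocess_map(
                hsmap, despike_threshold=pcfg["despike_threshold"],
                baseline_degree=pcfg["baseline_degree"])
            maps[name] = processed
            groups_of[name] = group
    log(f"loaded and preprocessed {len(maps)} maps")

    # ---- classifier --------------------------------------------------------
    ccfg = config["classify"]
    x_all = np.concatenate([maps[n].intensities() for n in maps])
    y_all = np.concatenate([truth_classes[n].flat() for n in maps])
    rng = np.random.default_rng(seed)
    pick = rng.choice(x_all.shape[0], size=min(ccfg["n_train"],
                                               x_all.shape[0]), replace=False)
    spec = classify.ClassifierSpec(seed=seed, batch_size=ccfg["batch_size"],
                                   min_epochs=ccfg["min_epochs"],
                                   max_epochs=ccfg["max_epochs"])
    model, report = classify.train_classifier(x_all[pick], y_all[pick], spec)
    log(f"classifier held-out accuracy {report.validation_accuracy:.3f} "
        f"({report.epochs_run} epochs)")
    classmaps = {}
    for name, hsmap in maps.items():
        cm = classify.predict_map(model, hsmap)
        classmaps[name] = cm
        ys, xs = np.nonzero(cm.mask)
        _save(pd.DataFrame({"x": xs, "y": ys, "label": cm.labels[ys, xs]}),
              out / f"classmap_{name}.csv", manifest)

    # ---- correlation + status ---------------------------------------------
    metric = config["correlate"]["metric"]
    bundles: dict[str, quantify.MapBundle] = {}
    for name, hsmap in maps.items():
        corr = {lbl: correlate.correlation_map(hsmap, references[lbl], metric)
                for lbl in REFERENCE_LABELS}
        frames = []
        for lbl in REFERENCE_LABELS:
            ys, xs = np.nonzero(corr[lbl].mask)
            frames.append(pd.DataFrame({
                "x": xs, "y": ys, "reference": lbl,
                "raw": corr[lbl].raw[ys, xs], "norm": corr[lbl].norm[ys, xs]}))
        _save(pd.concat(frames, ignore_index=True),
              out / f"scores_{name}.csv", manifest)
        status = exclusive.call_status(corr, classmaps[name],
                                       quantile=config["exclusive"]["quantile"])
        _save(status.table, out / f"status_{name}.csv", manifest)
        bundles[name] = quantify.MapBundle(corr, status)

    # ---- exclusive sets + VSPA ---------------------------------------------
    mod = config["vspa"]["modification"]
    base = BASE_OF[mod]
    mod_spectra, base_spectra = [], []
    counts = []
    for name, hsmap in maps.items():
        status = bundles[name].status
        for m in MODIFICATIONS:
            excl = exclusive.extract_exclusive(status, m, hsmap)
            counts.append({"map": name, "modification": m, "n": len(excl)})
            if m == mod and len(excl):
                mod_spectra.append(excl.spectra)
        t = status.table
        keep = t[base] == 1
        for other in MODIFICATIONS:
            keep &= t[other] == 0
        members = t.loc[keep, ["x", "y"]].to_numpy(int)
        if members.size:
            base_spectra.append(
                np.stack([hsmap.cube[y, x] for x, y in members]))
    _save(pd.DataFrame(counts), out / "exclusive_counts.csv", manifest)

    grid = next(iter(maps.values())).grid
    if mod_spectra and base_spectra:
        a = np.concatenate(mod_spectra)
        b = np.concatenate(base_spectra)
        if a.shape[0] >= 3 and b.shape[0] >= 3:
            result = vspa.volcano(a, b, grid, alpha=config["vspa"]["alpha"],
                                  mode=config["vspa"]["mode"])
            _save(vspa.significant_peaks_plot(result),
                  out / f"vspa_{_slug(mod)}.csv", manifest)
            log(f"VSPA {mod} vs exclusive {base}: "
                f"{int(result.significant.sum())} significant of "
                f"{result.positions.size} positions")
        else:
            log(f"VSPA skipped: exclusive sets too small "
                f"({a.shape[0]} vs {b.shape[0]})")
    else:
        log("VSPA skipped: empty exclusive sets")

    # ---- quantification ----------------------------------------------------
    if config["quantify"].get("enabled", True):
        ctrl = config["ctrl_group"]
        by_group: dict[str, list[quantify.MapBundle]] = {}
        for name, bundle in bundles.items():
            by_group.setdefault(groups_of[name], []).append(bundle)
        level_rows, test_rows = [], []
        for m in config["quantify"]["modifications"]:
            levels = quantify.collect_levels(by_group, m)
            rel = quantify.relative_levels(levels, ctrl_label=ctrl)
            for r in rel.values():
                level_rows.append({"group": r.group_label, "modification": m,
                                   "n": r.n,
                                   "median": levels[r.group_label].level(),
                                   "iqr": r.dispersion,
                                   "ratio_to_ctrl": r.ratio_to_ctrl})
            tests = quantify.group_tests(levels)
            for _, row in tests.pairwise.iterrows():
                test_rows.append({"modification": m, **row.to_dict(),
                                  "h": tests.h_statistic,
                                  "p_omnibus": tests.p_omnibus})
        _save(pd.DataFrame(level_rows), out / "levels.csv", manifest)
        _save(pd.DataFrame(test_rows), out / "tests.csv", manifest)
        z_levels = quantify.collect_levels(by_group, "Z-DNA")
        b_levels = quantify.collect_levels(by_group, "B-DNA")
        zscores = quantify.zdna_score(z_levels, b_levels, ctrl_label=ctrl)
        _save(pd.DataFrame([{"group": s.group_label, "zdna_score": s.score,
                             "n": s.n} for s in zscores.values()]),
              out / "zdna_scores.csv", manifest)

    # ---- embedding ---------------------------------------------------------
    ecfg = config["embed"]
    pool_x, pool_g = [], []
    for name, bundle in bundles.items():
        t = bundle.status.table
        keep = t["DNA"] == 1
        members = t.loc[keep, ["x", "y"]].to_numpy(int)
        if members.size:
            pool_x.append(np.stack([maps[name].cube[y, x]
                                    for x, y in members]))
            pool_g.extend([groups_of[name]] * members.shape[0])
    if pool_x:
        x = np.concatenate(pool_x)
        g = np.array(pool_g)
        if x.shape[0] > ecfg["max_spectra"]:
            pick = np.random.default_rng(seed + 7).choice(
                x.shape[0], ecfg["max_spectra"], replace=False)
            x, g = x[pick], g[pick]
        pca = pca_embed(x, g, k=ecfg["k"], grid=grid)
        _save(pca.to_frame(), out / "pca_scores.csv", manifest)
        _save(pca.group_medians(), out / "pca_group_medians.csv", manifest)
        perp = min(ecfg["perplexity"], (x.shape[0] - 2) / 3.0)
        tsne = tsne_embed(x, g, perplexity=perp, seed=seed)
        _save(tsne.to_frame(), out / "tsne_scores.csv", manifest)

    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return manifest
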