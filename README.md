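# epiraman

Spatial recognition and semi-quantification of epigenetic modifications and
Z-/B-DNA conformation in Raman hyperspectral tissue maps.

## What problem this solves

Raman hyperspectral mapping (RHM) records a full vibrational spectrum at every
pixel of a tissue section (maps of 10,000–18,000 spectra over the fingerprint
region, 600–1900 cm⁻¹ at ~2 cm⁻¹ resolution). Because DNA methylation
(DNA-m), histone lysine methylation/acetylation (Lys-m, Lys-a), arginine
methylation (Arg-m) and the B→Z DNA conformational switch each leave
characteristic spectral signatures, such maps can in principle report the
epigenetic state of individual cell nuclei — label-free and in place. This
package implements the complete analysis chain that turns a raw hyperspectral
map plus a small library of reference spectra into per-nucleus modification
calls and group-level "level relative to control" estimates. It is aimed at
vibrational-spectroscopy and computational-pathology groups who want a
tested, scriptable implementation of this workflow, together with a synthetic
tissue-map generator with known ground truth for validating every stage.

## The method

1. **Preprocessing** — cosmic-ray despiking (modified z-score on first
   differences with a single-bin sharpness check), 3rd-order polynomial
   baseline removal against the signal floor, optional denoising by a 1-D
   convolutional autoencoder (9-convolution encoder, 9-convolution decoder,
   flat sigmoidal output; Adam, batch 105, 42 epochs), then min–max
   normalization of every spectrum to [0, 1].
2. **Tissue classification** — a 10-convolution / 4-dense network assigns
   each pixel spectrum to stroma/empty (0), nucleus (1) or cytoplasm (2);
   70/30 train/validation split, categorical cross-entropy, batch 105.
3. **Correlation heatmaps** — every pixel spectrum *s* is scored against a
   reference *r* with Pearson's R = cov(s, r)/(σ_s σ_r) (Spearman, squared
   cosine, squared first-difference cosine and unit-normalized Euclidean
   distance are available for comparison); per-map scores are min–max
   normalized to [0, 1].
4. **Status calling and exclusive spectra** — within classifier-identified
   nuclei, a pixel is *positive* for a species when its Pearson score reaches
   that species' 3rd quartile (Q3, the 0.75 quantile over nucleus pixels);
   the *exclusive* spectra of a modification are the pixels positive for the
   modification and its base species (DNA, Lys or Arg) and negative for all
   other modifications.
5. **VSPA** — volcano-plot spectral peak analysis: per peak position,
   log₂(mean_A/mean_B) fold change with a two-sided Mann–Whitney U p-value,
   flagged at p < 0.01.
6. **Semi-quantification** — a group's level of a modification is the median
   Pearson score over base-positive nucleus spectra, reported as a ratio to
   the control group (control ≡ 1). The Z-DNA score is the group's Z/B level
   ratio relative to control (control ≡ 1.00). Groups are compared with
   Kruskal–Wallis H followed by Dunn's post hoc z-tests, Holm-adjusted.
7. **Group structure** — PCA (scores, loadings, per-group medians) and
   t-SNE of DNA-positive nucleus spectra.

Because no public tissue maps are available, the `synth` module generates
hyperspectral scenes with nucleus/cytoplasm/stroma architecture, Lorentzian
reference species, per-nucleus modification heterogeneity, polynomial
baselines, Gaussian noise and cosmic-ray spikes — with the ground truth
(class raster, mixing coefficients, modification levels) retained so every
pipeline stage can be tested for recovery.

## Worked example

```bash
epiraman demo --out demo --seed 3
```

generates a synthetic corpus (three groups — TUM-A with truth modification
level 0.8 and doubled Z-DNA, TUM-B and CTRL with level 0.4 — two 32×32 maps
each, plus the nine reference spectra) and runs the whole pipeline on it.
The log prints

```
defaults in effect: metric=pearson, quantile=0.75, alpha=0.01
loaded and preprocessed 6 maps
classifier held-out accuracy 1.000 (15 epochs)
VSPA Lys-a vs exclusive Lys: 0 significant of 17 positions
```

and `demo/results/levels.csv` holds the group levels, e.g. for Lys-a:

```
group,modification,n,median,iqr,ratio_to_ctrl
TUM-A,Lys-a,65,0.41625768,0.051410297,1.1729431
TUM-B,Lys-a,66,0.3510013,0.06328943,0.98906174
CTRL,Lys-a,60,0.3548831,0.035540633,1
```

TUM-A (generated at truth level 0.8) comes out ~17% above control while
TUM-B (generated at the control level 0.4) sits at ~0.99 — the generator's
ordering is recovered. `tests.csv` shows the corresponding Dunn/Holm
comparisons (TUM-A vs CTRL at q ≈ 7·10⁻¹², TUM-B vs CTRL non-significant),
and `zdna_scores.csv` gives the relative Z-DNA scores (TUM-A 1.049 with its
doubled Z-DNA mixing, TUM-B 1.001, CTRL exactly 1). The exclusive-set counts,
correlation score tables, class maps, VSPA table and PCA/t-SNE embeddings are
written alongside, with SHA-256 checksums in `manifest.json`; rerunning with
the same seed reproduces identical checksums.

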