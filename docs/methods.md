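# Methods

This note documents the models and procedures implemented in `epiraman`, the
parameter defaults and why they were chosen, what the synthetic-data
generator does and does not emulate, and the package's known limitations.

## Data model

A `HyperspectralMap` stores per-pixel spectra as a dense
`(height, width, n_wavenumbers)` cube with a boolean occupancy mask.
Coordinates are 0-based integer pixel indices, `x` = column, `y` = row,
origin top-left; the physical pixel pitch (µm) is metadata only. All spectra
of a map share one strictly ascending wavenumber grid; grids are sorted on
load regardless of file order. The normative on-disk formats are delimited
UTF-8 text (wide and long map tables, two-column reference files with a
`# label:` header). Analyses run on the *common fingerprint window*: the
intersection of the map grid and all reference ranges, clipped to
600–1900 cm⁻¹. References measured on a different grid are brought onto the
map grid by linear interpolation — monotone and ringing-free at sharp Raman
bands, which is why no higher-order scheme is used — and never extrapolated.

## Preprocessing

Order is fixed: despike → baseline → (optional) autoencoder → normalize01.

**Despiking.** Candidate bins come from a modified z-score
(0.6745·(d−median)/MAD) on the first differences, threshold 8. A candidate is
confirmed as a cosmic-ray spike only if both of its flanking differences are
at least twice the largest difference just outside them: a single-bin spike
rises and falls within one bin, while a genuine Raman band ~5 bins wide at
2 cm⁻¹ sampling has comparable slopes one bin further out. Confirmed bins
are replaced by linear interpolation of the surrounding good bins. The
sharpness confirmation matters on low-noise spectra, where the MAD is small
enough that band apexes would otherwise exceed any fixed z threshold.

**Baseline.** A degree-3 polynomial is fitted to the signal floor by
iterative reweighting: after each least-squares fit, points above the fitted
curve are clipped down onto it and the fit repeats (≤50 iterations,
tolerance 10⁻⁸ of the signal scale). Plain least squares would track the
peaks; the clipping iteration converges to the smooth background beneath
them. A spectrum that *is* a cubic polynomial is removed to numerical zero.

**Autoencoder.** The denoiser is a 1-D convolutional autoencoder: 9 encoder
convolutions (channels 8→32, kernels 7→3, max-pooling to a length-5
bottleneck), 9 decoder convolutions with nearest-neighbour upsampling, and a
flat dense sigmoidal output layer mapping back to the full grid length. Only
the layer counts and the training protocol (Adam, batch size 105, 42 epochs,
glorot-uniform initialization) are fixed by the reproduced protocol; the
channel/kernel plan is this package's choice, sized for ~650-point spectra.
The default loss is elementwise cross-entropy on [0, 1]-scaled intensities
(the natural reading of a "categorical cross-entropy" objective on a sigmoid
reconstruction head — a softmax over wavenumber bins would not reconstruct
intensities); mean-squared error is available via
`AutoencoderSpec(loss="mse")`. Inputs must be scaled to [0, 1] before
training. Note the optimization budget is measured in *steps*: at batch 105,
42 epochs on a few hundred spectra is only ~100 updates and underfits, while
on map-sized corpora (≥~900 spectra) the same 42 epochs denoise strongly.
Every training API takes an explicit integer seed; there is no hidden
global state, and training is bit-reproducible on one thread.

**Normalization.** Min–max to [0, 1] per spectrum. Constant spectra are
degenerate: the scalar API raises, the map pipeline flags the pixel
`excluded` and zeroes it. Pearson scoring downstream is invariant to this
affine rescaling (asserted in the tests).

## Tissue classifier

A 10-convolution / 4-dense softmax network (channels 8→48, dense
256→64→16→3; again only the layer counts and training settings are fixed by
the protocol, the widths are ours). Training shuffles with the seed, splits
70/30, one-hot encodes, and runs Adam with categorical cross-entropy, batch
105, early stopping on validation loss (patience 5) inside a 10–38 epoch
band, restoring the best-validation weights. Softmax ties resolve to the
lowest class index. Both corpus-level training (default, used by the
pipeline) and per-map training are possible by choice of the input set. The
networks run on a minimal pure-numpy engine (`epiraman.nn`: same-padded
conv1d, max-pool, upsample, dense, Adam) written for this package; gradient
correctness is verified against finite differences in the test suite.

## Correlation scoring

Five metrics: Pearson R (pipeline default), Spearman ρ, squared cosine,
squared first-difference cosine, unit-normalized Euclidean distance.
Distances are sign-flipped before the per-map min–max normalization so a
higher normalized score always means more similar; a map with identical raw
scores everywhere is flagged degenerate and set to 0.5. Normalization is
computed over all occupied pixels (not nuclei only), which is the documented
choice where the original workflow is silent. The metric-comparison step —
originally a visual inspection — is operationalized as the
nucleus/non-nucleus contrast of mean normalized scores against a DNA
reference on ground-truth classes, so it is testable.

## Status calling and exclusive spectra

Per species, the cutoff is the 0.75 quantile (linear interpolation between
order statistics — pinned for reproducibility) of raw Pearson scores over
nucleus pixels only, per map; score ≥ cutoff counts positive (ties positive,
pinned). The same rule covers all seven species including the bases. The
0.75 default reflects the reproduced protocol's tested range (0.50–0.95,
with 0.75 retained). Because the linear-interpolation quantile and the ≥
comparison depend only on ranks, status tables are invariant under any
strictly increasing transform of the scores. Exclusive sets (positive for
one modification and its base, negative for the other three modifications)
are pairwise disjoint by construction and shrink monotonically as the
quantile rises.

## VSPA

"Peak" positions default to local maxima of the pooled mean spectrum with
relative prominence ≥ 5% of its range (the original text does not define
the tested positions); an exhaustive per-wavenumber mode exists for
sensitivity analyses. Fold change is group_a over group_b (group_a = the
modified set), log₂-transformed; positions where either group mean is
non-positive are excluded and logged. The Mann–Whitney U test enumerates
the exact null for tie-free groups with both n ≤ 12 and otherwise uses the
midrank normal approximation with tie correction. No multiple-testing
correction is applied by default, matching the raw p < 0.01 rule;
Benjamini–Hochberg is available behind `adjust=True`.

## Semi-quantification and statistics

"Level" = median of per-spectrum Pearson scores (mean behind a flag) over
nucleus pixels positive for the modification's base species; spectra, not
patients or nuclei, are the analysis unit. Ratios to control are medians of
pooled scores, so the control's own ratio is exactly 1; the Z-DNA score is
(Z/B)/(Z/B)_control with both Z and B levels taken over DNA-positive nucleus
pixels for comparability. Group testing is Kruskal–Wallis H with tie
correction, then Dunn's pairwise z-tests with the pooled-rank variance and
tie term, Holm-adjusted over the full pairwise family *per modification*
(one family per panel, not pooled across modifications). Dunn/Holm is
implemented in-package (rank-mean z statistic; Holm via statsmodels) and
cross-checked against the closed-form formulas in the tests.

## Embeddings

PCA runs on mean-centered, unscaled spectra (intensities share units);
loadings, explained-variance fractions and per-group median scores are
reported. t-SNE uses perplexity 30 (clipped to (n−2)/3 when the pool is
small), 1000 iterations, PCA initialization, and is reproducible for a
fixed seed. The embedded pool is the DNA-positive nucleus spectra, the same
base-positive rule as quantification.

## Synthetic-data generator

Reference species are sums of Lorentzian peaks (Gaussian available) on the
600–1900 cm⁻¹ grid, min–max scaled; peak positions are loosely inspired by
common Raman assignments, and each modified species shares ≥ 50% of its
peak centers with its base while differing in ≥ 2 peaks, so base/modified
pairs are similar but distinguishable (Pearson R between them falls in
(0.3, 0.99)). Scenes place irregular connected nucleus blobs (Gaussian
bumps at rejection-sampled centers plus a smoothed random field,
thresholded; a scene too small for the requested nuclei raises a layout
error), surround them with cytoplasm and fill the rest with stroma. Mixing
coefficients are nonnegative: nuclei carry DNA, Lys, Arg, B-DNA and a
little protein; modified-species coefficients are
`truth_level × base_coefficient × per-nucleus factor × U(0.6, 1)`, where
the per-nucleus factor (U(0.15, 1) per modification) models cell-to-cell
epigenetic heterogeneity — the structure that makes exclusive-spectra
extraction meaningful. Z-DNA scales the same way off the B-DNA coefficient
via the scene's `z_level`. Rendering adds a per-pixel cubic baseline (drawn
coefficients are logged), Gaussian noise (default SD 0.02 on ~unit-height
signals) and Poisson-count single-bin spikes of ≥ 5× the pixel's maximum
signal (default rate 0.02/spectrum, height 6×, logged per bin) — isolated
single-bin spikes keep despiking unambiguous and auditable. Fixed seeds make
the corpus byte-reproducible.

What the generator does **not** emulate: physical Raman cross-sections,
instrument response and wavelength-dependent sensitivity, fluorescence
photobleaching kinetics, spatial autocorrelation of noise, water/paraffin
backgrounds, or realistic overlap between dozens of tissue biomolecules.
Passing recovery tests therefore demonstrates that the *pipeline logic* is
correct and sensitive at realistic noise levels, not that the biological
effect sizes on real tissue are reproduced.

## Problem sizes and numerical choices

Tests and the acceptance script use deliberately scaled-down scenes chosen
to exercise every code path at desk scale: 28–40-pixel-square maps
(~800–1,600 spectra) for unit tests, 32×32 three-map groups for the 20-seed
recovery studies, and five 80×80 maps (6,400 spectra each) for the
classifier-accuracy figure, versus the 10,000–18,000-spectra maps of the
original acquisitions (one 100×100 render is tested to anchor that scale).
Quantile estimation uses linear interpolation; the despike threshold is 8;
classifier and autoencoder learning rates are Adam defaults (10⁻³); float32
arithmetic is used inside the network engine. Where an algorithmic detail
was genuinely open (despike rule, baseline estimator, peak definition,
normalization pool, Holm family, per-map vs corpus training), the choice
made is stated above and pinned by a test.

## Limitations

- Correlation against references is not spectral unmixing; strongly
  co-varying species (e.g. DNA vs DNA-m, which share most bands) yield
  correlated scores, and the ratio-to-control contrasts for such pairs are
  correspondingly compressed.
- Multi-positive nucleus spectra are discarded by design (exclusivity), so
  co-occurring modifications at one pixel are not quantified.
- Treating spectra as the analysis unit inflates effective sample sizes
  relative to patients; the per-nucleus aggregation mode exists to probe
  this pseudo-replication but is not the default.
- The network engine is single-threaded CPU numpy: adequate for desk-scale
  corpora, not for training on many full-size maps at once.
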