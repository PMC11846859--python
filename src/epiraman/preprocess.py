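"""Spectral preprocessing: despiking, baseline removal, autoencoder denoising
and 0-1 normalization.

The pipeline order is fixed as despike -> baseline -> (optional) autoencoder
denoise -> normalize01, and every step is recorded in a
:class:`PreprocessReport` per spectrum.

Baseline removal fits a 3rd-order polynomial to the signal floor by iterative
reweighting: after each least-squares fit, points above the fitted curve are
pulled down onto it, so the polynomial converges to the smooth background
under the peaks rather than tracking them.

Cosmic-ray despiking uses a modified z-score (median/MAD) on the first
differences of the spectrum.  A single-bin spike produces one strongly
positive and one strongly negative consecutive difference, a signature that
genuine Raman bands (several bins wide at 2 cm^-1 resolution) never show;
flagged bins are replaced by linear interpolation of their neighbours.

The denoiser is a 1-D convolutional autoencoder — a 9-convolution encoder
compressing the spectrum to a short bottleneck and a 9-convolution decoder,
closed by a flat sigmoidal output layer mapping back to the full grid —
trained with Adam on [0, 1]-scaled spectra (elementwise cross-entropy loss by
default, mean-squared error behind a switch).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import nn
from .containers import (
    DegenerateInputError,
    HyperspectralMap,
    SchemaError,
    Spectrum,
)

__all__ = [
    "PreprocessReport",
    "AutoencoderSpec",
    "DenoiserModel",
    "remove_baseline",
    "remove_spikes",
    "normalize01",
    "train_autoencoder",
    "denoise",
    "preprocess_map",
]


@dataclass
class PreprocessReport:
    """Audit trail of the preprocessing applied to one spectrum."""

    n_spikes_removed: int = 0
    baseline_rms: float = 0.0
    denoise_applied: bool = False
    excluded: bool = False          # constant spectrum, dropped from analysis


# ---------------------------------------------------------------------------
# baseline


def _baseline_matrix(y: np.ndarray, degree: int = 3, max_iter: int = 50,
                     tol: float = 1e-8) -> np.ndarray:
    """Iterative polynomial floor fit, vectorized over rows of ``y``."""
    n, length = y.shape
    t = np.linspace(-1.0, 1.0, length)
    vand = np.vander(t, degree + 1, increasing=True)
    pinv = np.linalg.pinv(vand)
    work = y.copy()
    scale = max(np.abs(y).max(), 1e-12)
    fit = work
    for _ in range(max_iter):
        fit = (pinv @ work.T).T @ vand.T
        clipped = np.minimum(work, fit)
        if np.max(np.abs(clipped - work)) < tol * scale:
            work = clipped
            break
        work = clipped
    return fit


def remove_baseline(spectrum: Spectrum, degree: int = 3
                    ) -> tuple[Spectrum, Spectrum]:
    """Subtract a degree-3 polynomial signal floor; returns (corrected,
    baseline)."""
    y = spectrum.intensity
    if y.size < degree + 5:
        raise DegenerateInputError(
            f"baseline fit needs >= {degree + 5} points, got {y.size}")
    baseline = _baseline_matrix(y[None, :], degree=degree)[0]
    return (Spectrum(spectrum.grid, y - baseline),
            Spectrum(spectrum.grid, baseline))


# ---------------------------------------------------------------------------
# despiking


def _spike_bins(y: np.ndarray, threshold: float) -> np.ndarray:
    """Single-bin outliers: modified z-score candidates on the first
    differences, confirmed by a sharpness check against the neighbouring
    differences (a genuine band several bins wide has comparable flank
    slopes just outside the apex; a cosmic-ray bin does not)."""
    d = np.diff(y)
    med = np.median(d)
    mad = np.median(np.abs(d - med))
    if mad == 0:
        mad = np.mean(np.abs(d - med)) or 1e-300
    mz = 0.6745 * (d - med) / mad
    up = mz > threshold      # d[i] = y[i+1] - y[i] large positive
    down = mz < -threshold

    def outer(i: int) -> float:
        left_out = abs(d[i - 2]) if i >= 2 else 0.0
        right_out = abs(d[i + 1]) if i + 1 < d.size else 0.0
        return max(left_out, right_out)

    bins = [i for i in np.flatnonzero(up[:-1] & down[1:]) + 1
            if min(d[i - 1], -d[i]) >= 2.0 * outer(i)]
    if down.size > 1 and down[0] and -d[0] >= 2.0 * abs(d[1]):
        bins.append(0)
    if up.size > 1 and up[-1] and d[-1] >= 2.0 * abs(d[-2]):
        bins.append(y.size - 1)
    return np.unique(np.array(bins, dtype=int))


def remove_spikes(spectrum: Spectrum, threshold: float = 8.0
                  ) -> tuple[Spectrum, int]:
    """Replace single-bin cosmic-ray spikes by neighbour interpolation."""
    y = spectrum.intensity.copy()
    if y.size < 3:
        return spectrum, 0
    bins = _spike_bins(y, threshold)
    if bins.size == 0:
        return spectrum, 0
    good = np.setdiff1d(np.arange(y.size), bins)
    y[bins] = np.interp(bins.astype(float), good.astype(float), y[good])
    return Spectrum(spectrum.grid, y), int(bins.size)


# ---------------------------------------------------------------------------
# normalization


def normalize01(spectrum: Spectrum) -> Spectrum:
    """Min-max scale to [0, 1]; constant spectra are degenerate."""
    y = spectrum.intensity
    lo, hi = y.min(), y.max()
    if hi == lo:
        raise DegenerateInputError("constant spectrum cannot be normalized")
    return Spectrum(spectrum.grid, (y - lo) / (hi - lo))


# ---------------------------------------------------------------------------
# autoencoder denoiser


@dataclass(frozen=True)
class AutoencoderSpec:
    """Training configuration of the convolutional denoising autoencoder.

    Architecture is fixed at 9 encoder and 9 decoder convolutions plus the
    flat sigmoidal output layer; the channel plan below is this package's
    choice (the architecture source fixes only the layer counts).
    """

    epochs: int = 42
    batch_size: int = 105
    loss: str = "crossentropy"    # elementwise CE on [0,1]; or "mse"
    learning_rate: float = 1e-3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.loss not in ("crossentropy", "mse"):
            raise ValueError("loss must be 'crossentropy' or 'mse'")


def _autoencoder_layers(length: int) -> list[nn.Layer]:
    enc_plan = [(8, 7, True), (8, 7, True), (16, 5, True), (16, 5, True),
                (16, 5, True), (24, 3, True), (24, 3, False), (32, 3, False),
                (32, 3, True)]
    layers: list[nn.Layer] = []
    for filters, kernel, pool in enc_plan:
        layers.append(nn.Conv1D(filters, kernel))
        if pool:
            layers.append(nn.MaxPool1D(2))
    dec_plan = [(32, 3, True), (24, 3, True), (24, 3, True), (16, 3, True),
                (16, 5, True), (8, 5, True), (8, 7, True), (8, 7, False),
                (4, 7, False)]
    for filters, kernel, up in dec_plan:
        if up:
            layers.append(nn.Upsample1D(2))
        layers.append(nn.Conv1D(filters, kernel))
    layers.append(nn.Flatten())
    layers.append(nn.Dense(length, activation="linear"))  # sigmoid in loss
    return layers


@dataclass
class DenoiserModel:
    """A trained denoising autoencoder bound to one grid length."""

    net: nn.Sequential
    length: int
    spec: AutoencoderSpec
    history: dict = field(default_factory=dict)

    def transform(self, matrix: np.ndarray) -> np.ndarray:
        matrix = np.asarray(matrix, dtype=float)
        if matrix.ndim != 2 or matrix.shape[1] != self.length:
            raise SchemaError(
                f"denoiser expects (n, {self.length}) spectra, got "
                f"{matrix.shape}")
        return self.net.predict(matrix[:, :, None], loss=self.spec.loss)


def _as_matrix(spectra) -> np.ndarray:
    if isinstance(spectra, np.ndarray):
        return np.asarray(spectra, dtype=float)
    rows = [s.intensity for s in spectra]
    lengths = {r.size for r in rows}
    if len(lengths) != 1:
        raise SchemaError("spectra of unequal length")
    return np.stack(rows)


def train_autoencoder(spectra, spec: AutoencoderSpec | None = None
                      ) -> DenoiserModel:
    """Train the denoiser on [0, 1]-scaled spectra on one common grid."""
    spec = spec or AutoencoderSpec()
    x = _as_matrix(spectra)
    if x.shape[0] < spec.batch_size:
        raise ValueError(
            f"need >= batch_size={spec.batch_size} spectra, got {x.shape[0]}")
    if x.min() < -1e-9 or x.max() > 1 + 1e-9:
        raise ValueError("spectra must be scaled to [0, 1] before training")
    length = x.shape[1]
    net = nn.Sequential(_autoencoder_layers(length), input_shape=(length, 1),
                        seed=spec.seed)
    history = net.fit(x[:, :, None], x, loss=spec.loss, epochs=spec.epochs,
                      batch_size=spec.batch_size, lr=spec.learning_rate)
    return DenoiserModel(net, length, spec, history)


def denoise(model: DenoiserModel, spectrum: Spectrum) -> Spectrum:
    """Pass one spectrum through the autoencoder; output lies in [0, 1]."""
    if spectrum.intensity.size != model.length:
        raise SchemaError(
            f"spectrum length {spectrum.intensity.size} != training length "
            f"{model.length}")
    out = model.transform(spectrum.intensity[None, :])[0]
    return Spectrum(spectrum.grid, out)


# ---------------------------------------------------------------------------
# map-level pipeline


def preprocess_map(hsmap: HyperspectralMap, *, despike: bool = True,
                   baseline: bool = True, denoiser: DenoiserModel | None = None,
                   normalize: bool = True, despike_threshold: float = 8.0,
                   baseline_degree: int = 3
                   ) -> tuple[HyperspectralMap, list[PreprocessReport]]:
    """Apply the full chain to every occupied pixel of a map.

    Constant spectra (which cannot be normalized or correlated) are flagged
    ``excluded`` in their report and zeroed.  Returns the processed map and
    one report per pixel in row-major order.
    """
    x = hsmap.intensities()
    n = x.shape[0]
    reports = [PreprocessReport() for _ in range(n)]
    if despike:
        for i in range(n):
            spec, removed = remove_spikes(
                Spectrum(hsmap.grid, x[i]), threshold=despike_threshold)
            x[i] = spec.intensity
            reports[i].n_spikes_removed = removed
    if baseline:
        base = _baseline_matrix(x, degree=baseline_degree)
        x = x - base
        rms = np.sqrt(np.mean(base**2, axis=1))
        for i in range(n):
            reports[i].baseline_rms = float(rms[i])
    if denoiser is not None:
        # autoencoder expects [0,1] inputs; scale, denoise, keep [0,1]
        lo = x.min(axis=1, keepdims=True)
        hi = x.max(axis=1, keepdims=True)
        flat = (hi - lo)[:, 0] == 0
        span = np.where(hi - lo == 0, 1.0, hi - lo)
        x = denoiser.transform((x - lo) / span)
        for i in range(n):
            reports[i].denoise_applied = True
            if flat[i]:
                reports[i].excluded = True
    if normalize:
        lo = x.min(axis=1, keepdims=True)
        hi = x.max(axis=1, keepdims=True)
        flat = (hi - lo)[:, 0] == 0
        span = np.where(hi - lo == 0, 1.0, hi - lo)
        x = (x - lo) / span
        for i in np.flatnonzero(flat):
            reports[i].excluded = True
            x[i] = 0.0
    return hsmap.with_intensities(x), reports
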