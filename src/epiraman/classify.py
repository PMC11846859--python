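"""Convolutional tissue-class classifier for per-pixel Raman spectra.

A 10-convolution / 4-dense network assigns each preprocessed pixel spectrum
to stroma/empty (0), nucleus (1) or cytoplasm (2).  Training uses one-hot
labels, a seeded shuffle with a 70/30 train/validation split, Adam with
categorical cross-entropy, batch size 105, and early stopping on validation
loss (patience 5) within a 10-38 epoch band.  Channel widths taper 8 -> 48
across the convolutions and 256 -> 64 -> 16 -> 3 across the dense layers;
these widths are this package's choice — only the layer counts and training
settings are fixed by the protocol being reproduced.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.metrics import precision_recall_fscore_support

from . import nn
from .containers import (
    ClassMap,
    CLASS_NAMES,
    HyperspectralMap,
    SchemaError,
)

__all__ = [
    "ClassifierSpec",
    "TrainingReport",
    "ClassifierModel",
    "train_classifier",
    "predict_map",
    "render_class_image",
    "labels_from_image",
    "DEFAULT_PALETTE",
]

#: raster palette: nucleus green, cytoplasm red, stroma/other yellow
DEFAULT_PALETTE: dict[int, tuple[int, int, int]] = {
    0: (255, 255, 0),
    1: (0, 200, 0),
    2: (220, 0, 0),
}


@dataclass(frozen=True)
class ClassifierSpec:
    """Architecture and training settings of the tissue classifier."""

    conv_filters: tuple[int, ...] = (8, 8, 16, 16, 24, 24, 32, 32, 48, 48)
    conv_kernels: tuple[int, ...] = (7, 7, 5, 5, 5, 3, 3, 3, 3, 3)
    pool_after: tuple[int, ...] = (0, 1, 2, 3, 4, 6, 8)   # conv indices
    dense_units: tuple[int, ...] = (256, 64, 16)
    classes: int = 3
    batch_size: int = 105
    min_epochs: int = 10
    max_epochs: int = 38
    patience: int = 5
    test_fraction: float = 0.3
    learning_rate: float = 1e-3
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.conv_filters) != 10 or len(self.conv_kernels) != 10:
            raise ValueError("the classifier uses exactly 10 convolutions")
        if len(self.dense_units) != 3:
            raise ValueError("the classifier uses 4 dense layers "
                             "(3 hidden + softmax output)")


@dataclass
class TrainingReport:
    validation_accuracy: float
    epochs_run: int
    precision: np.ndarray       # per class
    recall: np.ndarray
    n_train: int
    n_test: int
    history: dict = field(default_factory=dict)


@dataclass
class ClassifierModel:
    net: nn.Sequential
    length: int
    spec: ClassifierSpec

    def predict_proba(self, matrix: np.ndarray) -> np.ndarray:
        matrix = np.asarray(matrix, dtype=float)
        if matrix.ndim != 2 or matrix.shape[1] != self.length:
            raise SchemaError(
                f"classifier expects (n, {self.length}) spectra, got "
                f"{matrix.shape}")
        return self.net.predict(matrix[:, :, None],
                                loss="categorical_crossentropy")

    def predict(self, matrix: np.ndarray) -> np.ndarray:
        # argmax takes the lowest index on exact softmax ties
        return self.predict_proba(matrix).argmax(axis=1)


def _build_net(length: int, spec: ClassifierSpec) -> nn.Sequential:
    layers: list[nn.Layer] = []
    for i, (f, k) in enumerate(zip(spec.conv_filters, spec.conv_kernels)):
        layers.append(nn.Conv1D(f, k))
        if i in spec.pool_after:
            layers.append(nn.MaxPool1D(2))
    layers.append(nn.Flatten())
    for units in spec.dense_units:
        layers.append(nn.Dense(units, activation="relu"))
    layers.append(nn.Dense(spec.classes, activation="linear"))  # softmax in loss
    return nn.Sequential(layers, input_shape=(length, 1), seed=spec.seed)


def train_classifier(spectra, labels, spec: ClassifierSpec | None = None
                     ) -> tuple[ClassifierModel, TrainingReport]:
    """Train on labeled spectra; returns the model and its held-out report.

    ``spectra`` is an ``(n, length)`` matrix (or list of
    :class:`~epiraman.containers.Spectrum`), ``labels`` integer classes in
    {0, 1, 2}.  All three classes must be present.
    """
    spec = spec or ClassifierSpec()
    if not isinstance(spectra, np.ndarray):
        spectra = np.stack([s.intensity for s in spectra])
    x = np.asarray(spectra, dtype=float)
    y = np.asarray(labels, dtype=int)
    if x.ndim != 2 or x.shape[0] != y.shape[0]:
        raise SchemaError("spectra matrix and labels are inconsistent")
    for cls in range(spec.classes):
        if not np.any(y == cls):
            raise ValueError(
                f"class {cls} ({CLASS_NAMES.get(cls, '?')}) absent from "
                "training data")
    if x.shape[0] < spec.batch_size:
        raise ValueError(
            f"need >= batch_size={spec.batch_size} samples, got {x.shape[0]}")

    rng = np.random.default_rng(spec.seed)
    perm = rng.permutation(x.shape[0])
    x, y = x[perm], y[perm]
    n_test = int(round(spec.test_fraction * x.shape[0]))
    x_test, y_test = x[:n_test], y[:n_test]
    x_train, y_train = x[n_test:], y[n_test:]
    onehot = np.eye(spec.classes)
    net = _build_net(x.shape[1], spec)
    history = net.fit(
        x_train[:, :, None], onehot[y_train],
        loss="categorical_crossentropy", epochs=spec.max_epochs,
        batch_size=spec.batch_size, lr=spec.learning_rate,
        validation_data=(x_test[:, :, None], onehot[y_test]),
        min_epochs=spec.min_epochs, patience=spec.patience)

    model = ClassifierModel(net, x.shape[1], spec)
    pred = model.predict(x_test)
    accuracy = float(np.mean(pred == y_test))
    precision, recall, _, _ = precision_recall_fscore_support(
        y_test, pred, labels=list(range(spec.classes)), zero_division=0.0)
    report = TrainingReport(accuracy, history["epochs_run"], precision,
                            recall, x_train.shape[0], n_test, history)
    return model, report


def predict_map(model: ClassifierModel, hsmap: HyperspectralMap) -> ClassMap:
    """Label every occupied pixel of a preprocessed map."""
    if len(hsmap.grid) != model.length:
        raise SchemaError(
            f"map grid length {len(hsmap.grid)} != classifier length "
            f"{model.length}")
    labels = np.zeros((hsmap.height, hsmap.width), dtype=int)
    labels[hsmap.mask] = model.predict(hsmap.intensities())
    return ClassMap(labels, hsmap.mask.copy())


def render_class_image(classmap: ClassMap,
                       palette: dict[int, tuple[int, int, int]] | None = None
                       ) -> np.ndarray:
    """RGB uint8 raster of a class map (nucleus green, cytoplasm red,
    stroma yellow by default)."""
    palette = palette or DEFAULT_PALETTE
    img = np.zeros((classmap.height, classmap.width, 3), dtype=np.uint8)
    for label, color in palette.items():
        img[classmap.labels == label] = color
    return img


def labels_from_image(image: np.ndarray,
                      palette: dict[int, tuple[int, int, int]] | None = None
                      ) -> np.ndarray:
    """Invert :func:`render_class_image` (exact palette colors only)."""
    palette = palette or DEFAULT_PALETTE
    labels = np.full(image.shape[:2], -1, dtype=int)
    for label, color in palette.items():
        labels[np.all(image == np.array(color, dtype=np.uint8), axis=-1)] = label
    if (labels < 0).any():
        raise ValueError("image contains colors outside the palette")
    return labels
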