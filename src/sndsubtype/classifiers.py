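"""Dense and convolutional subtype classifiers with the shared protocol:
shuffled 70/30 train/test split, an optional 10% held-out validation set
drawn first, and pooled multi-dataset training.

The dense network (DNN) is a standard multilayer perceptron fitted with
scikit-learn's ``MLPClassifier`` (SGD + momentum, cross-entropy via
softmax output). The convolutional network (CDNN) is the 5-layer stack
in :mod:`sndsubtype._convnet`: two convolutions, one max-pool
subsampling layer, one dense layer and one softmax output layer.

Default dense hyperparameters mirror the full-transcriptome setting
(hidden layers 760 and 120, learning rate 0.005, 2 epochs × 5 iteration
passes); for small synthetic cohorts pass an explicitly smaller spec —
the input size always follows the data.
"""

from __future__ import annotations

import pickle
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
from sklearn.neural_network import MLPClassifier

from ._convnet import ConvNet
from .errors import ArgumentError, ModelFormatError
from .image_embed import SampleImage
from .io_formats import ExpressionTable, LabelTable
from .snd import SNDMatrix

__all__ = [
    "DNNSpec",
    "CDNNSpec",
    "SplitSpec",
    "TrainedModel",
    "split_dataset",
    "train_dnn",
    "train_cdnn",
    "predict",
    "save_model",
    "load_model",
]

_MODEL_MAGIC = "snd-model"
_MODEL_VERSION = 1


@dataclass(frozen=True)
class DNNSpec:
    """Dense network hyperparameters.

    ``iterations`` multiplies ``epochs`` into total passes over the data
    (the optimizer framework the defaults come from counted the two
    separately). ``dropout`` is retained for config compatibility; the
    dense backend supports only 0.
    """

    hidden_sizes: tuple[int, ...] = (760, 120)
    learning_rate: float = 0.005
    epochs: int = 2
    iterations: int = 5
    dropout: float = 0.0
    momentum: float = 0.9
    activation: str = "relu"
    batch_size: int = 32
    seed: int = 0

    def __post_init__(self) -> None:
        if self.epochs < 1 or self.iterations < 1:
            raise ArgumentError("epochs and iterations must be >= 1")
        if not (0 <= self.dropout < 1):
            raise ArgumentError("dropout must lie in [0, 1)")
        if self.dropout > 0:
            raise ArgumentError("the dense backend does not implement dropout > 0")
        if not (0 <= self.momentum < 1):
            raise ArgumentError("momentum must lie in [0, 1)")
        if self.learning_rate <= 0:
            raise ArgumentError("learning rate must be positive")


@dataclass(frozen=True)
class CDNNSpec:
    """Convolutional network hyperparameters: (kernel, channels) per conv
    layer, pooling (window, stride), dense width, learning schedule."""

    conv_layers: tuple[tuple[int, int], ...] = ((5, 16), (3, 32))
    pool: tuple[int, int] = (2, 2)
    dense_size: int = 120
    learning_rate: float = 0.02
    epochs: int = 60
    momentum: float = 0.9
    batch_size: int = 32
    seed: int = 0

    def __post_init__(self) -> None:
        if self.epochs < 1:
            raise ArgumentError("epochs must be >= 1")
        if self.learning_rate <= 0:
            raise ArgumentError("learning rate must be positive")
        if len(self.conv_layers) != 2:
            raise ArgumentError("the 5-layer pattern uses exactly 2 conv layers")


@dataclass(frozen=True)
class SplitSpec:
    """Validation-first, then 70/30 train/test on the remainder."""

    validate_fraction: float = 0.10
    train_fraction_of_remainder: float = 0.70
    seed: int = 0
    stratified: bool = False

    def __post_init__(self) -> None:
        if not (0 <= self.validate_fraction < 1):
            raise ArgumentError("validate_fraction must lie in [0, 1)")
        if not (0 < self.train_fraction_of_remainder < 1):
            raise ArgumentError("train fraction must lie in (0, 1)")


@dataclass
class TrainedModel:
    """A fitted classifier plus everything needed to reuse it."""

    kind: str  # "dnn" | "cdnn"
    spec: DNNSpec | CDNNSpec
    class_order: tuple[str, ...]
    backend: object
    n_features: int  # flat feature count (dnn) or image side (cdnn)
    training_log: list = field(default_factory=list)


def _partition(ids: list[str], n_val: int, n_train: int) -> tuple[list, list, list]:
    val = ids[:n_val]
    train = ids[n_val : n_val + n_train]
    test = ids[n_val + n_train :]
    return train, test, val


def split_dataset(
    sample_ids: Sequence[str],
    labels: LabelTable | None,
    spec: SplitSpec,
) -> tuple[list[str], list[str], list[str]]:
    """Shuffle and partition sample IDs into (train, test, validate).

    The validation set (default 10%) is removed first, then the remainder
    is split 70/30. Sizes use round-half-up of the fractions. Stratified
    mode shuffles and partitions within each class, keeping proportions
    within ±1 sample per class.
    """
    ids = list(sample_ids)
    n = len(ids)
    if n == 0:
        raise ArgumentError("no samples to split")
    rng = np.random.default_rng(spec.seed)

    def sizes(count: int) -> tuple[int, int]:
        n_val = int(np.floor(spec.validate_fraction * count + 0.5))
        rem = count - n_val
        n_train = int(np.floor(spec.train_fraction_of_remainder * rem + 0.5))
        return n_val, n_train

    if not spec.stratified:
        perm = [ids[i] for i in rng.permutation(n)]
        n_val, n_train = sizes(n)
        return _partition(perm, n_val, n_train)

    if labels is None:
        raise ArgumentError("stratified splitting requires labels")
    mapping = labels.as_mapping()
    missing = [s for s in ids if s not in mapping]
    if missing:
        raise ArgumentError(f"unlabelled samples: {missing[:5]}")
    by_class: dict[str, list[str]] = {}
    for s in ids:
        by_class.setdefault(mapping[s], []).append(s)
    if n < 3 * len(by_class):
        raise ArgumentError(
            "stratified splitting needs at least 3 samples per class on average"
        )
    train: list[str] = []
    test: list[str] = []
    val: list[str] = []
    for cls in sorted(by_class):
        members = by_class[cls]
        perm = [members[i] for i in rng.permutation(len(members))]
        n_val, n_train = sizes(len(members))
        tr, te, va = _partition(perm, n_val, n_train)
        train += tr
        test += te
        val += va
    return train, test, val


def _features_and_labels(
    features: SNDMatrix | ExpressionTable,
    labels: LabelTable,
) -> tuple[np.ndarray, np.ndarray, tuple[str, ...], list[str]]:
    if isinstance(features, SNDMatrix):
        sample_ids, values = features.sample_ids, features.values
    elif isinstance(features, ExpressionTable):
        sample_ids, values = features.sample_ids, features.values
    else:
        raise ArgumentError(
            f"features must be an SNDMatrix or ExpressionTable, got {type(features)}"
        )
    mapping = labels.as_mapping()
    missing = [s for s in sample_ids if s not in mapping]
    if missing:
        raise ArgumentError(f"unlabelled training samples: {missing[:5]}")
    class_order = tuple(sorted(set(mapping[s] for s in sample_ids)))
    if len(class_order) < 2:
        raise ArgumentError("training set contains a single class")
    lut = {c: i for i, c in enumerate(class_order)}
    y = np.array([lut[mapping[s]] for s in sample_ids], dtype=int)
    return values.T.copy(), y, class_order, list(sample_ids)


def train_dnn(
    features: SNDMatrix | ExpressionTable,
    labels: LabelTable,
    spec: DNNSpec = DNNSpec(),
) -> TrainedModel:
    """Fit the dense network on gene features (samples = columns)."""
    x, y, class_order, _ = _features_and_labels(features, labels)
    total_epochs = spec.epochs * spec.iterations
    clf = MLPClassifier(
        hidden_layer_sizes=spec.hidden_sizes,
        activation=spec.activation,
        solver="sgd",
        learning_rate_init=spec.learning_rate,
        momentum=spec.momentum,
        nesterovs_momentum=False,
        batch_size=min(spec.batch_size, len(y)),
        max_iter=total_epochs,
        shuffle=True,
        random_state=spec.seed,
        alpha=0.0,
        tol=0.0,
        n_iter_no_change=total_epochs,
        learning_rate="constant",
    )
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # convergence warnings at small epoch counts
        clf.fit(x, y)
    log = [
        {"epoch": i + 1, "loss": float(l)} for i, l in enumerate(clf.loss_curve_)
    ]
    return TrainedModel(kind="dnn", spec=spec, class_order=class_order,
                        backend=clf, n_features=x.shape[1], training_log=log)


def _images_array(images) -> np.ndarray:
    if isinstance(images, np.ndarray):
        arr = images
    else:
        imgs = list(images)
        if not imgs:
            raise ArgumentError("no images provided")
        if isinstance(imgs[0], SampleImage):
            sides = {im.side for im in imgs}
            if len(sides) != 1:
                raise ArgumentError(f"inconsistent image sides: {sorted(sides)}")
            arr = np.stack([im.pixels for im in imgs])
        else:
            arr = np.stack([np.asarray(im, dtype=float) for im in imgs])
    if arr.ndim != 3 or arr.shape[1] != arr.shape[2]:
        raise ArgumentError(f"expected (n, side, side) images, got {arr.shape}")
    return np.asarray(arr, dtype=float)


def train_cdnn(
    images,
    labels: LabelTable,
    sample_ids: Sequence[str] | None = None,
    spec: CDNNSpec = CDNNSpec(),
) -> TrainedModel:
    """Fit the convolutional network on per-sample expression images.

    ``images`` is a list of :class:`SampleImage` or an (n, side, side)
    array; ``sample_ids`` gives the label-table key per image (defaults to
    the label table's own order when omitted and sizes match).
    """
    arr = _images_array(images)
    if sample_ids is None:
        if len(arr) != len(labels):
            raise ArgumentError(
                "sample_ids is required when image count differs from label count"
            )
        sample_ids = list(labels.sample_ids)
    mapping = labels.as_mapping()
    missing = [s for s in sample_ids if s not in mapping]
    if missing:
        raise ArgumentError(f"unlabelled training samples: {missing[:5]}")
    class_order = tuple(sorted(set(mapping[s] for s in sample_ids)))
    if len(class_order) < 2:
        raise ArgumentError("training set contains a single class")
    lut = {c: i for i, c in enumerate(class_order)}
    y = np.array([lut[mapping[s]] for s in sample_ids], dtype=int)
    net = ConvNet(
        side=arr.shape[1],
        n_classes=len(class_order),
        conv_layers=spec.conv_layers,
        pool=spec.pool,
        dense_size=spec.dense_size,
        seed=spec.seed,
    )
    log = net.fit(arr, y, epochs=spec.epochs, learning_rate=spec.learning_rate,
                  momentum=spec.momentum, batch_size=spec.batch_size)
    return TrainedModel(kind="cdnn", spec=spec, class_order=class_order,
                        backend=net, n_features=arr.shape[1], training_log=log)


def predict(model: TrainedModel, features) -> tuple[list[str], np.ndarray]:
    """Per-sample (argmax label, probability vector over class_order).

    Ties in the probability vector resolve to the earliest class in
    ``class_order`` (numpy argmax convention on the ordered classes).
    """
    if model.kind == "dnn":
        if isinstance(features, (SNDMatrix, ExpressionTable)):
            x = features.values.T
        else:
            x = np.asarray(features, dtype=float)
        if x.ndim != 2 or x.shape[1] != model.n_features:
            raise ArgumentError(
                f"expected {model.n_features} features per sample, received "
                f"{x.shape[1] if x.ndim == 2 else x.shape}"
            )
        proba = model.backend.predict_proba(x)
    elif model.kind == "cdnn":
        arr = _images_array(features)
        if arr.shape[1] != model.n_features:
            raise ArgumentError(
                f"expected image side {model.n_features}, received {arr.shape[1]}"
            )
        proba = model.backend.predict_proba(arr)
    else:
        raise ModelFormatError(f"unknown model kind {model.kind!r}")
    idx = proba.argmax(axis=1)
    return [model.class_order[i] for i in idx], proba


def accuracy(model: TrainedModel, features, labels: LabelTable,
             sample_ids: Sequence[str] | None = None) -> float:
    """Fraction of samples whose argmax label matches the label table."""
    if sample_ids is None:
        if isinstance(features, (SNDMatrix, ExpressionTable)):
            sample_ids = features.sample_ids
        else:
            sample_ids = list(labels.sample_ids)
    pred, _ = predict(model, features)
    mapping = labels.as_mapping()
    return float(np.mean([p == mapping[s] for p, s in zip(pred, sample_ids)]))


def save_model(model: TrainedModel, path: str | Path) -> None:
    payload = {
        "magic": _MODEL_MAGIC,
        "version": _MODEL_VERSION,
        "kind": model.kind,
        "spec": asdict(model.spec),
        "class_order": list(model.class_order),
        "n_features": model.n_features,
        "training_log": model.training_log,
        "backend": model.backend,
    }
    with Path(path).open("wb") as fh:
        pickle.dump(payload, fh)


def load_model(path: str | Path, kind: str | None = None) -> TrainedModel:
    """Load a saved model; ``kind`` (``"dnn"``/``"cdnn"``) enforces the type."""
    try:
        with Path(path).open("rb") as fh:
            payload = pickle.load(fh)
    except (pickle.UnpicklingError, EOFError, AttributeError) as exc:
        raise ModelFormatError(f"{path}: not a readable model file: {exc}") from exc
    if not isinstance(payload, dict) or payload.get("magic") != _MODEL_MAGIC:
        raise ModelFormatError(f"{path}: not a {_MODEL_MAGIC} file")
    if payload.get("version") != _MODEL_VERSION:
        raise ModelFormatError(
            f"{path}: model version {payload.get('version')!r} is not "
            f"supported (expected {_MODEL_VERSION})"
        )
    if kind is not None and payload["kind"] != kind:
        raise ModelFormatError(
            f"{path}: file holds a {payload['kind']} model, not {kind}"
        )
    spec_cls = DNNSpec if payload["kind"] == "dnn" else CDNNSpec
    raw_spec = dict(payload["spec"])
    if "hidden_sizes" in raw_spec:
        raw_spec["hidden_sizes"] = tuple(raw_spec["hidden_sizes"])
    if "conv_layers" in raw_spec:
        raw_spec["conv_layers"] = tuple(tuple(t) for t in raw_spec["conv_layers"])
    if "pool" in raw_spec:
        raw_spec["pool"] = tuple(raw_spec["pool"])
    return TrainedModel(
        kind=payload["kind"],
        spec=spec_cls(**raw_spec),
        class_order=tuple(payload["class_order"]),
        backend=payload["backend"],
        n_features=payload["n_features"],
        training_log=payload["training_log"],
    )
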