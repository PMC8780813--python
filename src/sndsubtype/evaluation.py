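"""Confusion matrices, per-subtype accuracies, inter-labeling consistency
and multi-model aggregate statistics.

Per-subtype accuracy is the row-normalized diagonal of the confusion
matrix: of the samples truly labelled PN, the fraction the model also
called PN. Accuracies are kept at full precision internally and rounded
to two decimals only for presentation. Aggregate SDs use the sample
(n − 1) convention.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from sklearn.metrics import confusion_matrix as _sk_confusion

from .errors import ArgumentError
from .io_formats import LabelTable

__all__ = [
    "ConfusionMatrix",
    "SubtypeAccuracyReport",
    "AggregateStats",
    "ConsistencyReport",
    "confusion",
    "per_subtype_accuracy",
    "consistency_between_labelings",
    "aggregate_accuracy_stats",
    "multi_model_report",
    "MultiModelReport",
]


@dataclass(frozen=True)
class ConfusionMatrix:
    """Counts of true label (rows) × predicted label (columns)."""

    class_order: tuple[str, ...]
    counts: np.ndarray

    def __post_init__(self) -> None:
        c = np.asarray(self.counts, dtype=int)
        k = len(self.class_order)
        if c.shape != (k, k):
            raise ArgumentError(f"counts shape {c.shape} != ({k}, {k})")
        if np.any(c < 0):
            raise ArgumentError("negative counts")
        object.__setattr__(self, "counts", c)
        object.__setattr__(self, "class_order", tuple(self.class_order))

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def permuted(self, new_order: Sequence[str]) -> "ConfusionMatrix":
        if sorted(new_order) != sorted(self.class_order):
            raise ArgumentError("new order must be a permutation of class_order")
        idx = [self.class_order.index(c) for c in new_order]
        return ConfusionMatrix(tuple(new_order), self.counts[np.ix_(idx, idx)])


@dataclass(frozen=True)
class SubtypeAccuracyReport:
    """Per-class accuracies in percent; classes with no samples are None."""

    per_class: dict[str, float | None]
    overall: float
    n_per_class: dict[str, int]

    def rounded(self) -> dict[str, float | None]:
        return {
            c: (None if v is None else round(v, 2))
            for c, v in self.per_class.items()
        }


@dataclass(frozen=True)
class AggregateStats:
    """Mean and sample SD (n − 1) of a list of percent accuracies."""

    values: tuple[float, ...]
    mean: float
    sd: float


@dataclass(frozen=True)
class ConsistencyReport:
    """Agreement between two labelings of the same samples.

    Per-class values are conditional on the *first* labeling: among
    samples the first study called class c, the percentage the second
    study also called c.
    """

    common_sample_count: int
    overall_consistency: float
    per_class_consistency: dict[str, float | None]


def _as_mapping(labels) -> dict[str, str]:
    if isinstance(labels, LabelTable):
        return labels.as_mapping()
    if isinstance(labels, Mapping):
        return dict(labels)
    raise ArgumentError("labels must be a LabelTable or a sample→label mapping")


def confusion(
    true_labels: LabelTable | Mapping[str, str],
    predicted: Mapping[str, str] | Sequence[str],
    class_order: Sequence[str] | None = None,
) -> ConfusionMatrix:
    """Cross-tabulate true vs predicted labels over the shared samples.

    ``predicted`` is a sample→label mapping, or a sequence aligned with
    the true-label table's sample order. Samples present in only one
    input raise, listing the offending IDs.
    """
    truth = _as_mapping(true_labels)
    if isinstance(predicted, Mapping):
        pred = dict(predicted)
    else:
        if not isinstance(true_labels, LabelTable):
            raise ArgumentError(
                "sequence predictions require a LabelTable to define sample order"
            )
        if len(predicted) != len(true_labels):
            raise ArgumentError(
                f"{len(predicted)} predictions for {len(true_labels)} samples"
            )
        pred = dict(zip(true_labels.sample_ids, predicted))
    only_truth = sorted(set(truth) - set(pred))
    only_pred = sorted(set(pred) - set(truth))
    if only_truth or only_pred:
        raise ArgumentError(
            f"sample sets differ; only in truth: {only_truth[:5]}, "
            f"only in predictions: {only_pred[:5]}"
        )
    if not truth:
        raise ArgumentError("no samples to tabulate")
    samples = list(truth)
    if class_order is None:
        class_order = tuple(sorted(set(truth.values()) | set(pred.values())))
    y_true = [truth[s] for s in samples]
    y_pred = [pred[s] for s in samples]
    counts = _sk_confusion(y_true, y_pred, labels=list(class_order))
    return ConfusionMatrix(tuple(class_order), counts)


def per_subtype_accuracy(cm: ConfusionMatrix) -> SubtypeAccuracyReport:
    """Row-normalized diagonal in percent, plus the overall percentage.

    The worked example: a true-PN row classified (PN, NE, CL, ME) =
    (52, 1, 0, 4) times gives PN accuracy 52/57 = 91.23%.
    """
    if cm.total == 0:
        raise ArgumentError("empty confusion matrix")
    row_sums = cm.counts.sum(axis=1)
    per_class: dict[str, float | None] = {}
    n_per_class: dict[str, int] = {}
    for i, c in enumerate(cm.class_order):
        n_per_class[c] = int(row_sums[i])
        per_class[c] = (
            None if row_sums[i] == 0
            else 100.0 * cm.counts[i, i] / row_sums[i]
        )
    overall = 100.0 * np.trace(cm.counts) / cm.total
    return SubtypeAccuracyReport(per_class=per_class, overall=float(overall),
                                 n_per_class=n_per_class)


def consistency_between_labelings(
    a: LabelTable | Mapping[str, str],
    b: LabelTable | Mapping[str, str],
) -> ConsistencyReport:
    """Agreement of two independent labelings on their common samples."""
    ma, mb = _as_mapping(a), _as_mapping(b)
    common = [s for s in ma if s in mb]
    if not common:
        raise ArgumentError("the two labelings share no samples")
    agree = [s for s in common if ma[s] == mb[s]]
    classes = sorted({ma[s] for s in common})
    per_class: dict[str, float | None] = {}
    for c in classes:
        members = [s for s in common if ma[s] == c]
        per_class[c] = (
            100.0 * sum(mb[s] == c for s in members) / len(members)
            if members else None
        )
    return ConsistencyReport(
        common_sample_count=len(common),
        overall_consistency=100.0 * len(agree) / len(common),
        per_class_consistency=per_class,
    )


def aggregate_accuracy_stats(values: Sequence[float]) -> AggregateStats:
    """Arithmetic mean and sample SD (ddof=1) of percent accuracies."""
    vals = tuple(float(v) for v in values)
    if len(vals) < 2:
        raise ArgumentError("need at least 2 values for mean and SD")
    arr = np.asarray(vals)
    return AggregateStats(values=vals, mean=float(arr.mean()),
                          sd=float(arr.std(ddof=1)))


@dataclass(frozen=True)
class MultiModelReport:
    """Per-dataset × per-model reports plus model-averaged per-class accuracy."""

    class_order: tuple[str, ...]
    reports: tuple[tuple[SubtypeAccuracyReport, ...], ...]  # [dataset][model]
    model_averaged_per_class: dict[str, float]
    between_model_sd_per_class: dict[str, float | None]
    weakest_class: str


def multi_model_report(models, datasets) -> MultiModelReport:
    """Evaluate every model on every (features, labels, sample_ids) dataset.

    Per-class accuracies are averaged over all model × dataset cells in
    which the class occurs; the class with the lowest model-averaged
    accuracy is flagged as the weakest — the incompatible-subtype readout.
    """
    from .classifiers import predict

    if not models or not datasets:
        raise ArgumentError("need at least one model and one dataset")
    class_order = models[0].class_order
    for m in models[1:]:
        if m.class_order != class_order:
            raise ArgumentError(
                f"class-order mismatch: {m.class_order} vs {class_order}"
            )
    all_reports: list[tuple[SubtypeAccuracyReport, ...]] = []
    per_class_values: dict[str, list[float]] = {c: [] for c in class_order}
    for ds in datasets:
        features, labels, sample_ids = _unpack_dataset(ds)
        row = []
        for model in models:
            pred, _ = predict(model, features)
            mapping = _as_mapping(labels)
            cm = confusion(
                {s: mapping[s] for s in sample_ids},
                dict(zip(sample_ids, pred)),
                class_order=class_order,
            )
            rep = per_subtype_accuracy(cm)
            row.append(rep)
            for c in class_order:
                if rep.per_class[c] is not None:
                    per_class_values[c].append(rep.per_class[c])
        all_reports.append(tuple(row))
    averaged = {
        c: float(np.mean(v)) for c, v in per_class_values.items() if v
    }
    if not averaged:
        raise ArgumentError("no class had any evaluated samples")
    sds = {
        c: (float(np.std(v, ddof=1)) if len(v) >= 2 else None)
        for c, v in per_class_values.items() if v
    }
    weakest = min(averaged, key=lambda c: (averaged[c], c))
    return MultiModelReport(
        class_order=class_order,
        reports=tuple(all_reports),
        model_averaged_per_class=averaged,
        between_model_sd_per_class=sds,
        weakest_class=weakest,
    )


def _unpack_dataset(ds):
    if len(ds) == 3:
        return ds
    features, labels = ds
    if hasattr(features, "sample_ids"):
        return features, labels, list(features.sample_ids)
    if isinstance(labels, LabelTable):
        return features, labels, list(labels.sample_ids)
    raise ArgumentError("dataset must be (features, labels[, sample_ids])")
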