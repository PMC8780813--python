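"""End-to-end study protocols on the synthetic multi-platform suite.

Three readouts mirror the pipeline's claims:

* cross-platform transfer — a dense net trained on one platform's raw
  features collapses on a differently-normalized platform, while the
  same architecture trained on SND-unified features transfers;
* incompatible-subtype detection — the injected mixture label shows the
  lowest model-averaged per-class accuracy across seeded convolutional
  models;
* pooling — training on the union of two SND-unified platform views
  improves accuracy on a held-out third platform over single-view
  training.

All problem sizes follow the default suite (200 genes, 4 classes × 60
samples, optional 60 mixture samples, 3 platforms, effect 1.5 SD,
platform noise 0.2) — small enough to run on one CPU in minutes while
keeping the qualitative orderings stable across seeds.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np

from .classifiers import (
    CDNNSpec,
    DNNSpec,
    SplitSpec,
    accuracy,
    split_dataset,
    train_cdnn,
    train_dnn,
)
from .evaluation import multi_model_report
from .image_embed import embed_matrix
from .io_formats import ExpressionTable, LabelTable
from .snd import SNDMatrix, build_reference_gene_list, snd_transform_matrix
from .synthetic import CohortConfig, simulate_multiplatform_suite

__all__ = [
    "SMALL_DNN",
    "SMALL_CDNN",
    "cross_platform_transfer",
    "mixture_detection",
    "pooling_improvement",
]

#: Dense spec scaled to the 200-gene synthetic cohorts: same 2-hidden-layer
#: shape as the full-transcriptome default, narrower and trained longer.
SMALL_DNN = DNNSpec(hidden_sizes=(64, 32), learning_rate=0.01,
                    epochs=8, iterations=5)

#: Convolutional spec for 15×15 expression images (the package defaults).
SMALL_CDNN = CDNNSpec()

_ANCHOR = "C1"  # the reference-gene-list anchor class (the PN analogue)


def _subset_cols(view: ExpressionTable, ids: list[str]) -> ExpressionTable:
    return view.subset_samples(ids)


def _concat_snd(a: SNDMatrix, b: SNDMatrix) -> SNDMatrix:
    assert a.rgl.gene_ids == b.rgl.gene_ids
    return SNDMatrix(
        rgl=a.rgl,
        sample_ids=[f"{s}@a" for s in a.sample_ids] + [f"{s}@b" for s in b.sample_ids],
        values=np.concatenate([a.values, b.values], axis=1),
    )


def _pooled_labels(labels: LabelTable) -> LabelTable:
    return LabelTable(
        [f"{s}@a" for s in labels.sample_ids] + [f"{s}@b" for s in labels.sample_ids],
        labels.labels + labels.labels,
        class_set=list(labels.class_set),
    )


def cross_platform_transfer(seed: int = 0) -> dict:
    """Train on platform 1, test on platform 2: raw vs SND features.

    Returns percent accuracies and the SND-minus-raw gap in percentage
    points. The train platform is an affine re-scaling of log-like
    intensities; the test platform reports unlogged intensities riding on
    a large additive background. Both are rank-preserving, so the SND
    route sees (noise apart) the same data while the raw route sees a
    feature scale and offset it never trained on.
    """
    config = CohortConfig(seed=seed)
    cohort = simulate_multiplatform_suite(config, k_platforms=3)
    train_view = cohort.views["platform1"]
    test_view = cohort.views["platform2"]
    split = SplitSpec(validate_fraction=0.0, seed=seed, stratified=True)
    train_ids, _, _ = split_dataset(train_view.sample_ids, cohort.labels, split)
    train_labels = cohort.labels.subset(train_ids)
    dnn_spec = replace(SMALL_DNN, seed=seed)

    raw_model = train_dnn(_subset_cols(train_view, train_ids), train_labels, dnn_spec)
    raw_acc = accuracy(raw_model, test_view, cohort.labels)

    rgl = build_reference_gene_list(
        _subset_cols(train_view, train_ids), train_labels, anchor_class=_ANCHOR
    )
    snd_train = snd_transform_matrix(_subset_cols(train_view, train_ids), rgl)
    snd_test = snd_transform_matrix(test_view, rgl)
    snd_model = train_dnn(snd_train, train_labels, dnn_spec)
    snd_acc = accuracy(snd_model, snd_test, cohort.labels)

    return {
        "raw_accuracy": 100.0 * raw_acc,
        "snd_accuracy": 100.0 * snd_acc,
        "gap": 100.0 * (snd_acc - raw_acc),
        "n_train": len(train_ids),
        "n_test": test_view.n_samples,
    }


def mixture_detection(seed: int = 0, n_models: int = 3) -> dict:
    """Per-class accuracy audit with the injected mixture subtype.

    The latent cohort (4 signature classes × 60 plus 60 mixture samples)
    is SND-unified, embedded as images, split 70/30, and classified by
    ``n_models`` seeded convolutional nets; per-class accuracies on the
    test split are averaged over models and the weakest class reported.
    """
    config = CohortConfig(seed=seed)
    cohort = simulate_multiplatform_suite(
        config, k_platforms=2, mixture={"label": "MIX", "n": 60}
    )
    rgl = build_reference_gene_list(cohort.latent, cohort.labels, _ANCHOR)
    snd = snd_transform_matrix(cohort.latent, rgl)
    images = embed_matrix(snd)
    split = SplitSpec(validate_fraction=0.0, seed=seed, stratified=True)
    train_ids, test_ids, _ = split_dataset(snd.sample_ids, cohort.labels, split)
    pos = {s: i for i, s in enumerate(snd.sample_ids)}
    tr_idx = [pos[s] for s in train_ids]
    te_idx = [pos[s] for s in test_ids]
    models = [
        train_cdnn(
            images[tr_idx], cohort.labels.subset(train_ids),
            spec=replace(SMALL_CDNN, seed=seed * 100 + k),
        )
        for k in range(n_models)
    ]
    report = multi_model_report(
        models, [(images[te_idx], cohort.labels.subset(test_ids), test_ids)]
    )
    return {
        "per_class": report.model_averaged_per_class,
        "weakest_class": report.weakest_class,
        "mixture_class": "MIX",
        "mixture_is_weakest": report.weakest_class == "MIX",
        "n_test": len(test_ids),
        "n_models": n_models,
    }


def pooling_improvement(seed: int = 0, n_models: int = 3) -> dict:
    """Does pooling two SND-unified platforms beat one on a third?

    Mirrors the pooled-training protocol: the full cohort (including the
    incompatible mixture subtype, as in the real multi-subtype datasets)
    is SND-unified per view with one reference gene list; a dense net is
    trained on platform 1 alone and on platforms 1+2 pooled; both are
    scored on the held-out platform 3. Because the two pooled views are
    the same latent samples under different distortions and noise, the
    pooled set acts like an augmented training set. Accuracies are
    averaged over ``n_models`` seeded trainings per condition, as in the
    multi-model protocol, so the readout reflects the data and not one
    optimizer trajectory.
    """
    config = CohortConfig(seed=seed)
    cohort = simulate_multiplatform_suite(
        config, k_platforms=3, mixture={"label": "MIX", "n": 60}
    )
    rgl = build_reference_gene_list(cohort.views["platform1"], cohort.labels, _ANCHOR)
    snd = {
        name: snd_transform_matrix(view, rgl)
        for name, view in cohort.views.items()
    }
    heldout = snd["platform3"]
    single_accs, pooled_accs = [], []
    for k in range(n_models):
        dnn_spec = replace(SMALL_DNN, seed=seed * 100 + k)
        single = train_dnn(snd["platform1"], cohort.labels, dnn_spec)
        pooled = train_dnn(
            _concat_snd(snd["platform1"], snd["platform2"]),
            _pooled_labels(cohort.labels),
            dnn_spec,
        )
        single_accs.append(accuracy(single, heldout, cohort.labels))
        pooled_accs.append(accuracy(pooled, heldout, cohort.labels))
    single_acc = float(np.mean(single_accs))
    pooled_acc = float(np.mean(pooled_accs))
    return {
        "single_accuracy": 100.0 * single_acc,
        "pooled_accuracy": 100.0 * pooled_acc,
        "improvement": 100.0 * (pooled_acc - single_acc),
        "n_heldout": heldout.values.shape[1],
        "n_models": n_models,
    }
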