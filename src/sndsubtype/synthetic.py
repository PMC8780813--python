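"""Synthetic multi-platform expression cohorts.

The generator emulates the situation the rank-based unification targets:
one latent cohort of labelled samples, observed through several
platform-specific *strictly monotone* distortions plus noise. Class
structure is additive gene-signature structure on a log-intensity-like
Gaussian baseline; an optional "incompatible" subtype is generated as a
mixture of the other classes' models — samples carrying a label of their
own but no distribution of their own, the synthetic analogue of a
subtype that does not fit the classification system.

Platform noise is specified relative to the distorted view's value SD,
so a 0.2 setting means the same signal-to-noise on every platform
regardless of the monotone map's output scale.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ArgumentError
from .io_formats import ExpressionTable, LabelTable

__all__ = [
    "CohortConfig",
    "PlatformTransform",
    "SyntheticCohort",
    "simulate_cohort",
    "apply_platform_transform",
    "inject_mixture_subtype",
    "simulate_multiplatform_suite",
    "default_platform_transforms",
    "nearest_centroid_accuracy",
]

#: Default class names for the four signature-bearing subtypes.
DEFAULT_CLASSES = ("C1", "C2", "C3", "C4")


@dataclass(frozen=True)
class CohortConfig:
    """Latent-cohort parameters.

    ``effect_size`` is the additive up-shift of a class's signature genes
    in units of the within-gene noise SD; 1.5 gives clearly separable but
    not trivial classes (a nearest-centroid oracle scores ≈1.0 while
    single genes stay noisy). Baseline gene means are spread with SD
    ``baseline_sd`` around ``baseline_mean`` on a log2-intensity-like
    scale, giving the unimodal per-sample distributions the rank
    transform assumes.
    """

    n_genes: int = 200
    n_samples_per_class: Mapping[str, int] = field(
        default_factory=lambda: {c: 60 for c in DEFAULT_CLASSES}
    )
    signature_size: int = 20
    effect_size: float = 1.5
    baseline_mean: float = 8.0
    baseline_sd: float = 1.0
    noise_sd: float = 1.0
    seed: int = 0
    class_signatures: Mapping[str, Sequence[str]] | None = None

    def __post_init__(self) -> None:
        if self.n_genes < 2:
            raise ArgumentError("need at least 2 genes")
        if any(n < 1 for n in self.n_samples_per_class.values()):
            raise ArgumentError("every class needs at least 1 sample")
        if self.effect_size < 0:
            raise ArgumentError("effect size must be >= 0")
        if self.noise_sd <= 0:
            raise ArgumentError("noise SD must be positive")
        k = len(self.n_samples_per_class)
        if self.class_signatures is None and self.signature_size * k > self.n_genes:
            raise ArgumentError(
                f"{k} disjoint signatures of {self.signature_size} genes do not "
                f"fit in {self.n_genes} genes"
            )


@dataclass(frozen=True)
class PlatformTransform:
    """A named strictly increasing distortion plus relative additive noise.

    Families: ``affine`` (a·x + b, a > 0); ``power`` ((x − xmin + c)^p,
    p > 0, on shifted positives); ``logistic`` (saturating
    1/(1 + exp(−(x − x0)/s)), s > 0); ``piecewise`` (monotone linear
    interpolation through increasing knots).
    """

    name: str
    kind: str
    params: Mapping[str, float | Sequence[float]] = field(default_factory=dict)
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        p = self.params
        if self.kind == "affine":
            if p.get("a", 1.0) <= 0:
                raise ArgumentError("affine slope must be > 0")
        elif self.kind == "power":
            if p.get("p", 1.0) <= 0:
                raise ArgumentError("power exponent must be > 0")
            if p.get("c", 1.0) <= 0:
                raise ArgumentError("power shift must be > 0")
        elif self.kind == "logistic":
            if p.get("s", 1.0) <= 0:
                raise ArgumentError("logistic scale must be > 0")
        elif self.kind == "piecewise":
            xs = np.asarray(p["xs"], dtype=float)
            ys = np.asarray(p["ys"], dtype=float)
            if len(xs) != len(ys) or len(xs) < 2:
                raise ArgumentError("piecewise needs matching knot arrays, >= 2 knots")
            if np.any(np.diff(xs) <= 0) or np.any(np.diff(ys) <= 0):
                raise ArgumentError("piecewise knots must be strictly increasing")
        else:
            raise ArgumentError(f"unknown transform kind {self.kind!r}")
        if self.noise_sd < 0:
            raise ArgumentError("noise SD must be >= 0")

    def apply(self, values: np.ndarray) -> np.ndarray:
        """The noise-free monotone map, elementwise."""
        x = np.asarray(values, dtype=float)
        p = self.params
        if self.kind == "affine":
            return p.get("a", 1.0) * x + p.get("b", 0.0)
        if self.kind == "power":
            shifted = x - x.min() + p.get("c", 1.0)
            return shifted ** p.get("p", 1.0)
        if self.kind == "logistic":
            return 1.0 / (1.0 + np.exp(-(x - p.get("x0", 0.0)) / p.get("s", 1.0)))
        xs = np.asarray(p["xs"], dtype=float)
        ys = np.asarray(p["ys"], dtype=float)
        # linear extrapolation beyond the knots keeps strict monotonicity
        out = np.interp(x, xs, ys)
        lo, hi = x < xs[0], x > xs[-1]
        out[lo] = ys[0] + (x[lo] - xs[0]) * (ys[1] - ys[0]) / (xs[1] - xs[0])
        out[hi] = ys[-1] + (x[hi] - xs[-1]) * (ys[-1] - ys[-2]) / (xs[-1] - xs[-2])
        return out


@dataclass
class SyntheticCohort:
    """Latent truth, platform views, labels, and construction metadata."""

    latent: ExpressionTable
    labels: LabelTable
    config: CohortConfig
    views: dict[str, ExpressionTable] = field(default_factory=dict)
    transforms: dict[str, PlatformTransform] = field(default_factory=dict)
    truth_meta: dict = field(default_factory=dict)

    @property
    def class_signatures(self) -> dict[str, tuple[str, ...]]:
        return self.truth_meta["class_signatures"]


def _gene_ids(n: int) -> list[str]:
    width = len(str(n))
    return [f"g{i + 1:0{width}d}" for i in range(n)]


def _resolve_signatures(config: CohortConfig, genes: list[str]) -> dict[str, tuple[str, ...]]:
    classes = list(config.n_samples_per_class)
    if config.class_signatures is not None:
        out = {}
        universe = set(genes)
        for c in classes:
            sig = tuple(config.class_signatures.get(c, ()))
            outside = [g for g in sig if g not in universe]
            if outside:
                raise ArgumentError(
                    f"signature genes outside the gene universe: {outside[:5]}"
                )
            out[c] = sig
        return out
    return {
        c: tuple(genes[i * config.signature_size : (i + 1) * config.signature_size])
        for i, c in enumerate(classes)
    }


def _draw_samples(
    rng: np.random.Generator,
    gene_means: np.ndarray,
    gene_index: Mapping[str, int],
    signatures: Mapping[str, Sequence[str]],
    donor_classes: Sequence[str],
    config: CohortConfig,
) -> np.ndarray:
    """One column per entry of donor_classes, drawn from that class model."""
    n_genes = len(gene_means)
    out = np.empty((n_genes, len(donor_classes)))
    for j, cls in enumerate(donor_classes):
        mean = gene_means.copy()
        for g in signatures[cls]:
            mean[gene_index[g]] += config.effect_size * config.noise_sd
        out[:, j] = mean + rng.normal(0.0, config.noise_sd, size=n_genes)
    return out


def simulate_cohort(config: CohortConfig = CohortConfig()) -> SyntheticCohort:
    """Draw the latent labelled cohort: baseline + class effect + noise."""
    rng = np.random.default_rng(config.seed)
    genes = _gene_ids(config.n_genes)
    gene_index = {g: i for i, g in enumerate(genes)}
    signatures = _resolve_signatures(config, genes)
    gene_means = rng.normal(config.baseline_mean, config.baseline_sd,
                            size=config.n_genes)
    sample_ids: list[str] = []
    sample_classes: list[str] = []
    for cls, n in config.n_samples_per_class.items():
        sample_ids += [f"{cls}_{i + 1:03d}" for i in range(n)]
        sample_classes += [cls] * n
    values = _draw_samples(rng, gene_means, gene_index, signatures,
                           sample_classes, config)
    latent = ExpressionTable(pd.DataFrame(values, index=genes, columns=sample_ids))
    labels = LabelTable(sample_ids, sample_classes,
                        class_set=sorted(config.n_samples_per_class))
    return SyntheticCohort(
        latent=latent,
        labels=labels,
        config=config,
        truth_meta={
            "class_signatures": signatures,
            "gene_means": gene_means,
            "mixture_class": None,
        },
    )


def apply_platform_transform(
    cohort: SyntheticCohort, transform: PlatformTransform
) -> SyntheticCohort:
    """Add (or refresh) the platform view ``transform.name``.

    View = monotone_map(latent) + Gaussian noise with SD equal to
    ``transform.noise_sd`` × SD(mapped values). With zero noise the
    within-sample ranks equal the latent ranks exactly.
    """
    mapped = transform.apply(cohort.latent.values)
    if transform.noise_sd > 0:
        rng = np.random.default_rng(transform.seed)
        scale = transform.noise_sd * float(mapped.std())
        mapped = mapped + rng.normal(0.0, scale, size=mapped.shape)
    view = ExpressionTable(
        pd.DataFrame(mapped, index=cohort.latent.gene_ids,
                     columns=cohort.latent.sample_ids)
    )
    cohort.views[transform.name] = view
    cohort.transforms[transform.name] = transform
    return cohort


def inject_mixture_subtype(
    cohort: SyntheticCohort,
    label: str = "MIX",
    n: int = 60,
    mixing: Mapping[str, float] | None = None,
    seed: int | None = None,
) -> SyntheticCohort:
    """Append n samples drawn from *other* classes' models under a new label.

    Each new sample picks a donor class with the given weights (uniform
    over existing classes by default) and is generated from that donor's
    distribution — so the new label has no distribution of its own, the
    defining property of an incompatible subtype. Existing platform views
    are regenerated to cover the new samples.
    """
    if n < 1:
        raise ArgumentError("need n >= 1 mixture samples")
    if label in cohort.labels.class_set:
        raise ArgumentError(f"label {label!r} already exists")
    classes = list(cohort.config.n_samples_per_class)
    if mixing is None:
        mixing = {c: 1.0 / len(classes) for c in classes}
    weights = np.array([float(mixing.get(c, 0.0)) for c in classes])
    if np.any(weights < 0) or not math.isclose(weights.sum(), 1.0, abs_tol=1e-9):
        raise ArgumentError("mixing weights must be non-negative and sum to 1")
    unknown = sorted(set(mixing) - set(classes))
    if unknown:
        raise ArgumentError(f"mixing weights over unknown classes: {unknown}")
    rng = np.random.default_rng(cohort.config.seed + 1 if seed is None else seed)
    donors = [classes[i] for i in rng.choice(len(classes), size=n, p=weights)]
    genes = cohort.latent.gene_ids
    gene_index = {g: i for i, g in enumerate(genes)}
    values = _draw_samples(rng, cohort.truth_meta["gene_means"], gene_index,
                           cohort.class_signatures, donors, cohort.config)
    new_ids = [f"{label}_{i + 1:03d}" for i in range(n)]
    latent = ExpressionTable(
        pd.concat(
            [cohort.latent.data,
             pd.DataFrame(values, index=genes, columns=new_ids)], axis=1
        )
    )
    labels = LabelTable(
        cohort.labels.sample_ids + new_ids,
        cohort.labels.labels + [label] * n,
        class_set=sorted(cohort.labels.class_set + [label]),
        metadata=cohort.labels.metadata,
    )
    out = SyntheticCohort(
        latent=latent, labels=labels, config=cohort.config,
        truth_meta={**cohort.truth_meta,
                    "mixture_class": label,
                    "mixture_donors": dict(zip(new_ids, donors))},
    )
    for t in cohort.transforms.values():
        apply_platform_transform(out, t)
    return out


def default_platform_transforms(
    k: int, noise_sd: float = 0.2, seed: int = 0
) -> list[PlatformTransform]:
    """k distinct monotone distortions cycling through the map families.

    The first three emulate common normalization outputs that differ the
    way real pipelines do — in offset, scale *and* curvature: a rescaled
    log-intensity (affine); an unlogged intensity riding on an additive
    background (power on shifted positives, values in the thousands); and
    a sharply saturating bounded score (logistic around the latent
    baseline). Further platforms perturb the family parameters.
    """
    if k < 1:
        raise ArgumentError("need k >= 1 transforms")
    rng = np.random.default_rng(seed)
    out: list[PlatformTransform] = []
    for i in range(k):
        fam = i % 3
        jitter = rng.uniform(0.8, 1.2)
        if fam == 0:
            t = PlatformTransform(
                name=f"platform{i + 1}", kind="affine",
                params={"a": 0.7 * jitter, "b": -2.0 + i},
                noise_sd=noise_sd, seed=seed * 1000 + i,
            )
        elif fam == 1:
            t = PlatformTransform(
                name=f"platform{i + 1}", kind="power",
                params={"p": 2.5 * jitter, "c": 40.0},
                noise_sd=noise_sd, seed=seed * 1000 + i,
            )
        else:
            t = PlatformTransform(
                name=f"platform{i + 1}", kind="logistic",
                params={"x0": 8.0, "s": 0.5 * jitter},
                noise_sd=noise_sd, seed=seed * 1000 + i,
            )
        out.append(t)
    return out


def simulate_multiplatform_suite(
    config: CohortConfig = CohortConfig(),
    k_platforms: int = 3,
    platform_noise_sd: float = 0.2,
    mixture: Mapping | None = None,
    seed: int | None = None,
) -> SyntheticCohort:
    """One latent cohort observed through k distinct platform distortions.

    ``mixture`` (e.g. ``{"label": "MIX", "n": 60}``) injects the
    incompatible subtype before the views are generated. The default
    acceptance-scale suite is 200 genes, 4 classes × 60 samples (+ 60
    mixture samples when requested), 3 platforms, effect 1.5 SD, platform
    noise 0.2.
    """
    if k_platforms < 2:
        raise ArgumentError("a multi-platform suite needs k >= 2 platforms")
    cohort = simulate_cohort(config)
    if mixture is not None:
        cohort = inject_mixture_subtype(cohort, **mixture)
    tseed = config.seed if seed is None else seed
    for t in default_platform_transforms(k_platforms, platform_noise_sd, tseed):
        apply_platform_transform(cohort, t)
    return cohort


def nearest_centroid_accuracy(
    train: tuple[np.ndarray, np.ndarray],
    test: tuple[np.ndarray, np.ndarray],
) -> float:
    """Oracle separability check: nearest class centroid in latent space.

    Arguments are (features, integer labels) with samples in rows. Used
    by tests to certify that a simulated cohort is separable before any
    network sees it.
    """
    x_tr, y_tr = train
    x_te, y_te = test
    classes = np.unique(y_tr)
    centroids = np.stack([x_tr[y_tr == c].mean(axis=0) for c in classes])
    d = ((x_te[:, None, :] - centroids[None, :, :]) ** 2).sum(axis=2)
    pred = classes[d.argmin(axis=1)]
    return float(np.mean(pred == y_te))
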