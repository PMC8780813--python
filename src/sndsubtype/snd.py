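"""Rank-based unification of expression profiles onto a standard normal.

Every sample is transformed using only its *internal* expression ranks:
the gene with rank r (1 = lowest expression) receives the r-th smallest
value of a fixed n-element standard-normal reference set. Each complete
sample therefore carries the identical value multiset and differs from
other samples only in the order of those values — which makes the
representation invariant to any strictly increasing per-sample distortion
(platform scaling, log transforms, normalization pipelines).

Genes are then re-ordered onto a fixed reference gene list (RGL) so that
position i means the same gene in every sample; RGL genes absent from a
sample are filled with 0 (the N(0,1) median), and sample genes absent from
the RGL are discarded.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
from scipy import stats

from .errors import ArgumentError
from .io_formats import ExpressionTable, LabelTable

__all__ = [
    "ReferenceDistribution",
    "ReferenceGeneList",
    "SNDMatrix",
    "make_reference_distribution",
    "build_reference_gene_list",
    "snd_transform_sample",
    "snd_transform_matrix",
]


@dataclass(frozen=True)
class ReferenceDistribution:
    """The sorted n-element N(0,1) value set ranks are mapped onto.

    ``quantile`` mode uses the deterministic mid-probability quantiles
    ppf((i + 0.5)/n); ``sampled`` mode sorts n standard-normal draws from
    ``seed`` — closer to literally drawing an N(0,1) array, but not
    bit-reproducible across libraries, so quantile is the default.
    """

    n: int
    values: np.ndarray
    mode: str = "quantile"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ArgumentError(f"reference distribution needs n >= 2, got {self.n}")
        v = np.asarray(self.values, dtype=float)
        if v.shape != (self.n,):
            raise ArgumentError("values length must equal n")
        if np.any(np.diff(v) < 0):
            raise ArgumentError("reference values must be sorted ascending")
        object.__setattr__(self, "values", v)

    def with_n(self, n: int) -> "ReferenceDistribution":
        """Rebuild with the same mode/seed for a different gene count."""
        if n == self.n:
            return self
        return make_reference_distribution(n, mode=self.mode, seed=self.seed)


def make_reference_distribution(
    n: int, mode: str = "quantile", seed: int = 0
) -> ReferenceDistribution:
    """Produce the sorted n-element standard-normal reference set."""
    if n < 2:
        raise ArgumentError(f"reference distribution needs n >= 2, got {n}")
    if mode == "quantile":
        values = stats.norm.ppf((np.arange(n) + 0.5) / n)
    elif mode == "sampled":
        values = np.sort(np.random.default_rng(seed).standard_normal(n))
    else:
        raise ArgumentError(f"unknown mode {mode!r} (expected 'quantile' or 'sampled')")
    return ReferenceDistribution(n=n, values=values, mode=mode, seed=seed)


@dataclass(frozen=True)
class ReferenceGeneList:
    """A fixed gene ordering giving SND vectors a common coordinate system."""

    gene_ids: tuple[str, ...]
    provenance: str = ""

    def __post_init__(self) -> None:
        if len(self.gene_ids) < 2:
            raise ArgumentError("reference gene list needs at least 2 genes")
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ArgumentError("reference gene list contains duplicates")
        object.__setattr__(self, "gene_ids", tuple(self.gene_ids))

    def __len__(self) -> int:
        return len(self.gene_ids)

    def index(self) -> dict[str, int]:
        return {g: i for i, g in enumerate(self.gene_ids)}


def build_reference_gene_list(
    table: ExpressionTable,
    labels: LabelTable,
    anchor_class: str,
    aggregate: str = "mean",
) -> ReferenceGeneList:
    """Order genes ascending by their aggregate expression in one subtype.

    The anchor class plays the role the Proneural subtype plays for GBM:
    its mean (or median) expression defines the canonical gene order. Ties
    are broken by gene ID, lexicographically, so the list is deterministic.
    """
    if aggregate not in ("mean", "median"):
        raise ArgumentError(f"aggregate must be 'mean' or 'median', got {aggregate!r}")
    mapping = labels.as_mapping()
    anchor = [s for s in table.sample_ids if mapping.get(s) == anchor_class]
    if not anchor:
        raise ArgumentError(
            f"anchor class {anchor_class!r} has no samples in the table"
        )
    sub = table.data[anchor]
    agg = sub.mean(axis=1) if aggregate == "mean" else sub.median(axis=1)
    order = sorted(zip(agg.to_numpy(), agg.index), key=lambda t: (t[0], t[1]))
    return ReferenceGeneList(
        gene_ids=tuple(g for _, g in order),
        provenance=f"ascending {aggregate} expression in {len(anchor)} "
        f"{anchor_class!r} samples",
    )


@dataclass
class SNDMatrix:
    """SND-transformed samples aligned to a reference gene list."""

    rgl: ReferenceGeneList
    sample_ids: list[str]
    values: np.ndarray  # rows = RGL genes, columns = samples
    fill_value: float = 0.0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.rgl), len(self.sample_ids)):
            raise ArgumentError(
                f"SND matrix shape {self.values.shape} does not match "
                f"{len(self.rgl)} RGL genes x {len(self.sample_ids)} samples"
            )

    @property
    def n_genes(self) -> int:
        return len(self.rgl)

    def to_expression_table(self) -> ExpressionTable:
        import pandas as pd

        return ExpressionTable(
            pd.DataFrame(self.values, index=list(self.rgl.gene_ids),
                         columns=self.sample_ids)
        )


def snd_transform_sample(
    expr: Mapping[str, float],
    rgl: ReferenceGeneList,
    refdist: ReferenceDistribution | None = None,
    fill_value: float = 0.0,
) -> np.ndarray:
    """Transform one sample's gene → value map onto the reference set.

    Steps: intersect with the RGL (values for genes outside the RGL are
    discarded); rank the retained values (ties broken by RGL position, so
    the mapping is deterministic and the output multiset is exactly the
    reference set); replace rank r with the r-th reference value; order by
    the RGL; fill absent RGL genes with ``fill_value``.

    ``refdist`` acts as a template: when its length differs from the number
    of retained genes it is rebuilt (same mode and seed) for that count, so
    short panels still occupy the full N(0,1) range.
    """
    idx = rgl.index()
    positions: list[int] = []
    vals: list[float] = []
    for g, v in expr.items():
        i = idx.get(g)
        if i is None:
            continue  # gene not in RGL: discarded
        positions.append(i)
        vals.append(float(v))
    if not positions:
        raise ArgumentError("no genes shared between the sample and the RGL")
    pos = np.asarray(positions, dtype=int)
    val = np.asarray(vals, dtype=float)
    if not np.all(np.isfinite(val)):
        bad = [g for g, v in expr.items() if g in idx and not np.isfinite(float(v))]
        raise ArgumentError(f"non-finite expression values for genes {bad[:5]}")
    m = len(val)
    if m < 2:
        raise ArgumentError("need at least 2 genes shared with the RGL")
    rd = make_reference_distribution(m) if refdist is None else refdist.with_n(m)
    # sort by (value, RGL position): stable ordinal ranks, ties by RGL order
    order = np.lexsort((pos, val))
    out = np.full(len(rgl), float(fill_value))
    out[pos[order]] = rd.values
    return out


def snd_transform_matrix(
    table: ExpressionTable,
    rgl: ReferenceGeneList,
    refdist: ReferenceDistribution | None = None,
    fill_value: float = 0.0,
) -> SNDMatrix:
    """Apply :func:`snd_transform_sample` to every column independently.

    No cross-sample statistic is used anywhere — that per-sample
    independence is what lets single samples from unseen platforms be
    unified without re-running any cohort-level normalization.
    """
    gene_ids = table.gene_ids
    cols = np.empty((len(rgl), table.n_samples), dtype=float)
    raw = table.values
    for j, sid in enumerate(table.sample_ids):
        expr = dict(zip(gene_ids, raw[:, j]))
        try:
            cols[:, j] = snd_transform_sample(expr, rgl, refdist, fill_value)
        except ArgumentError as exc:
            raise ArgumentError(f"sample {sid!r}: {exc}") from exc
    return SNDMatrix(rgl=rgl, sample_ids=list(table.sample_ids), values=cols,
                     fill_value=float(fill_value))
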