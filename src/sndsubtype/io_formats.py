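"""Tab-delimited expression-matrix, label and gene-list I/O.

All pipeline inputs are plain UTF-8 TSV: an expression matrix has a header
row of sample identifiers (first column holds gene identifiers) and one row
per gene; a label table has a sample-ID column, a subtype column, and any
number of metadata columns (e.g. IDH status).

Duplicate gene rows are collapsed by per-sample averaging; missing cells
("NA", "null", empty) are imputed with the gene's row median. Both policies
are deterministic and order-independent, and the rank-based transform
downstream makes median imputation the least disruptive choice.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ArgumentError, FormatError, ParseError

logger = logging.getLogger(__name__)

#: Cell contents treated as missing by default.
MISSING_TOKENS = ("NA", "null", "NaN", "nan", "")


@dataclass
class ExpressionTable:
    """A real-valued gene × sample matrix with identifiers.

    ``data`` is a pandas DataFrame indexed by gene ID with sample IDs as
    columns; units are whatever the source platform produced (log-intensity,
    RSEM, ...). Construction validates identifier uniqueness and shape.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        idx = self.data.index.astype(str)
        cols = self.data.columns.astype(str)
        if len(cols) == 0:
            raise FormatError("expression table has no samples")
        if len(idx) == 0:
            raise FormatError("expression table has no genes")
        if any(g == "" for g in idx) or any(s == "" for s in cols):
            raise FormatError("empty gene or sample identifier")
        if idx.has_duplicates:
            dup = idx[idx.duplicated()].unique().tolist()
            raise FormatError(
                f"duplicate gene identifiers after collapsing: {dup[:5]}"
            )
        if cols.has_duplicates:
            dup = cols[cols.duplicated()].unique().tolist()
            raise FormatError(f"duplicate sample identifiers: {dup[:5]}")
        self.data = self.data.copy()
        self.data.index = idx
        self.data.columns = cols

    @property
    def gene_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)

    @property
    def n_genes(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    def sample(self, sample_id: str) -> pd.Series:
        """One sample's gene → value map."""
        return self.data[sample_id]

    def subset_samples(self, sample_ids: Sequence[str]) -> "ExpressionTable":
        missing = [s for s in sample_ids if s not in self.data.columns]
        if missing:
            raise ArgumentError(f"samples not in table: {missing[:5]}")
        return ExpressionTable(self.data[list(sample_ids)])


@dataclass
class LabelTable:
    """Per-sample categorical subtype labels plus optional metadata columns."""

    sample_ids: list[str]
    labels: list[str]
    class_set: list[str] = field(default_factory=list)
    metadata: dict[str, dict[str, str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.sample_ids) != len(self.labels):
            raise FormatError("sample_ids and labels differ in length")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            seen: set[str] = set()
            dup = [s for s in self.sample_ids if s in seen or seen.add(s)]
            raise FormatError(f"duplicate sample identifiers: {dup[:5]}")
        if not self.class_set:
            self.class_set = sorted(set(self.labels))
        bad = sorted(set(self.labels) - set(self.class_set))
        if bad:
            raise FormatError(
                f"labels outside the declared class set {self.class_set}: {bad}"
            )

    def __len__(self) -> int:
        return len(self.sample_ids)

    def as_mapping(self) -> dict[str, str]:
        return dict(zip(self.sample_ids, self.labels))

    def label_of(self, sample_id: str) -> str:
        return self.as_mapping()[sample_id]

    def subset(self, sample_ids: Sequence[str]) -> "LabelTable":
        m = self.as_mapping()
        missing = [s for s in sample_ids if s not in m]
        if missing:
            raise ArgumentError(f"samples not in label table: {missing[:5]}")
        meta = {
            k: {s: v[s] for s in sample_ids if s in v}
            for k, v in self.metadata.items()
        }
        return LabelTable(
            list(sample_ids), [m[s] for s in sample_ids],
            class_set=list(self.class_set), metadata=meta,
        )

    def samples_where(self, column: str, value: str) -> list[str]:
        """Sample IDs whose metadata ``column`` equals ``value`` (e.g. IDH='WT')."""
        if column not in self.metadata:
            raise ArgumentError(f"no metadata column {column!r}")
        col = self.metadata[column]
        return [s for s in self.sample_ids if col.get(s) == value]


def read_expression_table(
    path: str | Path,
    missing_tokens: Iterable[str] = MISSING_TOKENS,
    impute: str = "median",
) -> ExpressionTable:
    """Read a tab-delimited gene × sample matrix.

    First header cell is ignored (gene-ID column name); duplicate gene rows
    are averaged per sample; missing cells are imputed with the gene's row
    median (``impute="median"``) or left NaN (``impute="none"``). The number
    of imputed cells is reported through the module logger.
    """
    path = Path(path)
    missing = set(missing_tokens)
    with path.open("r", encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n")
        if "\t" not in header:
            raise FormatError(f"{path}: header is not tab-delimited")
        sample_ids = header.split("\t")[1:]
        if any(s == "" for s in sample_ids):
            raise FormatError(f"{path}: empty sample identifier in header")
        if len(set(sample_ids)) != len(sample_ids):
            raise FormatError(f"{path}: duplicate sample identifiers in header")
        genes: list[str] = []
        rows: list[list[float]] = []
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            cells = line.split("\t")
            if len(cells) != len(sample_ids) + 1:
                raise FormatError(
                    f"{path}:{lineno}: expected {len(sample_ids) + 1} columns, "
                    f"got {len(cells)}"
                )
            genes.append(cells[0])
            row: list[float] = []
            for j, cell in enumerate(cells[1:], start=2):
                if cell in missing:
                    row.append(np.nan)
                    continue
                try:
                    row.append(float(cell))
                except ValueError as exc:
                    raise ParseError(
                        f"{path}:{lineno}: column {j}: "
                        f"non-numeric cell {cell!r}"
                    ) from exc
            rows.append(row)
    if not genes:
        raise FormatError(f"{path}: no data rows")
    df = pd.DataFrame(rows, index=genes, columns=sample_ids, dtype=float)
    if df.index.has_duplicates:
        n_dup = int(df.index.duplicated().sum())
        logger.info("%s: averaging %d duplicate gene rows", path, n_dup)
        df = df.groupby(level=0, sort=False).mean()
    n_missing = int(df.isna().to_numpy().sum())
    if n_missing and impute == "median":
        logger.info("%s: imputing %d missing cells with row medians", path, n_missing)
        med = df.median(axis=1)
        df = df.apply(lambda col: col.fillna(med))
    return ExpressionTable(df)


def write_expression_table(table: ExpressionTable, path: str | Path) -> None:
    """Write a table in the dialect :func:`read_expression_table` reads."""
    if table.n_samples == 0 or table.n_genes == 0:
        raise ArgumentError("refusing to write a degenerate (empty) table")
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        fh.write("gene\t" + "\t".join(table.sample_ids) + "\n")
        for gene, row in zip(table.gene_ids, table.values):
            fh.write(gene + "\t" + "\t".join(repr(float(v)) for v in row) + "\n")


def read_labels(
    path: str | Path,
    class_set: Sequence[str] | None = None,
    normalize_ids=None,
) -> LabelTable:
    """Read a 2+-column TSV: sample ID, label, then named metadata columns.

    A header row is required when metadata columns are present and optional
    otherwise (detected by whether the second header cell is a known label
    when ``class_set`` is fixed, else by the literal first cell "sample").
    ``normalize_ids`` is an optional callable applied to each sample ID
    (e.g. stripping TCGA barcode suffixes); off by default.
    """
    path = Path(path)
    lines = [
        ln.rstrip("\n") for ln in path.read_text(encoding="utf-8").splitlines()
        if ln.strip()
    ]
    if not lines:
        raise FormatError(f"{path}: empty label file")
    rows = [ln.split("\t") for ln in lines]
    width = len(rows[0])
    if width < 2:
        raise FormatError(f"{path}: expected at least 2 tab-separated columns")
    if any(len(r) != width for r in rows):
        raise FormatError(f"{path}: ragged rows")
    meta_names: list[str] = []
    first = rows[0]
    has_header = first[0].lower() in ("sample", "sample_id", "id")
    if has_header:
        meta_names = first[2:]
        rows = rows[1:]
    elif width > 2:
        raise FormatError(f"{path}: metadata columns require a header row")
    if not rows:
        raise FormatError(f"{path}: no data rows")
    sample_ids = [r[0] for r in rows]
    if normalize_ids is not None:
        sample_ids = [normalize_ids(s) for s in sample_ids]
    labels = [r[1] for r in rows]
    if class_set is not None:
        bad = sorted(set(labels) - set(class_set))
        if bad:
            raise FormatError(
                f"{path}: label(s) {bad} not in declared class set {list(class_set)}"
            )
    metadata = {
        name: {s: r[2 + k] for s, r in zip(sample_ids, rows)}
        for k, name in enumerate(meta_names)
    }
    return LabelTable(
        sample_ids, labels,
        class_set=list(class_set) if class_set is not None else [],
        metadata=metadata,
    )


def write_labels(labels: LabelTable, path: str | Path) -> None:
    path = Path(path)
    meta_names = list(labels.metadata)
    with path.open("w", encoding="utf-8") as fh:
        fh.write("sample\tlabel" + "".join("\t" + m for m in meta_names) + "\n")
        for s, lab in zip(labels.sample_ids, labels.labels):
            extra = "".join(
                "\t" + labels.metadata[m].get(s, "") for m in meta_names
            )
            fh.write(f"{s}\t{lab}{extra}\n")


def read_gene_list(path: str | Path) -> list[str]:
    """One gene ID per line, order significant."""
    genes = [
        ln.strip() for ln in Path(path).read_text(encoding="utf-8").splitlines()
        if ln.strip()
    ]
    if not genes:
        raise FormatError(f"{path}: empty gene list")
    return genes


def write_gene_list(genes: Sequence[str], path: str | Path) -> None:
    Path(path).write_text("\n".join(genes) + "\n", encoding="utf-8")


def strip_tcga_suffix(sample_id: str) -> str:
    """Normalization hook: keep the first three TCGA barcode fields."""
    parts = sample_id.split("-")
    return "-".join(parts[:3]) if sample_id.upper().startswith("TCGA") else sample_id


def align(table: ExpressionTable, labels: LabelTable) -> tuple[ExpressionTable, LabelTable]:
    """Intersect a cohort: samples present in both, in the table's order."""
    labelled = set(labels.sample_ids)
    common = [s for s in table.sample_ids if s in labelled]
    if not common:
        raise ArgumentError("no samples shared between expression table and labels")
    return table.subset_samples(common), labels.subset(common)
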