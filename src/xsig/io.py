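"""Readers and writers for the pipeline's external formats.

Expression tables are tab-separated, genes in rows (first column), samples in
columns (header row). Gene sets use the GMT dialect (name, description, then
members). Phenotype labels use a CLS-like three-line dialect. All readers
validate strictly and never reorder genes or samples.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

VALUE_KINDS = ("tag_count", "tpm", "intensity")


class FormatError(ValueError):
    """Raised when an input file violates its format contract."""


@dataclass
class ExpressionTable:
    """Gene x sample matrix of non-negative counts or continuous values.

    Parameters
    ----------
    data
        DataFrame with gene identifiers as the index and sample identifiers
        as columns. Identifiers are opaque strings; no species or platform
        semantics are inferred from them.
    value_kind
        One of ``tag_count`` (integer SAGE tag counts), ``tpm``
        (tags/transcripts per million) or ``intensity`` (log-scale
        microarray signal).
    """

    data: pd.DataFrame
    value_kind: str

    def __post_init__(self) -> None:
        if self.value_kind not in VALUE_KINDS:
            raise ValueError(f"unknown value_kind {self.value_kind!r}")
        idx = self.data.index
        cols = self.data.columns
        if idx.has_duplicates:
            dup = idx[idx.duplicated()][0]
            raise FormatError(f"duplicate gene identifier {dup!r}")
        if cols.has_duplicates:
            dup = cols[cols.duplicated()][0]
            raise FormatError(f"duplicate sample identifier {dup!r}")
        values = self.data.to_numpy()
        if values.size and not np.isfinite(values).all():
            raise FormatError("expression values must be finite (no missing values)")
        if values.size and (values < 0).any():
            g, s = np.argwhere(values < 0)[0]
            raise FormatError(
                f"negative value at gene {idx[g]!r}, sample {cols[s]!r}"
            )
        if self.value_kind == "tag_count":
            if values.size and not np.allclose(values, np.round(values)):
                g, s = np.argwhere(values != np.round(values))[0]
                raise FormatError(
                    f"non-integer tag count at gene {idx[g]!r}, sample {cols[s]!r}"
                )
            self.data = self.data.round().astype(np.int64)

    @property
    def gene_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def n_genes(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    def library_sizes(self) -> pd.Series:
        """Per-sample column totals (tag counts summed over genes)."""
        return self.data.sum(axis=0)

    def subset_samples(self, sample_ids: Sequence[str]) -> "ExpressionTable":
        missing = [s for s in sample_ids if s not in self.data.columns]
        if missing:
            raise KeyError(f"unknown sample identifiers: {missing}")
        return ExpressionTable(self.data.loc[:, list(sample_ids)].copy(), self.value_kind)


@dataclass
class PhenotypeLabels:
    """One categorical label per sample, in sample order."""

    sample_ids: list[str]
    labels: list[str]

    def __post_init__(self) -> None:
        if len(self.sample_ids) != len(self.labels):
            raise FormatError(
                f"{len(self.sample_ids)} samples but {len(self.labels)} labels"
            )

    @property
    def classes(self) -> list[str]:
        seen: dict[str, None] = {}
        for lab in self.labels:
            seen.setdefault(lab, None)
        return list(seen)

    def as_series(self) -> pd.Series:
        return pd.Series(self.labels, index=self.sample_ids, name="label")

    def require_two_classes(self) -> None:
        if len(self.classes) < 2:
            raise ValueError("two-class operation requires >= 2 distinct labels")


@dataclass(frozen=True)
class GeneSet:
    name: str
    description: str
    members: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.members:
            raise FormatError(f"gene set {self.name!r} is empty")


@dataclass
class GeneSetCollection:
    """Ordered collection of uniquely named gene sets."""

    entries: list[GeneSet] = field(default_factory=list)

    def __post_init__(self) -> None:
        names = [e.name for e in self.entries]
        if len(names) != len(set(names)):
            dup = next(n for i, n in enumerate(names) if n in names[:i])
            raise FormatError(f"duplicate gene set name {dup!r}")

    def __iter__(self):
        return iter(self.entries)

    def __len__(self) -> int:
        return len(self.entries)

    def __getitem__(self, name: str) -> GeneSet:
        for e in self.entries:
            if e.name == name:
                return e
        raise KeyError(name)

    @property
    def names(self) -> list[str]:
        return [e.name for e in self.entries]


def _dedup(items: Iterable[str]) -> tuple[str, ...]:
    seen: dict[str, None] = {}
    for it in items:
        seen.setdefault(it, None)
    return tuple(seen)


def read_expression_table(path: str | Path, value_kind: str) -> ExpressionTable:
    """Read a TSV expression table (first column gene id, header = samples)."""
    df = pd.read_csv(path, sep="\t", index_col=0, dtype={0: str})
    df.index = df.index.astype(str)
    df.index.name = None
    df.columns = df.columns.astype(str)
    try:
        df = df.astype(float)
    except ValueError as exc:
        raise FormatError(f"{path}: non-numeric expression value ({exc})") from exc
    try:
        return ExpressionTable(df, value_kind)
    except FormatError as exc:
        raise FormatError(f"{path}: {exc}") from exc


def write_expression_table(table: ExpressionTable, path: str | Path) -> None:
    """Write a TSV expression table; reals use 8 significant digits
    (guarantees round-trip agreement within 1e-6 relative tolerance)."""
    fmt = None if table.value_kind == "tag_count" else "%.8g"
    table.data.to_csv(path, sep="\t", float_format=fmt, index_label="gene_id")


def read_gene_sets(path: str | Path) -> GeneSetCollection:
    """Read a GMT file: per line, name, description, then >= 1 member."""
    entries: list[GeneSet] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(
                    f"{path}: line {lineno}: expected >= 3 tab-separated fields, "
                    f"got {len(fields)}"
                )
            name, desc, *members = fields
            members = [m for m in members if m]
            deduped = _dedup(members)
            if len(deduped) < len(members):
                log.warning(
                    "gene set %r: dropped %d duplicate member(s)",
                    name,
                    len(members) - len(deduped),
                )
            entries.append(GeneSet(name, desc, deduped))
    return GeneSetCollection(entries)


def write_gene_sets(collection: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w") as fh:
        for gs in collection:
            fh.write("\t".join([gs.name, gs.description, *gs.members]) + "\n")


def read_phenotype_labels(path: str | Path) -> PhenotypeLabels:
    """Read a CLS-like phenotype file.

    Line 1: ``<n_samples> <n_classes> 1``; line 2: ``# <class names...>``
    (optional); final non-comment line: one label per sample.
    """
    with open(path) as fh:
        lines = [ln.strip() for ln in fh if ln.strip()]
    if len(lines) < 2:
        raise FormatError(f"{path}: expected header and label lines")
    header = lines[0].split()
    try:
        n_samples = int(header[0])
    except (ValueError, IndexError) as exc:
        raise FormatError(f"{path}: malformed header {lines[0]!r}") from exc
    label_line = next((ln for ln in lines[1:] if not ln.startswith("#")), None)
    if label_line is None:
        raise FormatError(f"{path}: no label line found")
    labels = label_line.split()
    if len(labels) != n_samples:
        raise FormatError(
            f"{path}: header declares {n_samples} samples but "
            f"{len(labels)} labels follow"
        )
    sample_ids = [f"S{i + 1}" for i in range(n_samples)]
    return PhenotypeLabels(sample_ids, labels)


def write_phenotype_labels(labels: PhenotypeLabels, path: str | Path) -> None:
    classes = labels.classes
    with open(path, "w") as fh:
        fh.write(f"{len(labels.sample_ids)} {len(classes)} 1\n")
        fh.write("# " + " ".join(classes) + "\n")
        fh.write(" ".join(labels.labels) + "\n")


def read_homolog_table(path: str | Path) -> dict[str, list[str]]:
    """Read a homolog map TSV: source id, comma-separated ordered target ids.

    The order of target identifiers is authoritative input (the first entry
    is used as the representative during signature mapping).
    """
    mapping: dict[str, list[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise FormatError(
                    f"{path}: line {lineno}: expected 2 tab-separated fields"
                )
            src, targets = fields[0], fields[1]
            if src in mapping:
                raise FormatError(f"{path}: line {lineno}: duplicate source id {src!r}")
            target_list = [t for t in targets.split(",") if t]
            if not target_list:
                raise FormatError(f"{path}: line {lineno}: no target ids for {src!r}")
            deduped = list(_dedup(target_list))
            mapping[src] = deduped
    return mapping


def write_homolog_table(mapping: Mapping[str, Sequence[str]], path: str | Path) -> None:
    with open(path, "w") as fh:
        for src, targets in mapping.items():
            fh.write(f"{src}\t{','.join(targets)}\n")
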