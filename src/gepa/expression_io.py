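"""Readers and writers for on-disk artifacts.

Formats are deliberately plain: tab-separated expression matrices with a
mandatory header (first column gene id, remaining columns samples),
Cufflinks-style ``*.fpkm_tracking`` isoform tables, one-id-per-line gene
lists, and the tab-separated pattern table the classifier writes.  Missing
values are not permitted anywhere — an NA cell is a hard error, since the
preprocessing chain produces none.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from gepa.core import ClassificationRecord, PatternLabel

__all__ = [
    "ExpressionTable",
    "IsoformTable",
    "GeneList",
    "read_expression_table",
    "write_expression_table",
    "read_isoform_tracking",
    "read_gene_list",
    "write_pattern_table",
    "read_pattern_table",
]

GENE_LIST_ROLES = ("negative_control", "positive_control", "external", "annotation")


@dataclass
class ExpressionTable:
    """Gene × sample matrix of non-negative expression values.

    ``data`` is a float DataFrame with unique gene ids on the index and
    unique sample ids as columns.  ``normalized`` distinguishes raw FPKM
    input from the classifier-ready matrix (per-sample totals rescaled,
    pseudocount added, hence strictly positive).
    """

    data: pd.DataFrame
    normalized: bool = False

    def __post_init__(self) -> None:
        df = self.data
        if df.index.has_duplicates:
            dup = df.index[df.index.duplicated()][0]
            raise ValueError(f"duplicate gene id {dup!r}")
        if df.columns.has_duplicates:
            dup = df.columns[df.columns.duplicated()][0]
            raise ValueError(f"duplicate sample id {dup!r}")
        if len(df.columns) < 2:
            raise ValueError("an expression table needs at least 2 samples")
        vals = df.to_numpy()
        if not np.issubdtype(vals.dtype, np.number):
            raise ValueError("expression values must be numeric")
        if np.isnan(vals).any():
            g, s = np.argwhere(np.isnan(vals))[0]
            raise ValueError(f"missing value at gene {df.index[g]!r}, sample {df.columns[s]!r}")
        if (vals < 0).any():
            g, s = np.argwhere(vals < 0)[0]
            raise ValueError(
                f"negative value {vals[g, s]} at gene {df.index[g]!r}, sample {df.columns[s]!r}"
            )
        if self.normalized and (vals <= 0).any():
            g, s = np.argwhere(vals <= 0)[0]
            raise ValueError(
                f"normalized table must be strictly positive; offending gene "
                f"{df.index[g]!r}, sample {df.columns[s]!r}"
            )
        self.data = df.astype(float)

    @property
    def gene_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy()

    @property
    def n_genes(self) -> int:
        return len(self.data.index)

    @property
    def n_samples(self) -> int:
        return len(self.data.columns)

    def reorder_samples(self, sample_order: Sequence[str]) -> "ExpressionTable":
        missing = [s for s in sample_order if s not in self.data.columns]
        if missing:
            raise ValueError(f"unknown sample(s) in requested order: {missing}")
        if len(sample_order) != self.n_samples:
            absent = [s for s in self.data.columns if s not in set(sample_order)]
            raise ValueError(f"sample order omits sample(s): {absent}")
        return ExpressionTable(self.data.loc[:, list(sample_order)], self.normalized)


@dataclass
class IsoformTable:
    """Long-format isoform-level rows: isoform, parent gene, sample, FPKM, status.

    Statuses are free tokens preserved verbatim; only the configured
    usable-status token (``"OK"`` by default) has meaning downstream, where
    per-gene FPKM is the sum of the usable isoforms.
    """

    rows: pd.DataFrame  # columns: isoform_id, gene_id, sample_id, fpkm, status

    REQUIRED = ("isoform_id", "gene_id", "sample_id", "fpkm", "status")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.rows.columns]
        if missing:
            raise ValueError(
                f"isoform table missing column(s) {missing}; present: {list(self.rows.columns)}"
            )
        fpkm = pd.to_numeric(self.rows["fpkm"], errors="coerce")
        if fpkm.isna().any():
            bad = self.rows.loc[fpkm.isna()].iloc[0]
            raise ValueError(f"non-numeric FPKM for isoform {bad['isoform_id']!r}")
        if (fpkm < 0).any():
            bad = self.rows.loc[fpkm < 0].iloc[0]
            raise ValueError(f"negative FPKM for isoform {bad['isoform_id']!r}")
        rows = self.rows.copy()
        rows["fpkm"] = fpkm.astype(float)
        self.rows = rows.reset_index(drop=True)

    @property
    def sample_ids(self) -> list[str]:
        # first-appearance order
        return list(dict.fromkeys(self.rows["sample_id"]))

    @property
    def gene_ids(self) -> list[str]:
        return list(dict.fromkeys(self.rows["gene_id"]))

    @property
    def isoform_ids(self) -> list[str]:
        return list(dict.fromkeys(self.rows["isoform_id"]))

    def __len__(self) -> int:
        return len(self.rows)


@dataclass(frozen=True)
class GeneList:
    """Ordered, de-duplicated gene ids with a role tag."""

    ids: tuple[str, ...]
    role: str

    def __post_init__(self) -> None:
        if self.role not in GENE_LIST_ROLES:
            raise ValueError(f"unknown gene-list role {self.role!r}; expected one of {GENE_LIST_ROLES}")
        if not self.ids:
            raise ValueError("gene list is empty")
        if len(set(self.ids)) != len(self.ids):
            object.__setattr__(self, "ids", tuple(dict.fromkeys(self.ids)))

    def __len__(self) -> int:
        return len(self.ids)

    def __iter__(self):
        return iter(self.ids)


def read_expression_table(
    path: str | Path, sample_order: Sequence[str] | None = None
) -> ExpressionTable:
    """Read a raw gene × sample TSV (header row; first column gene ids).

    Duplicate gene ids, negative values, NA cells and non-numeric cells are
    hard errors.  ``sample_order``, when given, must name every column of
    the file exactly once; columns are returned in that order.
    """
    df = pd.read_csv(path, sep="\t", header=0, index_col=0, dtype=str)
    df.index = df.index.astype(str)
    if df.index.has_duplicates:
        dup = df.index[df.index.duplicated()][0]
        raise ValueError(f"{path}: duplicate gene id {dup!r}")
    numeric = pd.DataFrame(index=df.index)
    for col in df.columns:
        converted = pd.to_numeric(df[col], errors="coerce")
        bad = converted.isna() & df[col].notna()
        if bad.any():
            gene = df.index[bad][0]
            raise ValueError(
                f"{path}: non-numeric cell {df.loc[gene, col]!r} at gene {gene!r}, sample {col!r}"
            )
        if converted.isna().any():
            gene = df.index[converted.isna()][0]
            raise ValueError(f"{path}: missing value at gene {gene!r}, sample {col!r}")
        # re-parse through the correctly-rounded strtod so writes round-trip
        numeric[col] = df[col].astype(float)
    table = ExpressionTable(numeric, normalized=False)
    if sample_order is not None:
        table = table.reorder_samples(sample_order)
    return table


def write_expression_table(table: ExpressionTable, path: str | Path) -> None:
    """Write a gene × sample TSV that :func:`read_expression_table` round-trips.

    Floats are printed with Python's shortest-repr formatting, so re-reading
    reproduces every value bit for bit.
    """
    df = table.data.copy()
    df.index.name = "gene_id"
    # shortest-repr float formatting so re-reading is bit-identical
    df.to_csv(path, sep="\t", float_format=lambda x: repr(float(x)))


def read_isoform_tracking(
    path: str | Path,
    long_format: bool = False,
    sample_id: str | None = None,
) -> IsoformTable:
    """Read a Cufflinks-style isoform tracking table.

    Two dialects are accepted:

    * per-sample file (default): columns ``tracking_id, gene_id, FPKM,
      FPKM_status``; ``sample_id`` names the sample the file belongs to.
    * long format (``long_format=True``): the same columns plus a
      ``sample_id`` (or ``sample``) column.

    All rows are returned with statuses preserved verbatim — no filtering
    happens at read time.
    """
    df = pd.read_csv(path, sep="\t", header=0, dtype=str)
    required = ["tracking_id", "gene_id", "FPKM", "FPKM_status"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(
            f"{path}: missing required column(s) {missing}; present: {list(df.columns)}"
        )
    if long_format:
        sample_col = "sample_id" if "sample_id" in df.columns else (
            "sample" if "sample" in df.columns else None
        )
        if sample_col is None:
            raise ValueError(
                f"{path}: long format requires a sample_id column; present: {list(df.columns)}"
            )
        samples = df[sample_col].astype(str)
    else:
        if sample_id is None:
            raise ValueError("per-sample tracking files need an explicit sample_id")
        samples = pd.Series([sample_id] * len(df), index=df.index)
    rows = pd.DataFrame(
        {
            "isoform_id": df["tracking_id"].astype(str),
            "gene_id": df["gene_id"].astype(str),
            "sample_id": samples,
            "fpkm": pd.to_numeric(df["FPKM"], errors="coerce"),
            "status": df["FPKM_status"].astype(str),
        }
    )
    return IsoformTable(rows)


def concat_isoform_tables(tables: Sequence[IsoformTable]) -> IsoformTable:
    """Stack per-sample isoform tables into one long table."""
    if not tables:
        raise ValueError("no isoform tables to concatenate")
    return IsoformTable(pd.concat([t.rows for t in tables], ignore_index=True))


def read_gene_list(path: str | Path, role: str) -> GeneList:
    """Read a one-id-per-line gene list; blank lines and ``#`` comments skipped."""
    ids: list[str] = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            token = line.strip()
            if not token or token.startswith("#"):
                continue
            ids.append(token)
    deduped = tuple(dict.fromkeys(ids))
    if not deduped:
        raise ValueError(f"{path}: gene list is empty after skipping blanks/comments")
    return GeneList(deduped, role)


PATTERN_COLUMNS = (
    "gene_id",
    "pattern",
    "n_enriched_samples",
    "decision_fold_change",
    "sorted_sample_order",
)


def write_pattern_table(records: Sequence[ClassificationRecord], path: str | Path) -> None:
    """Write classification records as a tab-separated pattern table.

    Columns: gene_id, pattern (canonical string), n_enriched_samples
    (0 for Even/Gradient), decision_fold_change, sorted_sample_order
    (descending expression, joined by ``,``).  Output is bit-stable for a
    fixed input.
    """
    if not records:
        raise ValueError("no records to write")
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\t".join(PATTERN_COLUMNS) + "\n")
        for rec in records:
            fh.write(
                "\t".join(
                    (
                        rec.gene_id,
                        rec.label.canonical(),
                        str(rec.n_enriched_samples),
                        repr(rec.decision_fold_change),
                        ",".join(rec.descending_order),
                    )
                )
                + "\n"
            )


def read_pattern_table(
    path: str | Path, sample_ids: Sequence[str] | None = None
) -> list[ClassificationRecord]:
    """Re-read a pattern table written by :func:`write_pattern_table`."""
    df = pd.read_csv(path, sep="\t", header=0, dtype=str)
    missing = [c for c in PATTERN_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing pattern column(s) {missing}")
    records = []
    for _, row in df.iterrows():
        label = PatternLabel.from_string(row["pattern"], sample_ids)
        records.append(
            ClassificationRecord(
                gene_id=str(row["gene_id"]),
                label=label,
                decision_fold_change=float(row["decision_fold_change"]),
                descending_order=tuple(row["sorted_sample_order"].split(",")),
            )
        )
    return records
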