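"""Downstream analyses built on classification output.

* map an external gene list (e.g. a published top-100 predicted-regulator
  list) onto the category space and report its distribution;
* percent-of-sum specificity profiles for heatmap-style displays;
* isoform-level classification and isoform-switch detection (a gene whose
  transcript isoforms land in discordant enrichment categories, indicating
  stage-associated alternative splicing);
* annotation subsetting, e.g. restricting results to lncRNAs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from gepa.core import (
    ClassificationRecord,
    PatternLabel,
    Threshold,
    DEFAULT_THRESHOLD,
    category_counts,
    classify_matrix,
)
from gepa.expression_io import ExpressionTable, GeneList, IsoformTable
from gepa.preprocess import PreprocessConfig, drop_all_zero_genes, normalize_and_pseudocount

__all__ = [
    "CategoryDistribution",
    "IsoformSwitchCall",
    "IsoformClassification",
    "map_external_list",
    "percent_of_sum",
    "classify_isoforms",
    "detect_isoform_switches",
    "subset_by_annotation",
]


@dataclass(frozen=True)
class CategoryDistribution:
    """Category counts and percentages for a queried gene list.

    Percentages are over the matched genes only and sum to 100; unmatched
    ids are listed, never counted.  ``grouped`` holds an optional coarser
    grouping of the same counts (user-defined category → group map).
    """

    list_name: str
    counts: Mapping[str, int]
    percentages: Mapping[str, float]
    n_matched: int
    n_unmatched: int
    unmatched_ids: tuple[str, ...] = ()
    grouped: Mapping[str, int] = field(default_factory=dict)


def map_external_list(
    records: Sequence[ClassificationRecord],
    external: GeneList,
    sample_ids: Sequence[str] | None = None,
    list_name: str | None = None,
    grouping: Mapping[str, str] | None = None,
) -> CategoryDistribution:
    """Distribute an external gene list over the nominal category space.

    Counts are zero-filled over all categories; percentages are over the
    matched genes.  ``grouping`` (category name → group name) aggregates
    the full-granularity counts into user-defined coarser bars.
    """
    by_id = {rec.gene_id: rec for rec in records}
    matched = [g for g in external if g in by_id]
    unmatched = tuple(g for g in external if g not in by_id)
    if not matched:
        raise ValueError("no id of the external list matches the classified genes")
    sub = [by_id[g] for g in matched]
    cc = category_counts(sub, sample_ids)
    percentages = {name: 100.0 * c / len(matched) for name, c in cc.counts.items()}
    grouped: dict[str, int] = {}
    if grouping:
        for name, c in cc.counts.items():
            grouped[grouping.get(name, name)] = grouped.get(grouping.get(name, name), 0) + c
    return CategoryDistribution(
        list_name=list_name or external.role,
        counts=cc.counts,
        percentages=percentages,
        n_matched=len(matched),
        n_unmatched=len(unmatched),
        unmatched_ids=unmatched,
        grouped=grouped,
    )


def percent_of_sum(table: ExpressionTable, gene_ids: Sequence[str]) -> pd.DataFrame:
    """Per-gene relative expression as percent of the across-sample sum.

    For each requested gene, value_s / Σ_s value_s × 100; every row sums to
    100.  The display convention behind specificity heatmaps.
    """
    if not table.normalized:
        raise ValueError("percent_of_sum expects a normalized table")
    unknown = [g for g in gene_ids if g not in table.data.index]
    if unknown:
        raise ValueError(f"unknown gene id {unknown[0]!r}")
    sub = table.data.loc[list(gene_ids)]
    return sub.div(sub.sum(axis=1), axis=0) * 100.0


@dataclass(frozen=True)
class IsoformClassification:
    """Per-isoform classification plus the isoform → gene grouping."""

    records: tuple[ClassificationRecord, ...]  # gene_id field holds the isoform id
    gene_of: Mapping[str, str]

    def by_gene(self) -> dict[str, list[ClassificationRecord]]:
        groups: dict[str, list[ClassificationRecord]] = {}
        for rec in self.records:
            groups.setdefault(self.gene_of[rec.gene_id], []).append(rec)
        return groups


def classify_isoforms(
    iso: IsoformTable,
    config: PreprocessConfig = PreprocessConfig(),
    threshold: Threshold | float = DEFAULT_THRESHOLD,
) -> IsoformClassification:
    """Run the classifier at isoform granularity.

    Usable-status rows are pivoted to an isoform × sample matrix, then the
    same chain as for genes is applied — drop all-zero isoforms, rescale
    each sample over the isoform totals themselves, add the pseudocount —
    and each isoform is classified independently.
    """
    rows = iso.rows[iso.rows["status"] == config.ok_status_token]
    if rows.empty:
        raise ValueError("no usable-status isoform rows to classify")
    iso_order = list(dict.fromkeys(rows["isoform_id"]))
    sample_order = iso.sample_ids
    pivot = (
        rows.groupby(["isoform_id", "sample_id"], sort=False)["fpkm"].sum().unstack(fill_value=0.0)
    )
    full = pd.DataFrame(0.0, index=iso_order, columns=sample_order)
    common_s = [s for s in sample_order if s in pivot.columns]
    full.loc[pivot.index.intersection(iso_order), common_s] = pivot.loc[
        pivot.index.intersection(iso_order), common_s
    ]
    table = ExpressionTable(full, normalized=False)
    ready = normalize_and_pseudocount(drop_all_zero_genes(table), config)
    records = tuple(classify_matrix(ready, threshold))
    gene_of = dict(zip(rows["isoform_id"], rows["gene_id"]))
    gene_of = {i: gene_of[i] for i in ready.gene_ids}
    return IsoformClassification(records, gene_of)


@dataclass(frozen=True)
class IsoformSwitchCall:
    """Per-gene isoform-switch verdict.

    ``switch_flag`` is true iff the gene has at least two isoforms whose
    labels differ and at least one of them is enriched; ``reason`` names a
    discordant category pair (or why the gene was not flagged).
    """

    gene_id: str
    isoform_labels: Mapping[str, PatternLabel]
    switch_flag: bool
    reason: str

    def __post_init__(self) -> None:
        if self.switch_flag:
            labels = list(self.isoform_labels.values())
            distinct = {lab.key for lab in labels}
            if len(labels) < 2 or len(distinct) < 2 or not any(l.is_enriched for l in labels):
                raise ValueError("switch_flag requires >=2 discordant isoforms, one enriched")


def detect_isoform_switches(
    groups: Mapping[str, Sequence[ClassificationRecord]],
) -> list[IsoformSwitchCall]:
    """Flag genes whose isoforms fall into discordant enrichment categories.

    ``groups`` maps gene id → its isoform-level records (as produced by
    :meth:`IsoformClassification.by_gene`).  A gene is flagged iff it has
    ≥ 2 isoforms with non-identical labels and at least one enriched label;
    two sentinel labels disagreeing (Gradient vs Even) is not a switch.
    Genes with fewer than two isoforms pass through unflagged.  The verdict
    does not depend on isoform order.
    """
    calls: list[IsoformSwitchCall] = []
    for gene_id, recs in groups.items():
        labels = {rec.gene_id: rec.label for rec in recs}
        if len(labels) < 2:
            calls.append(IsoformSwitchCall(gene_id, labels, False, "single_isoform"))
            continue
        distinct: dict[object, str] = {}
        for iso_id, lab in labels.items():
            distinct.setdefault(lab.key, lab.canonical())
        any_enriched = any(lab.is_enriched for lab in labels.values())
        if len(distinct) >= 2 and any_enriched:
            names = sorted(distinct.values())
            enriched_name = next(
                lab.canonical()
                for lab in sorted(labels.values(), key=lambda l: l.canonical())
                if lab.is_enriched
            )
            other = next(n for n in names if n != enriched_name)
            calls.append(
                IsoformSwitchCall(gene_id, labels, True, f"{enriched_name} vs {other}")
            )
        elif len(distinct) < 2:
            calls.append(IsoformSwitchCall(gene_id, labels, False, "concordant"))
        else:
            calls.append(IsoformSwitchCall(gene_id, labels, False, "no_enriched_label"))
    return calls


def subset_by_annotation(
    records: Sequence[ClassificationRecord],
    annotation: GeneList,
    sample_ids: Sequence[str] | None = None,
) -> tuple[list[ClassificationRecord], CategoryDistribution]:
    """Restrict records to an annotation-defined subset (e.g. lncRNAs).

    Returns the filtered records (in original order) and their category
    distribution.
    """
    wanted = set(annotation)
    sub = [rec for rec in records if rec.gene_id in wanted]
    if not sub:
        raise ValueError("annotation list has no overlap with the classified genes")
    dist = map_external_list(records, annotation, sample_ids, list_name="annotation")
    return sub, dist
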