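"""The GEPA classifier.

Every gene is reduced to one vector of positive expression values, one per
cell state.  The classifier sorts the vector in descending order and scans
consecutive pairs from the top: the first pair whose fold change (higher /
lower) reaches the threshold defines a cut, and the states above the cut
are the gene's enrichment pattern.  If no pair reaches the threshold the
gene is "Even" when the overall max/min ratio is below the threshold and
"Gradient" otherwise.

The rule is deliberately deterministic — no p-values, no between-gene
comparison — so the category space is a fixed partition: for N states
there are 2^N − 2 enriched subsets plus the two sentinels.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "Threshold",
    "PatternLabel",
    "ClassificationRecord",
    "CategoryCounts",
    "DEFAULT_THRESHOLD",
    "classify_gene",
    "classify_matrix",
    "enumerate_categories",
    "category_counts",
]

#: Default fold-change threshold.  Calibration against housekeeping-gene
#: negative controls and lineage-marker positive controls selects 2.5 as the
#: value minimizing false-positive plus false-negative rates.
DEFAULT_THRESHOLD = 2.5

GRADIENT = "Gradient"
EVEN = "Even"


@dataclass(frozen=True)
class Threshold:
    """Fold-change threshold; must exceed 1.

    A threshold ≤ 1 would make the very first comparison of the sorted
    vector terminate the scan for every gene, so it is rejected.
    """

    value: float

    def __post_init__(self) -> None:
        if not np.isfinite(self.value) or self.value <= 1.0:
            raise ValueError(f"threshold must be a finite value > 1, got {self.value!r}")


def _as_threshold(t: "Threshold | float") -> float:
    if isinstance(t, Threshold):
        return float(t.value)
    return float(Threshold(float(t)).value)


@dataclass(frozen=True)
class PatternLabel:
    """Category assigned to one gene.

    ``kind`` is one of ``enriched``, ``gradient``, ``even``.  For enriched
    labels ``enriched_samples`` is a non-empty proper subset of the sample
    universe, stored in the user-supplied sample order; for the sentinels it
    is empty.
    """

    kind: str
    enriched_samples: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.kind not in ("enriched", "gradient", "even"):
            raise ValueError(f"unknown label kind {self.kind!r}")
        if self.kind == "enriched" and not self.enriched_samples:
            raise ValueError("enriched label requires at least one sample")
        if self.kind != "enriched" and self.enriched_samples:
            raise ValueError(f"{self.kind!r} label must not carry samples")

    @property
    def is_enriched(self) -> bool:
        return self.kind == "enriched"

    @property
    def key(self) -> "frozenset[str] | str":
        """Order-independent identity used for counting."""
        if self.kind == "enriched":
            return frozenset(self.enriched_samples)
        return GRADIENT if self.kind == "gradient" else EVEN

    def canonical(self) -> str:
        """Canonical category string, e.g. ``"ES&MCP&CM"``, ``"Even"``.

        Enriched samples are joined by ``&`` in the user-supplied sample
        order, giving stable order-independent category names.
        """
        if self.kind == "enriched":
            return "&".join(self.enriched_samples)
        return GRADIENT if self.kind == "gradient" else EVEN

    @classmethod
    def even(cls) -> "PatternLabel":
        return cls("even")

    @classmethod
    def gradient(cls) -> "PatternLabel":
        return cls("gradient")

    @classmethod
    def enriched(cls, samples: Iterable[str]) -> "PatternLabel":
        return cls("enriched", tuple(samples))

    @classmethod
    def from_string(cls, text: str, sample_ids: Sequence[str] | None = None) -> "PatternLabel":
        """Parse a canonical category string.

        If ``sample_ids`` is given, the enriched samples are re-ordered to
        that canonical order and validated against it.
        """
        if text == EVEN:
            return cls.even()
        if text == GRADIENT:
            return cls.gradient()
        parts = tuple(text.split("&"))
        if sample_ids is not None:
            unknown = set(parts) - set(sample_ids)
            if unknown:
                raise ValueError(f"unknown sample(s) in pattern {text!r}: {sorted(unknown)}")
            parts = tuple(s for s in sample_ids if s in set(parts))
        return cls.enriched(parts)


@dataclass(frozen=True)
class ClassificationRecord:
    """Per-gene classification result, with audit fields.

    ``decision_fold_change`` is the consecutive ratio that terminated the
    scan for enriched genes; for Even and Gradient it is the overall
    max/min ratio (an output-only audit value, not part of the rule).
    ``descending_order`` is the stable descending-expression permutation of
    the sample ids (ties keep the user-supplied order).
    """

    gene_id: str
    label: PatternLabel
    decision_fold_change: float
    descending_order: tuple[str, ...]

    @property
    def n_enriched_samples(self) -> int:
        return len(self.label.enriched_samples)


def classify_gene(
    values: Sequence[float] | np.ndarray,
    sample_ids: Sequence[str],
    threshold: Threshold | float = DEFAULT_THRESHOLD,
    gene_id: str = "",
) -> ClassificationRecord:
    """Classify one gene's expression vector.

    Parameters
    ----------
    values
        Strictly positive expression values (normalized and pseudocounted),
        one per sample.  Non-positive values are rejected: the caller must
        apply the pseudocount first so all fold changes are well defined.
    sample_ids
        Sample names in the user-supplied canonical order; same length as
        ``values`` (N ≥ 2).
    threshold
        Fold-change threshold T > 1.  The comparison is ``ratio >= T``.

    Returns
    -------
    ClassificationRecord
        The assigned :class:`PatternLabel` plus audit fields.

    Notes
    -----
    Procedure: sort descending (stable; ties keep input order), then scan
    consecutive pairs from the top.  At the first pair with
    ``v_k / v_{k+1} >= T`` return an enriched label over the top-k samples.
    If no pair triggers, the gene is Even when ``v_max / v_min < T`` and
    Gradient otherwise (equality at the boundary is Gradient).  Comparisons
    are exact — no epsilon — so category counts are reproducible bit for bit.
    """
    v = np.asarray(values, dtype=float)
    n = v.size
    if n != len(sample_ids):
        raise ValueError(f"got {n} values for {len(sample_ids)} samples")
    if n < 2:
        raise ValueError("classification requires at least 2 samples")
    if not np.all(np.isfinite(v)) or np.any(v <= 0):
        raise ValueError(
            f"gene {gene_id or '<unnamed>'}: all values must be finite and > 0 "
            "(apply normalization and pseudocount first)"
        )
    t = _as_threshold(threshold)

    # stable argsort of -v keeps the user-supplied order among ties
    order = np.argsort(-v, kind="stable")
    sv = v[order]
    ratios = sv[:-1] / sv[1:]
    hits = np.nonzero(ratios >= t)[0]
    descending = tuple(sample_ids[i] for i in order)
    if hits.size:
        k = int(hits[0])
        top = set(order[: k + 1].tolist())
        enriched = tuple(s for i, s in enumerate(sample_ids) if i in top)
        label = PatternLabel.enriched(enriched)
        fc = float(ratios[k])
    else:
        fc = float(sv[0] / sv[-1])
        label = PatternLabel.gradient() if fc >= t else PatternLabel.even()
    return ClassificationRecord(gene_id, label, fc, descending)


def classify_matrix(table, threshold: Threshold | float = DEFAULT_THRESHOLD) -> list[ClassificationRecord]:
    """Classify every gene of a preprocessed expression table.

    The table must be normalized (classifier-ready); each gene is classified
    independently and gene order is preserved.
    """
    if not table.normalized:
        raise ValueError("classify_matrix requires a normalized (classifier-ready) table")
    gene_ids = list(table.gene_ids)
    if not gene_ids:
        raise ValueError("cannot classify an empty table")
    sample_ids = list(table.sample_ids)
    values = np.asarray(table.values, dtype=float)
    t = _as_threshold(threshold)
    return [
        classify_gene(values[i], sample_ids, t, gene_id=g) for i, g in enumerate(gene_ids)
    ]


def enumerate_categories(
    sample_ids: Sequence[str], include_sentinels: bool = True
) -> list[PatternLabel]:
    """Enumerate the nominal category space for a sample universe.

    All proper non-empty subsets of the N samples, ordered by subset size
    and then by sample order, followed by Gradient and Even when
    ``include_sentinels``.  Length is ``2^N − 2`` (+2 with sentinels): for
    the five cardiovascular states this is the 32-category space.
    """
    sample_ids = list(sample_ids)
    n = len(sample_ids)
    if n < 2:
        raise ValueError("category enumeration requires at least 2 samples")
    if len(set(sample_ids)) != n:
        raise ValueError("duplicate sample ids")
    labels: list[PatternLabel] = [
        PatternLabel.enriched(combo)
        for size in range(1, n)
        for combo in itertools.combinations(sample_ids, size)
    ]
    if include_sentinels:
        labels.append(PatternLabel.gradient())
        labels.append(PatternLabel.even())
    return labels


@dataclass(frozen=True)
class CategoryCounts:
    """Counts and fractions of classification records per nominal category.

    ``counts`` is zero-filled over the full category space so absent
    categories are explicit.  ``aggregates`` summarizes single-lineage,
    multi-lineage, Gradient and Even totals.
    """

    counts: Mapping[str, int]
    fractions: Mapping[str, float]
    aggregates: Mapping[str, int]
    n_genes: int
    sample_ids: tuple[str, ...] = field(default=())

    def __getitem__(self, category: str) -> int:
        return self.counts[category]


def category_counts(
    records: Sequence[ClassificationRecord],
    sample_ids: Sequence[str] | None = None,
) -> CategoryCounts:
    """Tabulate records over the full nominal category space.

    ``sample_ids`` fixes the category universe and its canonical order; when
    omitted it is inferred from the first record's descending order (the
    category *set* is then correct, only the display order of composite
    names may differ from the caller's convention).
    """
    if not records:
        raise ValueError("category_counts requires at least one record")
    if sample_ids is None:
        sample_ids = records[0].descending_order
    sample_ids = list(sample_ids)
    labels = enumerate_categories(sample_ids, include_sentinels=True)
    by_key = {lab.key: lab.canonical() for lab in labels}
    counts = {lab.canonical(): 0 for lab in labels}
    n_single = n_multi = n_grad = n_even = 0
    for rec in records:
        key = rec.label.key
        name = by_key.get(key)
        if name is None:
            raise ValueError(
                f"record {rec.gene_id!r} labelled over samples outside the universe "
                f"{sample_ids}: {rec.label.canonical()!r}"
            )
        counts[name] += 1
        if rec.label.is_enriched:
            if rec.n_enriched_samples == 1:
                n_single += 1
            else:
                n_multi += 1
        elif rec.label.kind == "gradient":
            n_grad += 1
        else:
            n_even += 1
    n = len(records)
    fractions = {name: c / n for name, c in counts.items()}
    aggregates = {
        "single_lineage": n_single,
        "multi_lineage": n_multi,
        "gradient": n_grad,
        "even": n_even,
    }
    return CategoryCounts(counts, fractions, aggregates, n, tuple(sample_ids))
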