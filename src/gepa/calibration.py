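"""Threshold calibration and the shuffle null.

The fold-change threshold trades sensitivity against specificity: a loose
threshold calls lineage enrichment on housekeeping genes (false positives),
a stringent one misses genuine lineage markers (false negatives).  The
calibration machinery measures both rates from user-supplied control lists
across a threshold grid and recommends the threshold minimizing their sum —
the procedure that selects 2.5 on the cardiovascular differentiation data
this classifier was designed around.

The shuffle null destroys the gene × sample structure while conserving the
value multiset, showing that the enrichment-category distribution reflects
real structure rather than the value distribution alone.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from gepa.core import (
    ClassificationRecord,
    Threshold,
    category_counts,
    classify_matrix,
)
from gepa.expression_io import ExpressionTable, GeneList

__all__ = [
    "ControlRate",
    "CalibrationReport",
    "false_positive_rate",
    "false_negative_rate",
    "threshold_sweep",
    "shuffle_matrix",
]

SHUFFLE_MODES = ("global", "within_gene")


@dataclass(frozen=True)
class ControlRate:
    """A control-list rate: exact fraction plus its integer ingredients.

    ``rate`` is the unrounded k/n; ``n_found`` counts control ids present
    among the classified genes (the denominator), ``missing_ids`` the
    control ids absent from the matrix (reported, never counted).
    """

    rate: float
    n_flagged: int
    n_found: int
    missing_ids: tuple[str, ...] = ()

    @property
    def percent(self) -> float:
        return 100.0 * self.rate

    def rounded(self, digits: int = 3) -> float:
        """Rate rounded to 0.1% for comparison with published figures."""
        return round(self.rate, digits)


def false_positive_rate(
    records: Sequence[ClassificationRecord], negatives: GeneList
) -> ControlRate:
    """Fraction of present negative controls assigned any enriched pattern.

    Housekeeping genes should come out Even or Gradient; any lineage
    enrichment pattern counts as a false positive.  The denominator is the
    number of control ids actually present among the records.
    """
    by_id = {rec.gene_id: rec for rec in records}
    present = [g for g in negatives if g in by_id]
    if not present:
        raise ValueError("no negative-control id matches the classified genes")
    flagged = sum(1 for g in present if by_id[g].label.is_enriched)
    missing = tuple(g for g in negatives if g not in by_id)
    return ControlRate(flagged / len(present), flagged, len(present), missing)


def false_negative_rate(
    records: Sequence[ClassificationRecord],
    positives: GeneList,
    expected: Mapping[str, Sequence[str]] | None = None,
) -> ControlRate:
    """Fraction of present positive controls NOT assigned an enriched pattern.

    A positive control is captured by ANY enriched pattern by default — the
    calibration counts lineage-enrichment presence, not lineage identity.
    Pass ``expected`` (gene id → required enriched sample subset) for the
    strict mode where capture additionally requires the expected lineage set.
    """
    by_id = {rec.gene_id: rec for rec in records}
    present = [g for g in positives if g in by_id]
    if not present:
        raise ValueError("no positive-control id matches the classified genes")

    def captured(g: str) -> bool:
        rec = by_id[g]
        if not rec.label.is_enriched:
            return False
        if expected is not None and g in expected:
            return set(rec.label.enriched_samples) == set(expected[g])
        return True

    lost = sum(1 for g in present if not captured(g))
    missing = tuple(g for g in positives if g not in by_id)
    return ControlRate(lost / len(present), lost, len(present), missing)


@dataclass(frozen=True)
class CalibrationReport:
    """Per-threshold false-positive / false-negative rates and counts."""

    thresholds: tuple[float, ...]
    fpr: tuple[float, ...]
    fnr: tuple[float, ...]
    n_negative_found: int
    n_positive_found: int
    recommended_threshold: float
    category_counts: Mapping[float, Mapping[str, int]] = field(default_factory=dict)
    seed: int | None = None

    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "thresholds": list(self.thresholds),
            "fpr": list(self.fpr),
            "fnr": list(self.fnr),
            "n_negative_found": self.n_negative_found,
            "n_positive_found": self.n_positive_found,
            "recommended_threshold": self.recommended_threshold,
            "category_counts": {str(t): dict(c) for t, c in self.category_counts.items()},
        }
        if self.seed is not None:
            payload["seed"] = self.seed
        text = json.dumps(payload, indent=2, sort_keys=True)
        if path is not None:
            Path(path).write_text(text + "\n", encoding="utf-8")
        return text


def threshold_sweep(
    table: ExpressionTable,
    thresholds: Sequence[float],
    negatives: GeneList | None = None,
    positives: GeneList | None = None,
) -> CalibrationReport:
    """Classify the matrix at each threshold and report both error rates.

    Thresholds must be strictly increasing and each > 1.  The recommended
    threshold is the sweep's argmin of fpr + fnr (missing control lists
    contribute 0 to the sum).
    """
    ts = [Threshold(float(t)).value for t in thresholds]
    if any(b <= a for a, b in zip(ts, ts[1:])):
        raise ValueError(f"thresholds must be strictly increasing, got {list(thresholds)}")
    fprs: list[float] = []
    fnrs: list[float] = []
    counts: dict[float, Mapping[str, int]] = {}
    n_neg = n_pos = 0
    for t in ts:
        records = classify_matrix(table, t)
        counts[t] = category_counts(records, table.sample_ids).counts
        if negatives is not None:
            fp = false_positive_rate(records, negatives)
            fprs.append(fp.rate)
            n_neg = fp.n_found
        else:
            fprs.append(0.0)
        if positives is not None:
            fn = false_negative_rate(records, positives)
            fnrs.append(fn.rate)
            n_pos = fn.n_found
        else:
            fnrs.append(0.0)
    best = int(np.argmin([a + b for a, b in zip(fprs, fnrs)]))
    return CalibrationReport(
        thresholds=tuple(ts),
        fpr=tuple(fprs),
        fnr=tuple(fnrs),
        n_negative_found=n_neg,
        n_positive_found=n_pos,
        recommended_threshold=ts[best],
        category_counts=counts,
    )


def shuffle_matrix(table: ExpressionTable, seed: int, mode: str = "global") -> ExpressionTable:
    """Permute a normalized matrix, conserving the value multiset exactly.

    mode="global"
        All values permuted uniformly at random across the whole matrix,
        destroying both gene-wise and sample-wise structure (the null that
        collapses the lineage-enrichment distribution).
    mode="within_gene"
        Each gene's vector permuted across samples.  This conserves every
        gene's own value multiset, hence its enriched-vs-not status; it
        only scrambles WHICH lineages come out enriched.

    Deterministic for a fixed seed.
    """
    if mode not in SHUFFLE_MODES:
        raise ValueError(f"unknown shuffle mode {mode!r}; expected one of {SHUFFLE_MODES}")
    rng = np.random.default_rng(seed)
    vals = table.values.copy()
    if mode == "global":
        flat = vals.ravel()
        rng.shuffle(flat)
        shuffled = flat.reshape(vals.shape)
    else:
        shuffled = rng.permuted(vals, axis=1)
    df = pd.DataFrame(shuffled, index=table.gene_ids, columns=table.sample_ids)
    return ExpressionTable(df, normalized=table.normalized)
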