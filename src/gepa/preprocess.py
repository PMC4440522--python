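"""FPKM preprocessing chain.

The classifier's substrate is built in a fixed order: isoform rows are
summed to gene level over usable ("OK") isoforms, genes that are zero in
every sample are removed, each sample column is rescaled so its total is a
fixed target (one million by default), and finally a pseudocount of one is
added everywhere.  The order matters — filtering changes column sums — and
is pinned.  Applying the pseudocount after scaling keeps fold changes
stable for low-abundance genes: a ratio can never exceed the ratio of the
rescaled values plus one.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Union

import numpy as np
import pandas as pd
import yaml

from gepa.expression_io import ExpressionTable, IsoformTable

__all__ = [
    "PreprocessConfig",
    "aggregate_isoforms",
    "drop_all_zero_genes",
    "normalize_and_pseudocount",
    "prepare_matrix",
]


@dataclass(frozen=True)
class PreprocessConfig:
    """Parameters of the preprocessing chain.

    target_total
        Post-normalization column total (default one million, i.e. values
        become FPKM per million of the per-sample FPKM sum).
    pseudocount
        Added to every value after rescaling (default 1).
    ok_status_token
        The single isoform quality status counted as usable (default "OK").
    """

    target_total: float = 1_000_000.0
    pseudocount: float = 1.0
    ok_status_token: str = "OK"

    def __post_init__(self) -> None:
        if self.target_total <= 0:
            raise ValueError("target_total must be > 0")
        if self.pseudocount < 0:
            raise ValueError("pseudocount must be >= 0")

    @classmethod
    def from_file(cls, path: str | Path) -> "PreprocessConfig":
        """Load from a YAML or JSON mapping with any subset of the fields."""
        text = Path(path).read_text(encoding="utf-8")
        data = json.loads(text) if str(path).endswith(".json") else yaml.safe_load(text)
        if data is None:
            data = {}
        if not isinstance(data, dict):
            raise ValueError(f"{path}: config must be a mapping")
        unknown = set(data) - {"target_total", "pseudocount", "ok_status_token"}
        if unknown:
            raise ValueError(f"{path}: unknown config key(s) {sorted(unknown)}")
        return cls(**data)


def aggregate_isoforms(
    iso: IsoformTable, config: PreprocessConfig = PreprocessConfig()
) -> ExpressionTable:
    """Sum usable isoforms to gene level.

    A gene's FPKM in a sample is the sum of its isoforms there whose status
    equals the usable token; genes whose isoforms are all unusable in a
    sample get 0 there (they are only removed later, and only if zero in
    every sample).  Gene and sample order follow first appearance in the
    isoform table.
    """
    if len(iso) == 0:
        raise ValueError("empty isoform table")
    rows = iso.rows
    gene_order = iso.gene_ids
    sample_order = iso.sample_ids
    ok = rows[rows["status"] == config.ok_status_token]
    agg = (
        ok.groupby(["gene_id", "sample_id"], sort=False)["fpkm"].sum().unstack(fill_value=0.0)
        if len(ok)
        else pd.DataFrame()
    )
    full = pd.DataFrame(0.0, index=gene_order, columns=sample_order)
    if not agg.empty:
        common_g = [g for g in gene_order if g in agg.index]
        common_s = [s for s in sample_order if s in agg.columns]
        full.loc[common_g, common_s] = agg.loc[common_g, common_s]
    return ExpressionTable(full, normalized=False)


def drop_all_zero_genes(table: ExpressionTable) -> ExpressionTable:
    """Remove genes whose FPKM is 0 in every sample; order preserved."""
    if table.normalized:
        raise ValueError("all-zero filtering applies to raw tables only")
    keep = (table.values > 0).any(axis=1)
    if not keep.any():
        raise ValueError("no gene has a positive value in any sample")
    return ExpressionTable(table.data.loc[keep], normalized=False)


def normalize_and_pseudocount(
    table: ExpressionTable, config: PreprocessConfig = PreprocessConfig()
) -> ExpressionTable:
    """Rescale each sample to the target total, then add the pseudocount.

    Each value v in sample s becomes ``v * target_total / colsum(s) +
    pseudocount``.  A sample with zero total cannot be rescaled and is an
    error.
    """
    if table.normalized:
        raise ValueError("table is already normalized")
    colsums = table.values.sum(axis=0)
    zero = np.nonzero(colsums <= 0)[0]
    if zero.size:
        raise ValueError(f"sample {table.sample_ids[zero[0]]!r} has zero total expression")
    scaled = table.data * (config.target_total / colsums) + config.pseudocount
    return ExpressionTable(scaled, normalized=True)


def prepare_matrix(
    iso_or_table: Union[IsoformTable, ExpressionTable],
    config: PreprocessConfig = PreprocessConfig(),
) -> ExpressionTable:
    """Full chain: aggregate (if isoform input) → drop all-zero → normalize.

    Accepts either an isoform table or an already gene-level raw table and
    returns the classifier-ready matrix.
    """
    if isinstance(iso_or_table, IsoformTable):
        table = aggregate_isoforms(iso_or_table, config)
    elif isinstance(iso_or_table, ExpressionTable):
        if iso_or_table.normalized:
            raise ValueError("input table is already normalized")
        table = iso_or_table
    else:
        raise TypeError(f"expected IsoformTable or ExpressionTable, got {type(iso_or_table)!r}")
    table = drop_all_zero_genes(table)
    return normalize_and_pseudocount(table, config)
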